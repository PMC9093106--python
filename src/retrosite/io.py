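"""File I/O: FASTA/FASTQ via Biopython, tables via pandas.

Site tables are emitted both as a QC-rich TSV and as BED (0-based
half-open) for genome-browser use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simlib import LibrarySim, ReadTriple, ToyGenome, TruthRecord
from .sites import IntegrationSite

TRUTH_COLUMNS = [
    "sample",
    "chrom",
    "junction_pos_1based",
    "strand",
    "tsd_len",
    "promoter5",
    "intron_present",
    "copy_count",
]


def write_fasta(genome: ToyGenome, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> ToyGenome:
    return ToyGenome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def _fastq_records(items: Iterable[tuple[str, str, str]]):
    for read_id, seq, quals in items:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
        yield rec


def write_fastq(path, items: Iterable[tuple[str, str, str]]) -> None:
    """Write (read_id, sequence, Phred+33 quality string) records."""
    SeqIO.write(_fastq_records(items), str(path), "fastq")


def read_fastq_triples(r1_path, r2_path, index_path) -> list[ReadTriple]:
    """Zip matched R1/R2/index FASTQ files back into read triples."""
    triples = []
    for r1, r2, ix in zip(
        SeqIO.parse(str(r1_path), "fastq"),
        SeqIO.parse(str(r2_path), "fastq"),
        SeqIO.parse(str(index_path), "fastq"),
        strict=True,
    ):
        if not (r1.id == r2.id == ix.id):
            raise ValueError(f"read id mismatch across mates: {r1.id}/{r2.id}/{ix.id}")

        def q(rec):
            return "".join(chr(v + 33) for v in rec.letter_annotations["phred_quality"])

        triples.append(
            ReadTriple(r1.id, str(r1.seq), q(r1), str(r2.seq), q(r2), str(ix.seq), q(ix))
        )
    return triples


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": t.sample_id,
                "chrom": t.chrom,
                "junction_pos_1based": t.junction_pos_1based,
                "strand": t.strand,
                "tsd_len": t.tsd_len,
                "promoter5": t.promoter5,
                "intron_present": t.intron_present,
                "copy_count": t.copy_count,
            }
            for t in truth
        ],
        columns=TRUTH_COLUMNS,
    )


def write_library(sim: LibrarySim, outdir) -> dict[str, dict[str, Path]]:
    """Write per-sample R1/R2/I1 FASTQ files plus the truth TSV.

    Returns {sample: {"r1": path, "r2": path, "i1": path}}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for sample, triples in sim.reads.items():
        p = {
            "r1": outdir / f"{sample}_R1.fastq",
            "r2": outdir / f"{sample}_R2.fastq",
            "i1": outdir / f"{sample}_I1.fastq",
        }
        write_fastq(p["r1"], ((t.read_id, t.r1_seq, t.r1_quals) for t in triples))
        write_fastq(p["r2"], ((t.read_id, t.r2_seq, t.r2_quals) for t in triples))
        write_fastq(p["i1"], ((t.read_id, t.index_seq, t.index_quals) for t in triples))
        paths[sample] = p
    truth_to_frame(sim.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_fasta(sim.genome, outdir / "reference.fa")
    return paths


def sites_to_frame(sample_id: str, sites: list[IntegrationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": sample_id,
                "chrom": s.chrom,
                "junction_pos_1based": s.junction_pos_1based,
                "strand": s.strand,
                "n_molecules": s.n_molecules,
                "n_reads": s.n_reads,
                "modal_support_fraction": s.modal_support_fraction,
                "copy_number": s.copy_number,
                "flags": ",".join(sorted(s.flags)),
                "tsd_len": s.tsd_len,
                "promoter5_call": s.promoter5_call,
            }
            for s in sites
        ]
    )


def sites_to_bed(sample_id: str, sites: list[IntegrationSite], path) -> None:
    """BED6: 0-based half-open single-base junction intervals, score=n_molecules."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(
                f"{s.chrom}\t{s.junction_pos_1based - 1}\t{s.junction_pos_1based}\t"
                f"{sample_id}:site{i}\t{s.n_molecules}\t{s.strand}\n"
            )


def read_specs_tsv(path):
    """Read insertion specs (sample_id, chrom, position, strand, tsd_len,
    promoter5, intron_present, copy_count) from a TSV."""
    from .simlib import InsertionSpec

    df = pd.read_csv(path, sep="\t")
    return [
        InsertionSpec(
            sample_id=str(r["sample_id"]),
            chrom=str(r["chrom"]),
            position=int(r["position"]),
            strand=str(r["strand"]),
            tsd_len=int(r["tsd_len"]),
            promoter5=str(r["promoter5"]),
            intron_present=bool(r["intron_present"]),
            copy_count=int(r["copy_count"]),
        )
        for r in df.to_dict("records")
    ]
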