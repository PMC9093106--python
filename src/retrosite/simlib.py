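"""Toy genomes, provirus planting, and LM-PCR library simulation.

The simulator emulates a ligation-mediated PCR (LM-PCR) junction library for
an LTR retroelement such as HERV-K. Genomic DNA carrying planted proviruses
is sheared, linker-ligated, and amplified with one primer in the 3' LTR and
one in the linker; read 1 therefore starts inside the 3' LTR, runs through
the LTR's terminal hexamer (CCTACA or CCTTCA), and continues into host DNA,
while read 2 enters from the linker-proximal shear end. An 8-bp index read
carries the sample barcode.

Integration biology modelled here:

* integrase duplicates the ``tsd_len`` host bases at the integration point,
  so the target-site duplication (TSD, 5-6 bp for HERV-K) flanks the provirus
  on both sides;
* reverse transcription regenerates U3 at the 5' LTR, so a retrotransposed
  copy carries a U3 5' junction whereas a plasmid-derived integrant retains
  the CMV promoter (``promoter5`` on :class:`InsertionSpec`);
* a reporter cassette interrupted by an intron is integrated with the intron
  spliced out only if the copy went through an RNA intermediate
  (``intron_present`` False for retrotransposed copies).

Clone abundance follows the distinct-amplicon convention: every genome copy
of a clone shears at one random position, so one clone copy contributes one
fragment length, and the number of *different* lengths at a site estimates
its copy number. ``molecules_per_copy`` controls sequencing oversampling of
that single fragment; PCR duplicates add further identical emissions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .dna import random_dna, revcomp, validate_dna

TERMINAL_HEXAMERS = ("CCTACA", "CCTTCA")

# Surrogate provirus segments. Fixed arbitrary sequences so truth is stable
# across runs; a 300-500 bp surrogate with labelled U3/R/U5 and reporter
# segments stands in for a full-length provirus.
_SEG_RNG = np.random.default_rng(987654321)
U3_TAG = random_dna(_SEG_RNG, 40)
CMV_TAG = random_dna(_SEG_RNG, 40)
R_SEGMENT = random_dna(_SEG_RNG, 20)
U5_BODY = random_dna(_SEG_RNG, 44)
GAGPOL_STUFFER = random_dna(_SEG_RNG, 120)
REPORTER_EXON1 = random_dna(_SEG_RNG, 30)
REPORTER_INTRON = "GT" + random_dna(_SEG_RNG, 36) + "AG"
REPORTER_EXON2 = random_dna(_SEG_RNG, 30)
LINKER_SEQ = random_dna(_SEG_RNG, 25)

PRIMER_3LTR_OUTER = "CCTCCATATGCTGAACGCTGGTT"  # B3-K1
PRIMER_3LTR_INNER = (
    "AATGATACGGCGACCACCGAGATCTACACCCAAATCTCTCGTCCCACCTTACGAGAAACACCCACAGG"
)  # P5B5-K2


def build_provirus(
    promoter5: str = "U3",
    intron_present: bool = True,
    terminal_hexamer: str = "CCTACA",
) -> str:
    """Assemble a surrogate provirus: 5'LTR - stuffer - reporter - 3'LTR.

    The 5' LTR starts with either the U3 tag (retrotransposed state) or the
    CMV tag (plasmid state); both LTRs end in U5 terminated by the given
    hexamer. ``intron_present=False`` yields the spliced reporter.
    """
    if terminal_hexamer not in TERMINAL_HEXAMERS:
        raise ValueError(f"terminal_hexamer must be one of {TERMINAL_HEXAMERS}")
    if promoter5 not in ("U3", "CMV"):
        raise ValueError("promoter5 must be 'U3' or 'CMV'")
    five_tag = U3_TAG if promoter5 == "U3" else CMV_TAG
    ltr_tail = R_SEGMENT + U5_BODY + terminal_hexamer
    reporter = REPORTER_EXON1 + (REPORTER_INTRON if intron_present else "") + REPORTER_EXON2
    return five_tag + ltr_tail + GAGPOL_STUFFER + reporter + U3_TAG + ltr_tail


@dataclass(frozen=True)
class ToyGenome:
    """Named chromosome sequences used as the mapping reference."""

    chromosomes: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        cleaned = {}
        for name, seq in self.chromosomes.items():
            cleaned[name] = validate_dna(seq, what=f"chromosome {name}")
        object.__setattr__(self, "chromosomes", cleaned)

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __iter__(self):
        return iter(self.chromosomes.items())


def make_reference(seed: int, chrom_lengths: Mapping[str, int]) -> ToyGenome:
    """Deterministic uniform-ACGT toy genome; homopolymer runs capped at 30 bp."""
    if not chrom_lengths:
        raise ValueError("chrom_lengths is empty")
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length {length}")
    rng = np.random.default_rng(seed)
    return ToyGenome({name: random_dna(rng, length) for name, length in chrom_lengths.items()})


@dataclass(frozen=True)
class InsertionSpec:
    """One provirus to plant: where, in which orientation, and in what state."""

    sample_id: str
    chrom: str
    position: int  # 0-based host offset of the integration point
    strand: str
    tsd_len: int = 6
    promoter5: str = "U3"
    intron_present: bool = False
    copy_count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")
        if self.promoter5 not in ("U3", "CMV"):
            raise ValueError("promoter5 must be 'U3' or 'CMV'")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth for one planted provirus.

    ``junction_pos_1based`` is the reported coordinate contract: the 1-based
    reference coordinate of the first host base 3' of the LTR terminus, read
    in the provirus orientation. ``shear_lengths`` holds one entry per
    sequenced molecule (pre-duplication).
    """

    sample_id: str
    chrom: str
    position: int
    strand: str
    tsd_len: int
    promoter5: str
    intron_present: bool
    copy_count: int
    junction_pos_1based: int
    shear_lengths: list[int] = field(default_factory=list)

    @classmethod
    def from_spec(cls, spec: InsertionSpec) -> "TruthRecord":
        j = spec.position + 1 if spec.strand == "+" else spec.position + spec.tsd_len
        return cls(
            sample_id=spec.sample_id,
            chrom=spec.chrom,
            position=spec.position,
            strand=spec.strand,
            tsd_len=spec.tsd_len,
            promoter5=spec.promoter5,
            intron_present=spec.intron_present,
            copy_count=spec.copy_count,
            junction_pos_1based=j,
        )


def plant_insertion(
    genome: ToyGenome, spec: InsertionSpec, provirus_seq: str
) -> tuple[str, TruthRecord]:
    """Insert a provirus with an integrase-style target-site duplication.

    Returns the modified chromosome sequence and the truth record. The
    ``tsd_len`` host bases at the integration point appear once on each side
    of the provirus; strand '-' inserts the reverse complement.
    """
    provirus_seq = validate_dna(provirus_seq, what="provirus")
    if not any(provirus_seq.endswith(h) for h in TERMINAL_HEXAMERS):
        raise ValueError(
            f"provirus must end in one of {TERMINAL_HEXAMERS} (the 3' LTR terminus)"
        )
    host = genome[spec.chrom]
    p, t = spec.position, spec.tsd_len
    if p + t > len(host):
        raise ValueError(
            f"position {p} + tsd_len {t} exceeds chromosome {spec.chrom} "
            f"length {len(host)}"
        )
    oriented = provirus_seq if spec.strand == "+" else revcomp(provirus_seq)
    planted = host[: p + t] + oriented + host[p:]
    return planted, TruthRecord.from_spec(spec)


@dataclass(frozen=True)
class LibraryParams:
    """Knobs of the simulated LM-PCR library.

    read_len
        Length of R1 and R2 in bp.
    ltr_tail
        The 3'-LTR suffix carried at the start of R1 (its length sets how many
        LTR bases precede the host junction in each read). Reads slice the
        planted provirus itself, so a CCTTCA-terminated copy differs from this
        default in its final hexamer only.
    shear_min / shear_max
        Uniform sonication-fragment range, measured junction to shear end.
    molecules_per_copy
        Sequenced molecules per clone copy; all share that copy's single
        shear length (library oversampling of one fragment).
    subst_error_rate / pcr_dup_rate
        Per-base substitution probability; probability a molecule is emitted
        twice with identical sequence and length.
    index_qual_profile
        Per-position Phred scores of the 8-bp index read, so the >20 gate can
        be exercised position by position.
    """

    read_len: int = 100
    index_len: int = 8
    ltr_tail: str = (U5_BODY + "CCTACA")[-20:]
    linker_seq: str = LINKER_SEQ
    primer_3ltr_outer: str = PRIMER_3LTR_OUTER
    primer_3ltr_inner: str = PRIMER_3LTR_INNER
    subst_error_rate: float = 0.0
    pcr_dup_rate: float = 0.0
    shear_min: int = 150
    shear_max: int = 600
    molecules_per_copy: int = 3
    base_qual: int = 35
    index_qual_profile: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.subst_error_rate <= 1.0:
            raise ValueError("subst_error_rate must be in [0, 1]")
        if not 0.0 <= self.pcr_dup_rate <= 1.0:
            raise ValueError("pcr_dup_rate must be in [0, 1]")
        if self.shear_min > self.shear_max:
            raise ValueError("shear_min must be <= shear_max")
        if self.read_len > self.shear_min:
            raise ValueError(
                f"read_len {self.read_len} exceeds the shortest fragment "
                f"(shear_min {self.shear_min})"
            )
        if self.molecules_per_copy < 1:
            raise ValueError("molecules_per_copy must be >= 1")

    def index_quals(self) -> tuple[int, ...]:
        if self.index_qual_profile is not None:
            if len(self.index_qual_profile) != self.index_len:
                raise ValueError("index_qual_profile length must equal index_len")
            return tuple(self.index_qual_profile)
        return (self.base_qual,) * self.index_len


@dataclass(frozen=True)
class ReadTriple:
    """One sequenced molecule: mate 1, mate 2, and the index read (Phred+33)."""

    read_id: str
    r1_seq: str
    r1_quals: str
    r2_seq: str
    r2_quals: str
    index_seq: str
    index_quals: str

    def __post_init__(self) -> None:
        for seq, quals, what in (
            (self.r1_seq, self.r1_quals, "R1"),
            (self.r2_seq, self.r2_quals, "R2"),
            (self.index_seq, self.index_quals, "index"),
        ):
            if len(seq) != len(quals):
                raise ValueError(f"{what}: sequence and quality lengths differ")


def _phred_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@dataclass
class LibrarySim:
    """A simulated library: reads per sample plus complete ground truth."""

    genome: ToyGenome
    params: LibraryParams
    reads: dict[str, list[ReadTriple]]
    truth: list[TruthRecord]
    planted: dict[str, dict[str, str]]  # sample -> chrom -> planted sequence
    spans: list[tuple[str, int, int]]  # per truth record: (chrom, a, b) in planted coords
    barcodes: dict[str, str]

    def provirus_sequence(self, i: int) -> str:
        """Planted provirus *i* in its own 5'->3' orientation."""
        rec = self.truth[i]
        chrom, a, b = self.spans[i]
        seg = self.planted[rec.sample_id][chrom][a:b]
        return seg if rec.strand == "+" else revcomp(seg)

    def five_prime_host_flank(self, i: int, flank: int = 30) -> str:
        """Host bases immediately 5' of provirus *i*, in provirus orientation.

        This is what Sanger sequencing across the 5' junction would read just
        before the provirus begins; its suffix carries the TSD copy.
        """
        rec = self.truth[i]
        chrom, a, b = self.spans[i]
        seq = self.planted[rec.sample_id][chrom]
        if rec.strand == "+":
            return seq[max(0, a - flank) : a]
        return revcomp(seq[b : b + flank])

    def five_prime_junction_seq(self, i: int, host_flank: int = 40, prov_len: int = 120) -> str:
        """Sequence spanning the 5' host/provirus junction, provirus orientation."""
        rec = self.truth[i]
        chrom, a, b = self.spans[i]
        seq = self.planted[rec.sample_id][chrom]
        if rec.strand == "+":
            return seq[max(0, a - host_flank) : a + prov_len]
        return revcomp(seq[max(0, b - prov_len) : b + host_flank])


def _plant_sample(
    genome: ToyGenome,
    specs: list[InsertionSpec],
    proviruses: list[str],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Plant all of one sample's proviruses; return planted chroms and spans.

    Specs on a chromosome are planted left to right, accumulating the
    coordinate shift each insertion introduces so truth coordinates stay in
    the original reference frame.
    """
    order = sorted(range(len(specs)), key=lambda i: (specs[i].chrom, specs[i].position))
    planted = {name: seq for name, seq in genome}
    shift: dict[str, int] = {}
    last_end: dict[str, int] = {}
    spans: list[tuple[str, int, int] | None] = [None] * len(specs)
    for i in order:
        spec, prov = specs[i], proviruses[i]
        if spec.position < last_end.get(spec.chrom, 0):
            raise ValueError(
                f"insertions overlap on {spec.chrom} near position {spec.position}"
            )
        sub = ToyGenome({spec.chrom: planted[spec.chrom]})
        shifted = dataclasses.replace(
            spec, position=spec.position + shift.get(spec.chrom, 0)
        )
        planted[spec.chrom], _ = plant_insertion(sub, shifted, prov)
        a = shifted.position + spec.tsd_len
        spans[i] = (spec.chrom, a, a + len(prov))
        shift[spec.chrom] = shift.get(spec.chrom, 0) + spec.tsd_len + len(prov)
        last_end[spec.chrom] = spec.position + spec.tsd_len
    return planted, spans  # type: ignore[return-value]


def simulate_library(
    genome: ToyGenome,
    specs: list[InsertionSpec],
    params: LibraryParams,
) -> LibrarySim:
    """Simulate R1/R2/index reads for every sample's planted insertions.

    Per clone copy one shear length is drawn uniformly from
    ``[shear_min, shear_max]``; the fragment runs from the 3'-LTR junction
    into host DNA for that many bases. R1 = LTR tail + host flank, R2 =
    reverse complement of the linker-proximal fragment end, both truncated to
    ``read_len``. Determinism: one master seed, per-sample streams spawned in
    sorted sample order.
    """
    samples = sorted({s.sample_id for s in specs})
    if not samples:
        raise ValueError("no insertion specs given")
    tail_len = len(params.ltr_tail)
    if tail_len >= params.read_len:
        raise ValueError("ltr_tail must be shorter than read_len")

    master = np.random.SeedSequence(params.seed)
    sample_seeds = dict(zip(samples, master.spawn(len(samples) + 1)))
    bc_rng = np.random.default_rng(master.spawn(1)[0])
    barcodes = {s: random_dna(bc_rng, params.index_len) for s in samples}

    reads: dict[str, list[ReadTriple]] = {s: [] for s in samples}
    truth: list[TruthRecord] = [TruthRecord.from_spec(s) for s in specs]
    planted_all: dict[str, dict[str, str]] = {}
    spans_all: list[tuple[str, int, int]] = [None] * len(specs)  # type: ignore[list-item]
    iq = _phred_string(params.index_quals())
    rq = _phred_string((params.base_qual,) * params.read_len)

    for sample in samples:
        rng = np.random.default_rng(sample_seeds[sample])
        idx = [i for i, s in enumerate(specs) if s.sample_id == sample]
        provs = [
            build_provirus(
                specs[i].promoter5,
                specs[i].intron_present,
                str(rng.choice(TERMINAL_HEXAMERS)),
            )
            for i in idx
        ]
        planted, spans = _plant_sample(genome, [specs[i] for i in idx], provs)
        planted_all[sample] = planted
        for local, i in enumerate(idx):
            spans_all[i] = spans[local]

        for local, i in enumerate(idx):
            spec = specs[i]
            chrom, a, b = spans[local]
            seq = planted[chrom]
            for copy in range(spec.copy_count):
                shear = int(rng.integers(params.shear_min, params.shear_max + 1))
                if spec.strand == "+":
                    if b + shear > len(seq):
                        raise ValueError(
                            f"fragment of {shear} bp runs off {chrom} for the "
                            f"insertion at {spec.position}"
                        )
                    frag = seq[b - tail_len : b + shear]
                else:
                    if a - shear < 0:
                        raise ValueError(
                            f"fragment of {shear} bp runs off {chrom} for the "
                            f"insertion at {spec.position}"
                        )
                    frag = revcomp(seq[a - shear : a + tail_len])
                r1 = frag[: params.read_len]
                r2 = revcomp(frag)[: params.read_len]
                for mol in range(params.molecules_per_copy):
                    truth[i].shear_lengths.append(shear)
                    r1e = _apply_substitutions(r1, params.subst_error_rate, rng)
                    r2e = _apply_substitutions(r2, params.subst_error_rate, rng)
                    rid = f"{sample}|ins{i}|c{copy}|m{mol}"
                    triple = ReadTriple(rid, r1e, rq, r2e, rq, barcodes[sample], iq)
                    reads[sample].append(triple)
                    if rng.random() < params.pcr_dup_rate:
                        reads[sample].append(dataclasses.replace(triple, read_id=rid + "|dup"))
    return LibrarySim(
        genome=genome,
        params=params,
        reads=reads,
        truth=truth,
        planted=planted_all,
        spans=spans_all,
        barcodes=barcodes,
    )
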