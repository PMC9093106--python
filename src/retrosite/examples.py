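"""Canned synthetic study designs for validation and demonstration.

:func:`study_cohort` reproduces, at desk scale, the design of a three-sample
integration-site comparison: a control sample (standing in for the database
or parental genome), plus two derived samples sharing some nonreference
insertions and carrying sample-specific ones. Insertions cover both strands,
TSDs of 5 and 6 bp, U3- and CMV-type 5' junctions, and reporter proviruses
with and without the intron. With the default depth the library holds on the
order of 10,000 read triples across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simlib import InsertionSpec, LibraryParams, LibrarySim, ToyGenome, make_reference, simulate_library

from .pipeline import PipelineConfig

CONTROL = "ctrl"
SAMPLE_B = "lineB"
SAMPLE_C = "lineC"

GROUPS = {"reference": [CONTROL], "lineB": [SAMPLE_B], "lineC": [SAMPLE_C]}
REFERENCE_GROUP = "reference"

from .junction import LtrMotifSet
from .simlib import U5_BODY

# Analysis configuration: the assay's LTR is a known sequence, so trimming
# validates the bases 5' of the terminal hexamer against the U5 body; and at
# this depth (~120 reads per molecule) a junction supported by fewer than 5
# reads is a trimming/PCR artifact, not a clone.
STUDY_PIPELINE = PipelineConfig(
    motifs=LtrMotifSet(ltr_context=U5_BODY), min_reads=5
)

# locus table: (chrom, position, strand, tsd_len, promoter5, intron_present,
#               samples carrying it, copy_count per sample)
_LOCI = [
    ("chr1", 4000, "+", 6, "U3", False, (CONTROL, SAMPLE_B, SAMPLE_C), 2),
    ("chr1", 9000, "-", 5, "U3", False, (CONTROL, SAMPLE_B, SAMPLE_C), 3),
    ("chr1", 14000, "+", 5, "U3", False, (CONTROL, SAMPLE_B, SAMPLE_C), 1),
    ("chr2", 4000, "-", 6, "U3", False, (CONTROL, SAMPLE_B, SAMPLE_C), 2),
    ("chr2", 9000, "+", 6, "U3", False, (CONTROL, SAMPLE_B, SAMPLE_C), 4),
    ("chr1", 19000, "+", 6, "U3", False, (SAMPLE_B, SAMPLE_C), 3),
    ("chr1", 24000, "-", 5, "U3", False, (SAMPLE_B, SAMPLE_C), 2),
    ("chr2", 14000, "+", 5, "U3", False, (SAMPLE_B, SAMPLE_C), 4),
    ("chr2", 19000, "-", 6, "U3", False, (SAMPLE_B, SAMPLE_C), 2),
    ("chr1", 29000, "+", 6, "CMV", True, (SAMPLE_B,), 3),
    ("chr1", 34000, "-", 5, "U3", False, (SAMPLE_B,), 5),
    ("chr2", 24000, "+", 6, "U3", False, (SAMPLE_B,), 2),
    ("chr1", 39000, "-", 6, "U3", False, (SAMPLE_C,), 3),
    ("chr2", 29000, "+", 5, "CMV", True, (SAMPLE_C,), 2),
    ("chr2", 34000, "-", 6, "U3", False, (SAMPLE_C,), 4),
]

CHROM_LENGTHS = {"chr1": 45000, "chr2": 40000}


@dataclass
class StudyCohort:
    genome: ToyGenome
    specs: list[InsertionSpec]
    params: LibraryParams
    sim: LibrarySim

    @property
    def truth_loci(self) -> dict[tuple[str, int, str], dict]:
        """Planted loci keyed by (chrom, junction_pos_1based, strand)."""
        out: dict[tuple[str, int, str], dict] = {}
        for chrom, pos, strand, tsd, prom, intron, samples, cc in _LOCI:
            j = pos + 1 if strand == "+" else pos + tsd
            out[(chrom, j, strand)] = {
                "tsd_len": tsd,
                "promoter5": prom,
                "intron_present": intron,
                "samples": set(samples),
                "copy_count": cc,
            }
        return out


def study_specs() -> list[InsertionSpec]:
    specs = []
    for chrom, pos, strand, tsd, prom, intron, samples, cc in _LOCI:
        for sample in samples:
            specs.append(
                InsertionSpec(
                    sample_id=sample,
                    chrom=chrom,
                    position=pos,
                    strand=strand,
                    tsd_len=tsd,
                    promoter5=prom,
                    intron_present=intron,
                    copy_count=cc,
                )
            )
    return specs


def study_cohort(
    seed: int = 0,
    subst_error_rate: float = 0.0,
    molecules_per_copy: int = 120,
    pcr_dup_rate: float = 0.05,
) -> StudyCohort:
    """Build the three-sample study cohort and simulate its LM-PCR library.

    Defaults give roughly 10,000 read triples over 29 planted insertion
    events at 15 distinct loci (5 reference, 4 shared nonreference, 3+3
    sample-specific). ``subst_error_rate`` of 0 and 0.002 are the two
    standard validation conditions.
    """
    genome = make_reference(seed, CHROM_LENGTHS)
    specs = study_specs()
    params = LibraryParams(
        seed=seed,
        subst_error_rate=subst_error_rate,
        pcr_dup_rate=pcr_dup_rate,
        molecules_per_copy=molecules_per_copy,
    )
    sim = simulate_library(genome, specs, params)
    return StudyCohort(genome=genome, specs=specs, params=params, sim=sim)
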