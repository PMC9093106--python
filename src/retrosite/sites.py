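"""Integration-site calling and retrotransposition hallmark checks.

A site is a cluster of molecules sharing a 3'-LTR/host junction. Hallmarks
verified here: the 5-6 bp target-site duplication (TSD) that integrase
leaves on both flanks; a U3 (rather than plasmid CMV) sequence at the 5' LTR
junction, evidencing reverse transcription; removal of the reporter intron;
and junction integrity, a modal-support proxy for excluding junctions whose
reads disagree (indel-suspect sites).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import simlib
from .dna import revcomp, validate_dna
from .mapper import Molecule
from .simlib import ToyGenome

logger = logging.getLogger(__name__)

FLAG_INDEL_SUSPECT = "indel_suspect"
FLAG_NONUNIQUE_FLANK = "nonunique_flank"


@dataclass
class IntegrationSite:
    """A called junction with its molecule support and QC annotations."""

    chrom: str
    junction_pos_1based: int
    strand: str
    n_molecules: int
    n_reads: int
    modal_support_fraction: float
    flags: set[str] = field(default_factory=set)
    tsd_len: Optional[int] = None
    promoter5_call: Optional[str] = None
    sample_id: Optional[str] = None
    copy_number: Optional[int] = None
    molecules: list[Molecule] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.junction_pos_1based, self.strand)


def call_sites(
    molecules: Iterable[Molecule],
    cluster_window: int = 5,
    min_molecules: int = 1,
    min_reads: int = 1,
) -> list[IntegrationSite]:
    """Cluster molecules into sites at the modal junction position.

    Molecules on the same chromosome and strand whose junctions are within
    ``cluster_window`` of a neighbour (single linkage) form one site, placed
    at the read-weighted modal junction (ties resolved to the smallest
    coordinate). ``modal_support_fraction`` is the fraction of the site's
    reads at that modal position. Sites with fewer than ``min_molecules``
    molecules or fewer than ``min_reads`` supporting reads are dropped:
    at deep sequencing coverage a junction seen in only a handful of reads
    is a trimming or PCR artifact, not a clone.
    """
    by_group: dict[tuple[str, str], list[Molecule]] = defaultdict(list)
    for m in molecules:
        by_group[(m.chrom, m.strand)].append(m)
    sites: list[IntegrationSite] = []
    for (chrom, strand), mols in by_group.items():
        mols.sort(key=lambda m: (m.junction_pos_1based, m.fragment_length))
        cluster: list[Molecule] = []
        for m in mols:
            if cluster and m.junction_pos_1based - cluster[-1].junction_pos_1based > cluster_window:
                sites.append(_finish_cluster(chrom, strand, cluster))
                cluster = []
            cluster.append(m)
        if cluster:
            sites.append(_finish_cluster(chrom, strand, cluster))
    sites = [s for s in sites if s.n_molecules >= min_molecules and s.n_reads >= min_reads]
    sites.sort(key=lambda s: (s.chrom, s.junction_pos_1based, s.strand))
    return sites


def _finish_cluster(chrom: str, strand: str, mols: list[Molecule]) -> IntegrationSite:
    read_votes: Counter = Counter()
    for m in mols:
        read_votes[m.junction_pos_1based] += m.n_reads
    n_reads = sum(read_votes.values())
    top = max(read_votes.values())
    modal = min(pos for pos, n in read_votes.items() if n == top)
    return IntegrationSite(
        chrom=chrom,
        junction_pos_1based=modal,
        strand=strand,
        n_molecules=len(mols),
        n_reads=n_reads,
        modal_support_fraction=top / n_reads,
        molecules=list(mols),
    )


def tsd_length(upstream_flank: str, downstream_flank: str, max_len: int = 10) -> int:
    """Length of the target-site duplication shared by the two flanks.

    ``upstream_flank`` is host sequence immediately 5' of the provirus (its
    suffix abuts the provirus); ``downstream_flank`` is host immediately 3'
    (its prefix abuts it). Returns the largest L <= max_len with
    suffix(upstream, L) == prefix(downstream, L), or 0.
    """
    limit = min(max_len, len(upstream_flank), len(downstream_flank))
    if limit < max_len:
        logger.warning(
            "flank shorter than max_len=%d; comparing over %d bases", max_len, limit
        )
    for L in range(limit, 0, -1):
        if upstream_flank[-L:] == downstream_flank[:L]:
            return L
    return 0


@dataclass(frozen=True)
class PromoterRefs:
    """Diagnostic tags distinguishing a U3 5' LTR from a plasmid CMV one."""

    u3_tag: str = simlib.U3_TAG
    cmv_tag: str = simlib.CMV_TAG
    min_match: int = 10

    def __post_init__(self) -> None:
        validate_dna(self.u3_tag, what="u3_tag")
        validate_dna(self.cmv_tag, what="cmv_tag")
        n = min(len(self.u3_tag), len(self.cmv_tag))
        dist = sum(a != b for a, b in zip(self.u3_tag[:n], self.cmv_tag[:n]))
        if dist < self.min_match:
            raise ValueError(
                "u3_tag and cmv_tag are not distinguishable "
                f"(prefix Hamming distance {dist} < {self.min_match})"
            )


def promoter5_check(five_prime_junction_seq: str, refs: PromoterRefs = PromoterRefs()) -> str:
    """Classify the 5' LTR of an integrant as U3, CMV, or ambiguous.

    Reverse transcription regenerates U3 at the 5' end, so a U3 junction
    evidences retrotransposition while CMV marks a plasmid-derived
    integrant. Exact substring matching; both-or-neither gives ambiguous.
    """
    has_u3 = refs.u3_tag in five_prime_junction_seq
    has_cmv = refs.cmv_tag in five_prime_junction_seq
    if has_u3 and not has_cmv:
        return "U3"
    if has_cmv and not has_u3:
        return "CMV"
    return "ambiguous"


def intron_removed(
    provirus_seq: str,
    intron_seq: str = simlib.REPORTER_INTRON,
    exons: tuple[str, str] = (simlib.REPORTER_EXON1, simlib.REPORTER_EXON2),
) -> bool:
    """True iff the reporter intron is absent while both exon segments remain.

    An integrated copy that went through transcription and splicing has lost
    the intron; a directly integrated plasmid copy retains it. Raises if the
    exon segments are missing (not a reporter provirus).
    """
    for i, exon in enumerate(exons, start=1):
        if exon not in provirus_seq:
            raise ValueError(f"reporter exon {i} not found: not a reporter provirus")
    return intron_seq not in provirus_seq


def junction_integrity(site: IntegrationSite, min_modal_fraction: float = 0.8) -> bool:
    """Pass iff the modal junction carries >= ``min_modal_fraction`` of reads.

    A failing site gets the ``indel_suspect`` flag (reads disagreeing on the
    junction suggest indels at it) and is retained but excluded from
    downstream classification.
    """
    ok = site.modal_support_fraction >= min_modal_fraction
    if not ok:
        site.flags.add(FLAG_INDEL_SUSPECT)
    return ok


def apparent_tsd(
    genome: ToyGenome, chrom: str, position: int, tsd_len: int, flank: int = 12
) -> int:
    """The duplication length observable at a planted integration point.

    Integrase duplicating ``tsd_len`` bases inside host sequence that repeats
    itself (e.g. a homopolymer) yields flanks sharing more than ``tsd_len``
    terminal bases; the longer duplication is genuinely present and the
    planted length is not recoverable from sequence. This computes the
    expected :func:`tsd_length` result from the pre-insertion host alone;
    it equals ``tsd_len`` at every unambiguous locus.
    """
    host = genome[chrom]
    p, t = position, tsd_len
    return tsd_length(host[max(0, p + t - flank) : p + t], host[p : p + flank])


def reference_downstream_flank(
    genome: ToyGenome, chrom: str, junction_pos_1based: int, strand: str, flank: int = 10
) -> str:
    """Host bases 3' of the LTR terminus at a called junction, provirus frame.

    For a plus-strand site this is the forward reference starting at the
    junction; for a minus-strand site, the reverse complement ending at it.
    Paired with a 5'-junction host flank it feeds :func:`tsd_length`.
    """
    seq = genome[chrom]
    j = junction_pos_1based
    if strand == "+":
        return seq[j - 1 : j - 1 + flank]
    return revcomp(seq[max(0, j - flank) : j])
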