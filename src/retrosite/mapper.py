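"""Ungapped k-mer-seeded read mapping with a unique-best contract, plus
molecule deduplication.

The mapper replaces an external aligner with a small auditable one: it seeds
on the first k-mer of the read (and of its reverse complement), extends
without gaps counting mismatches, and reports ``unique`` only when exactly
one placement attains the minimal mismatch count. The simulator introduces
substitutions only, so ungapped extension is sufficient. Duplicate removal
collapses reads sharing (chrom, junction, strand, fragment length) into one
molecule — the distinct-length fragment being the abundance unit downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .dna import revcomp
from .simlib import ToyGenome

UNIQUE = "unique"
MULTI = "multi"
UNMAPPED = "unmapped"


@dataclass
class KmerIndex:
    """Exact k-mer -> (chrom, offset, strand) lookup over both strands.

    A ``-`` entry under k-mer *w* means *w* equals the reverse complement of
    the forward genome k-mer at that offset, i.e. a read starting with *w*
    may align reverse-complemented with its first base at offset+k-1.
    """

    k: int
    genome: ToyGenome
    positions: dict[str, list[tuple[str, int, str]]]


def build_index(genome: ToyGenome, k: int = 15) -> KmerIndex:
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    shortest = min(len(seq) for _, seq in genome)
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest chromosome ({shortest} bp)")
    positions: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for chrom, seq in genome:
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            positions[kmer].append((chrom, off, "+"))
            positions[revcomp(kmer)].append((chrom, off, "-"))
    return KmerIndex(k=k, genome=genome, positions=dict(positions))


@dataclass
class Alignment:
    read_id: str
    chrom: str | None
    start: int | None  # 0-based leftmost reference coordinate
    strand: str | None
    mismatches: int | None
    uniqueness: str


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance, short-circuiting once past *limit*."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def map_read(
    index: KmerIndex,
    host_seq: str,
    max_mismatch: int = 2,
    read_id: str = "",
) -> Alignment:
    """Seed on the read's first k-mer, extend ungapped, demand a unique best.

    Candidates are every indexed placement of the seed; a candidate survives
    if the full-length ungapped comparison has at most ``max_mismatch``
    mismatches. ``unique`` requires exactly one survivor at the minimal
    mismatch count; ties give ``multi``; no survivor (or a read shorter than
    k) gives ``unmapped``. Candidate order, and hence tie-breaking, is by
    (chrom, start, strand).
    """
    k, L = index.k, len(host_seq)
    if L < k:
        return Alignment(read_id, None, None, None, None, UNMAPPED)
    placements: list[tuple[str, int, str, int]] = []
    seen: set[tuple[str, int, str]] = set()
    for chrom, off, strand in index.positions.get(host_seq[:k], ()):
        seq = index.genome[chrom]
        if strand == "+":
            start = off
            if start + L > len(seq):
                continue
            ref = seq[start : start + L]
        else:
            start = off + k - L
            if start < 0:
                continue
            ref = revcomp(seq[start : start + L])
        key = (chrom, start, strand)
        if key in seen:
            continue
        seen.add(key)
        mm = _mismatches(host_seq, ref, max_mismatch)
        if mm <= max_mismatch:
            placements.append((chrom, start, strand, mm))
    if not placements:
        return Alignment(read_id, None, None, None, None, UNMAPPED)
    placements.sort(key=lambda p: (p[0], p[1], p[2]))
    best = min(p[3] for p in placements)
    winners = [p for p in placements if p[3] == best]
    chrom, start, strand, mm = winners[0]
    status = UNIQUE if len(winners) == 1 else MULTI
    return Alignment(read_id, chrom, start, strand, mm, status)


def junction_position(aln: Alignment, read_len: int) -> int:
    """1-based junction coordinate implied by an alignment of a trimmed read.

    A plus-strand provirus read maps forward starting at the junction; a
    minus-strand read maps reverse-complemented ending at it.
    """
    if aln.strand == "+":
        return aln.start + 1
    return aln.start + read_len


@dataclass(frozen=True)
class ReadPlacement:
    """One uniquely mapped read reduced to its molecule coordinates."""

    read_id: str
    chrom: str
    junction_pos_1based: int
    strand: str
    fragment_length: int


@dataclass
class Molecule:
    """A distinct sequenced fragment: one junction plus one shear length."""

    chrom: str
    junction_pos_1based: int
    strand: str
    fragment_length: int
    read_ids: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def deduplicate(placements: Iterable[ReadPlacement]) -> list[Molecule]:
    """Collapse reads sharing (chrom, junction, strand, fragment_length).

    Reads from the same sonication fragment — PCR or optical duplicates —
    agree on all four coordinates and become one molecule. Output is sorted
    by (chrom, junction, strand, fragment_length); the operation is
    idempotent.
    """
    groups: dict[tuple[str, int, str, int], Molecule] = {}
    for p in placements:
        key = (p.chrom, p.junction_pos_1based, p.strand, p.fragment_length)
        mol = groups.get(key)
        if mol is None:
            groups[key] = Molecule(*key, read_ids=[p.read_id])
        else:
            mol.read_ids.append(p.read_id)
    return [groups[k] for k in sorted(groups)]
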