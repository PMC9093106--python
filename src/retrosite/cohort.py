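"""Cross-sample comparison of integration-site sets.

Sites called per sample are merged into loci, tabulated as a loci x samples
presence/abundance matrix, and classified against a designated reference
group: a locus seen in the reference samples is a *reference* insertion
(present in the control genome); one absent there but shared by every focal
sample is *nonreference universal*; one confined to a single focal group is
*nonreference specific* to it. Loci failing junction-integrity or
flank-uniqueness checks are excluded before classification, and called loci
can be matched against a list of known polymorphic insertions (e.g. K113,
K20, K22) by coordinate or cytoband.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dna import find_all, revcomp
from .sites import IntegrationSite
from .simlib import ToyGenome

logger = logging.getLogger(__name__)

REFERENCE = "reference"
NONREF_UNIVERSAL = "nonreference_universal"
NONREF_SPECIFIC = "nonreference_specific"
NONREF_PARTIAL = "nonreference_partial"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class Locus:
    """A merged integration locus shared across samples."""

    key: str
    chrom: str
    pos: int  # 1-based junction coordinate (minimum member coordinate)
    strand: Optional[str] = None
    cytoband: Optional[str] = None


@dataclass
class SiteMatrix:
    """Loci x samples table: presence plus copy numbers."""

    loci: list[Locus]
    presence: pd.DataFrame  # bool, index=locus key, columns=samples
    copies: pd.DataFrame  # int, same shape

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    def locus(self, key: str) -> Locus:
        return next(l for l in self.loci if l.key == key)


def build_matrix(
    per_sample_sites: Mapping[str, Sequence[IntegrationSite]],
    merge_window: int = 10,
) -> SiteMatrix:
    """Merge per-sample sites into loci and tabulate presence and copies.

    Junctions on the same chromosome and strand within ``merge_window`` of a
    neighbour (single linkage) become one locus whose coordinate is the
    minimum member coordinate. Each input site lands in exactly one locus.
    """
    samples = sorted(per_sample_sites)
    entries: list[tuple[str, str, int, str, int]] = []  # chrom, strand, pos, sample, copies
    for sample in samples:
        for s in per_sample_sites[sample]:
            cn = s.copy_number if s.copy_number is not None else s.n_molecules
            entries.append((s.chrom, s.strand, s.junction_pos_1based, sample, cn))
    loci: list[Locus] = []
    presence_rows: dict[str, dict[str, bool]] = {}
    copy_rows: dict[str, dict[str, int]] = {}
    entries.sort()
    i = 0
    while i < len(entries):
        chrom, strand, pos, _, _ = entries[i]
        j = i + 1
        while (
            j < len(entries)
            and entries[j][0] == chrom
            and entries[j][1] == strand
            and entries[j][2] - entries[j - 1][2] <= merge_window
        ):
            j += 1
        members = entries[i:j]
        locus = Locus(
            key=f"{chrom}:{pos}:{strand}", chrom=chrom, pos=pos, strand=strand
        )
        loci.append(locus)
        presence_rows[locus.key] = {s: False for s in samples}
        copy_rows[locus.key] = {s: 0 for s in samples}
        for _, _, _, sample, cn in members:
            presence_rows[locus.key][sample] = True
            copy_rows[locus.key][sample] += cn
        i = j
    loci.sort(key=lambda l: (l.chrom, l.pos))
    index = [l.key for l in loci]
    presence = pd.DataFrame.from_dict(presence_rows, orient="index").reindex(
        index=index, columns=samples
    ).fillna(False).astype(bool)
    copies = pd.DataFrame.from_dict(copy_rows, orient="index").reindex(
        index=index, columns=samples
    ).fillna(0).astype(int)
    return SiteMatrix(loci=loci, presence=presence, copies=copies)


def matrix_from_presence(df: pd.DataFrame, sample_columns: Sequence[str]) -> SiteMatrix:
    """Build a SiteMatrix from an already-tabulated presence/absence table.

    ``df`` needs columns ``locus`` (cytoband label), ``chrom``, ``pos`` and
    one 0/1 column per sample. Used for encoded published tables, where
    merging has already happened.
    """
    loci = [
        Locus(
            key=f"{r.chrom}:{int(r.pos)}",
            chrom=str(r.chrom),
            pos=int(r.pos),
            cytoband=str(r.locus),
        )
        for r in df.itertuples()
    ]
    index = [l.key for l in loci]
    presence = pd.DataFrame(
        df[list(sample_columns)].astype(bool).values, index=index, columns=list(sample_columns)
    )
    copies = presence.astype(int)
    return SiteMatrix(loci=loci, presence=presence, copies=copies)


def load_presence_tsv(path) -> SiteMatrix:
    """Read a presence table TSV (locus, chrom, pos, then sample columns)."""
    df = pd.read_csv(path, sep="\t")
    sample_cols = [c for c in df.columns if c not in ("locus", "chrom", "pos")]
    return matrix_from_presence(df, sample_cols)


@dataclass
class LocusCall:
    category: str
    witness: Optional[str] = None  # group witnessing a specific/universal call
    reason: Optional[str] = None  # exclusion reason


@dataclass
class SiteClassification:
    """Total assignment of every locus to one category."""

    calls: dict[str, LocusCall]

    def __getitem__(self, key: str) -> LocusCall:
        return self.calls[key]

    def items(self):
        return self.calls.items()

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for call in self.calls.values():
            out[call.category] = out.get(call.category, 0) + 1
        return out


def classify(
    matrix: SiteMatrix,
    groups: Mapping[str, Sequence[str]],
    reference_group: str,
    excluded: Optional[Mapping[str, str]] = None,
) -> SiteClassification:
    """Partition loci into reference / nonreference classes.

    reference
        Present in any sample of ``reference_group`` (i.e. in the control
        genome).
    nonreference_universal
        Absent from the reference group, present in every focal sample.
    nonreference_specific
        Absent from the reference group and from every focal group except
        one, and present in all samples of that group (the witness).
    nonreference_partial
        Any remaining nonreference presence pattern (e.g. some but not all
        samples of a group) — detection too inconsistent to call either way.
    excluded
        Listed in ``excluded`` (locus key -> reason, e.g. indel_suspect or
        nonunique_flank); removed before the universal/specific census.
    """
    if reference_group not in groups:
        raise ValueError(f"reference_group {reference_group!r} not in groups")
    excluded = dict(excluded or {})
    ref_samples = set(groups[reference_group])
    focal_groups = {g: set(ss) for g, ss in groups.items() if g != reference_group}
    focal_samples = set().union(*focal_groups.values()) if focal_groups else set()
    known_samples = ref_samples | focal_samples
    missing = set(matrix.samples) - known_samples
    if missing:
        raise ValueError(f"samples not assigned to any group: {sorted(missing)}")

    calls: dict[str, LocusCall] = {}
    for locus in matrix.loci:
        present = {s for s in matrix.samples if matrix.presence.at[locus.key, s]}
        if not present:
            raise ValueError(f"locus {locus.key} present in no sample")
        if locus.key in excluded:
            calls[locus.key] = LocusCall(EXCLUDED, reason=excluded[locus.key])
        elif present & ref_samples:
            calls[locus.key] = LocusCall(REFERENCE, witness=reference_group)
        elif focal_samples and focal_samples <= present:
            calls[locus.key] = LocusCall(NONREF_UNIVERSAL)
        else:
            hit_groups = [g for g, ss in focal_groups.items() if present & ss]
            if len(hit_groups) == 1 and focal_groups[hit_groups[0]] <= present:
                calls[locus.key] = LocusCall(NONREF_SPECIFIC, witness=hit_groups[0])
            else:
                calls[locus.key] = LocusCall(
                    NONREF_PARTIAL, witness=",".join(sorted(hit_groups))
                )
    return SiteClassification(calls)


def count_category(
    classification: SiteClassification,
    predicate: Callable[[str, LocusCall], bool],
) -> int:
    """Count loci whose (key, call) satisfies the predicate."""
    return sum(1 for key, call in classification.items() if predicate(key, call))


def uniqueness_filter(
    genome: ToyGenome,
    chrom: str,
    junction_pos_1based: int,
    strand: str = "+",
    flank_len: int = 50,
) -> bool:
    """Pass iff the junction flank occurs exactly once in the genome.

    Extracts the ``flank_len`` host bases 3' of the LTR terminus (the bases
    junction reads contain) and exact-searches both strands of every
    chromosome. Multiple hits — or zero, as for a flank that does not match
    the reference at 100% identity — fail.
    """
    seq = genome[chrom]
    j = junction_pos_1based
    if strand == "+":
        flank = seq[j - 1 : j - 1 + flank_len]
    else:
        flank = revcomp(seq[max(0, j - flank_len) : j])
    if len(flank) < flank_len:
        logger.warning(
            "flank at %s:%d truncated to %d bp by the chromosome end",
            chrom, j, len(flank),
        )
    if not flank:
        return False
    hits = 0
    for _, cseq in genome:
        hits += len(find_all(cseq, flank))
        rc = revcomp(flank)
        if rc != flank:
            hits += len(find_all(cseq, rc))
        if hits > 1:
            return False
    return hits == 1


@dataclass(frozen=True)
class KnownInsertion:
    name: str
    cytoband: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None


@dataclass
class KnownInsertionList:
    entries: list[KnownInsertion]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("known-insertion names must be unique")

    @classmethod
    def from_tsv(cls, path) -> "KnownInsertionList":
        df = pd.read_csv(path, sep="\t")
        entries = []
        for row in df.to_dict("records"):
            chrom, pos = row.get("chrom"), row.get("pos")
            cyto = row.get("cytoband")
            entries.append(
                KnownInsertion(
                    name=str(row["name"]),
                    cytoband=None if pd.isna(cyto) else str(cyto),
                    chrom=None if chrom is None or pd.isna(chrom) else str(chrom),
                    pos=None if pos is None or pd.isna(pos) else int(pos),
                )
            )
        return cls(entries)


def match_known(
    loci: Iterable[Locus],
    known: KnownInsertionList,
    window: int = 100,
) -> list[tuple[Locus, KnownInsertion]]:
    """Match loci against known polymorphic insertions.

    A locus matches an entry with coordinates if it lies within ``window`` bp
    on the same chromosome; an entry without coordinates matches on equal
    cytoband labels.
    """
    matches: list[tuple[Locus, KnownInsertion]] = []
    for locus in loci:
        for entry in known.entries:
            if entry.chrom is not None and entry.pos is not None:
                if locus.chrom == entry.chrom and abs(locus.pos - entry.pos) <= window:
                    matches.append((locus, entry))
            elif entry.cytoband is not None and locus.cytoband is not None:
                if locus.cytoband == entry.cytoband:
                    matches.append((locus, entry))
    return matches


def per_chromosome_counts(
    matrix: SiteMatrix, classification: SiteClassification
) -> pd.DataFrame:
    """Loci per chromosome per category (Circos-style count table)."""
    rows = []
    for locus in matrix.loci:
        rows.append({"chrom": locus.chrom, "category": classification[locus.key].category})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    return df.groupby(["chrom", "category"]).size().unstack(fill_value=0)
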