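"""End-to-end orchestration: read triples -> junction reads -> molecules ->
sites -> cross-sample classification.

Fragment length (the abundance unit) is recovered from the mate: R2 enters
from the linker-proximal shear end, so a concordant R1/R2 pair brackets the
fragment and its length is the distance from the junction to the far end of
the R2 alignment.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import clonality
from .cohort import (
    KnownInsertionList,
    SiteClassification,
    SiteMatrix,
    build_matrix,
    classify,
    match_known,
    uniqueness_filter,
)
from .junction import LtrMotifSet, index_quality_filter, select_and_trim
from .mapper import (
    UNIQUE,
    KmerIndex,
    ReadPlacement,
    build_index,
    deduplicate,
    junction_position,
    map_read,
)
from .simlib import ReadTriple, ToyGenome
from .sites import (
    FLAG_NONUNIQUE_FLANK,
    IntegrationSite,
    call_sites,
    junction_integrity,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the calling pipeline (defaults are the package's
    conventions; see docs/methods.md for rationale)."""

    min_phred_exclusive: int = 20
    min_host_len: int = 20
    motifs: LtrMotifSet = LtrMotifSet()
    k: int = 15
    max_mismatch: int = 2
    max_fragment: int = 10_000
    cluster_window: int = 5
    min_molecules: int = 1
    min_reads: int = 1
    min_modal_fraction: float = 0.8
    flank_len: int = 50
    merge_window: int = 10


@dataclass
class SampleResult:
    sample_id: str
    sites: list[IntegrationSite]
    molecules: list
    stats: Counter = field(default_factory=Counter)


def process_sample(
    sample_id: str,
    triples: Sequence[ReadTriple],
    index: KmerIndex,
    cfg: PipelineConfig = PipelineConfig(),
) -> SampleResult:
    """Run one sample: quality gate, LTR trim, map, dedup, call, QC-flag."""
    stats: Counter = Counter(input=len(triples))
    kept = index_quality_filter(triples, cfg.min_phred_exclusive)
    stats["index_pass"] = len(kept)
    placements: list[ReadPlacement] = []
    for t in kept:
        jr, reason = select_and_trim(t, cfg.motifs, cfg.min_host_len)
        if jr is None:
            stats[reason] += 1
            continue
        aln = map_read(index, jr.host_seq, cfg.max_mismatch, read_id=t.read_id)
        if aln.uniqueness != UNIQUE:
            stats[f"r1_{aln.uniqueness}"] += 1
            continue
        junction = junction_position(aln, len(jr.host_seq))
        mate = map_read(index, t.r2_seq, cfg.max_mismatch, read_id=t.read_id)
        if mate.uniqueness != UNIQUE:
            stats["mate_unresolved"] += 1
            continue
        if mate.chrom != aln.chrom or mate.strand == aln.strand:
            stats["discordant"] += 1
            continue
        if aln.strand == "+":
            frag_len = mate.start + len(t.r2_seq) - aln.start
        else:
            frag_len = junction - mate.start
        if not 0 < frag_len <= cfg.max_fragment:
            stats["discordant"] += 1
            continue
        placements.append(
            ReadPlacement(t.read_id, aln.chrom, junction, aln.strand, frag_len)
        )
    stats["placed"] = len(placements)
    molecules = deduplicate(placements)
    stats["molecules"] = len(molecules)
    sites = call_sites(molecules, cfg.cluster_window, cfg.min_molecules, cfg.min_reads)
    for s in sites:
        s.sample_id = sample_id
        junction_integrity(s, cfg.min_modal_fraction)
        if not uniqueness_filter(
            index.genome, s.chrom, s.junction_pos_1based, s.strand, cfg.flank_len
        ):
            s.flags.add(FLAG_NONUNIQUE_FLANK)
        s.copy_number = clonality.copy_number(s.molecules)
    stats["sites"] = len(sites)
    logger.info("sample %s: %s", sample_id, dict(stats))
    return SampleResult(sample_id, sites, molecules, stats)


@dataclass
class CohortResult:
    sample_results: dict[str, SampleResult]
    matrix: SiteMatrix
    classification: SiteClassification
    abundance: pd.DataFrame
    excluded_sites: list[IntegrationSite]
    known_matches: list


def process_cohort(
    per_sample_triples: Mapping[str, Sequence[ReadTriple]],
    genome: ToyGenome,
    groups: Mapping[str, Sequence[str]],
    reference_group: str,
    cfg: PipelineConfig = PipelineConfig(),
    known: Optional[KnownInsertionList] = None,
) -> CohortResult:
    """Run every sample and compare site sets across the cohort.

    Sites carrying QC flags (indel-suspect junctions, non-unique flanks) are
    excluded before the matrix is built, mirroring the order raw sites ->
    exclusions -> universal/specific census.
    """
    index = build_index(genome, cfg.k)
    results = {
        sample: process_sample(sample, triples, index, cfg)
        for sample, triples in per_sample_triples.items()
    }
    excluded: list[IntegrationSite] = []
    clean: dict[str, list[IntegrationSite]] = {}
    for sample, res in results.items():
        clean[sample] = [s for s in res.sites if not s.flags]
        excluded.extend(s for s in res.sites if s.flags)
    matrix = build_matrix(clean, cfg.merge_window)
    classification = classify(matrix, groups, reference_group)
    abundance = clonality.abundance_table(
        {
            sample: {
                f"{s.chrom}:{s.junction_pos_1based}:{s.strand}": s.copy_number
                for s in sites_
            }
            for sample, sites_ in clean.items()
            if sites_
        }
    )
    known_matches = match_known(matrix.loci, known) if known is not None else []
    return CohortResult(results, matrix, classification, abundance, excluded, known_matches)
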