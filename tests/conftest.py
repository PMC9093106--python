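"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from retrosite.dna import revcomp
from retrosite.simlib import ToyGenome, make_reference


def brute_force_map(genome: ToyGenome, read: str, max_mismatch: int = 2):
    """Exhaustive both-strand mismatch scan over every offset.

    Independent oracle for the k-mer mapper: vectorised Hamming distance of
    the read (and its reverse complement) against every window of every
    chromosome. Returns (chrom, start0, strand, mismatches, uniqueness) with
    the same unique/multi/unmapped contract and tie-break order.
    """
    L = len(read)
    fwd = np.frombuffer(read.encode(), dtype=np.uint8)
    rev = np.frombuffer(revcomp(read).encode(), dtype=np.uint8)
    placements = []
    for chrom, seq in genome:
        if len(seq) < L:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, pattern in (("+", fwd), ("-", rev)):
            mm = (windows != pattern).sum(axis=1)
            for off in np.nonzero(mm <= max_mismatch)[0]:
                placements.append((chrom, int(off), strand, int(mm[off])))
    if not placements:
        return None, None, None, None, "unmapped"
    placements.sort(key=lambda p: (p[0], p[1], p[2]))
    best = min(p[3] for p in placements)
    winners = [p for p in placements if p[3] == best]
    chrom, start, strand, mm = winners[0]
    return chrom, start, strand, mm, ("unique" if len(winners) == 1 else "multi")


@pytest.fixture(scope="session")
def genome_100kb() -> ToyGenome:
    return make_reference(11, {"chr1": 100_000})


@pytest.fixture(scope="session")
def genome_small() -> ToyGenome:
    return make_reference(5, {"chrA": 6_000, "chrB": 5_000})
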