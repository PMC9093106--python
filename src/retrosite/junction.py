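"""Index-read quality gating and reduction of reads to host-genome segments.

The demultiplexing gate keeps a read only if *every* position of its 8-bp
index read has Phred strictly greater than the threshold (default >20).
Junction reduction then finds the 3'-LTR terminal hexamer (CCTACA or CCTTCA)
near the start of R1 and trims everything up to and including it, leaving the
host segment used for mapping.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .dna import validate_dna
from .simlib import ReadTriple

logger = logging.getLogger(__name__)

REASON_OK = "ok"
REASON_NO_MOTIF = "no-motif"
REASON_SHORT_HOST = "short-host"


@dataclass(frozen=True)
class LtrMotifSet:
    """Terminal hexamers of the 3' LTR and the R1 window they must end in.

    ``ltr_context``, if given, is the known LTR sequence ending just before
    the terminal hexamer (the U5 body); a motif occurrence is then accepted
    only when the ``context_len`` read bases 5' of it match the context's
    suffix exactly. The LTR is a known sequence in a primer-designed assay,
    so this rejects hexamers arising in host DNA or from sequencing error
    without touching genuine termini.
    """

    motifs: tuple[str, ...] = ("CCTACA", "CCTTCA")
    search_window: int = 60
    ltr_context: Optional[str] = None
    context_len: int = 6

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif set is empty")
        for m in self.motifs:
            validate_dna(m, what="motif")
            if len(m) != 6:
                raise ValueError(f"motifs must be hexamers, got {m!r}")
        if self.search_window < 6:
            raise ValueError("search_window must be >= 6")
        if self.ltr_context is not None:
            validate_dna(self.ltr_context, what="ltr_context")

    def context_ok(self, r1_seq: str, motif_start: int) -> bool:
        if self.ltr_context is None:
            return True
        n = min(self.context_len, motif_start, len(self.ltr_context))
        return r1_seq[motif_start - n : motif_start] == self.ltr_context[len(self.ltr_context) - n :]


@dataclass
class JunctionRead:
    """A read reduced to its host-genome segment after LTR trimming."""

    read_id: str
    host_seq: str
    motif_used: str
    fragment_length: Optional[int] = None
    sample_id: Optional[str] = None


def _min_index_phred(quals: str) -> int:
    return min(ord(c) - 33 for c in quals)


def index_quality_filter(
    reads: Iterable[ReadTriple],
    min_phred_exclusive: int = 20,
    index_len: int = 8,
) -> list[ReadTriple]:
    """Keep reads whose every index-read position has Phred > threshold.

    The inequality is strict: a position at exactly the threshold discards
    the read. Reads with a malformed index read (wrong length) are rejected
    with a warning rather than raising. Order is preserved.
    """
    kept: list[ReadTriple] = []
    n_lowq = n_malformed = 0
    for r in reads:
        if len(r.index_quals) != index_len:
            logger.warning(
                "read %s: index read length %d != %d, rejected",
                r.read_id, len(r.index_quals), index_len,
            )
            n_malformed += 1
            continue
        if _min_index_phred(r.index_quals) > min_phred_exclusive:
            kept.append(r)
        else:
            n_lowq += 1
    logger.info(
        "index filter: kept %d, discarded %d low-quality, %d malformed",
        len(kept), n_lowq, n_malformed,
    )
    return kept


def select_and_trim(
    read: ReadTriple,
    motifs: LtrMotifSet = LtrMotifSet(),
    min_host_len: int = 20,
) -> tuple[Optional[JunctionRead], str]:
    """Trim R1 at the first LTR terminal hexamer ending within the window.

    Matching is exact (0 mismatches). R1 starts at a fixed position inside
    the LTR (the sequencing primer sits in it), so the sequence before the
    terminal hexamer is LTR and contains no motif; the *first* occurrence is
    therefore the LTR terminus. Taking a later occurrence instead would
    mis-trim every read of any site whose host flank happens to contain the
    hexamer. Returns ``(JunctionRead, "ok")`` or ``(None, reason)`` with
    reason ``no-motif`` or ``short-host``.
    """
    window = read.r1_seq[: motifs.search_window]
    best_end = None
    best_motif = None
    for m in motifs.motifs:
        start = window.find(m)
        while start != -1:
            if motifs.context_ok(read.r1_seq, start):
                if best_end is None or start + len(m) < best_end:
                    best_end = start + len(m)
                    best_motif = m
                break
            start = window.find(m, start + 1)
    if best_motif is None:
        return None, REASON_NO_MOTIF
    host = read.r1_seq[best_end:]
    if len(host) < min_host_len:
        return None, REASON_SHORT_HOST
    return JunctionRead(read.read_id, host, best_motif), REASON_OK


@dataclass
class TrimStats:
    counts: Counter = field(default_factory=Counter)


def trim_stream(
    reads: Iterable[ReadTriple],
    motifs: LtrMotifSet = LtrMotifSet(),
    min_host_len: int = 20,
) -> tuple[list[tuple[ReadTriple, JunctionRead]], Counter]:
    """Apply :func:`select_and_trim` to a stream, tallying rejection reasons.

    Returns (kept pairs of original read and its junction reduction, counter
    over {ok, no-motif, short-host}).
    """
    kept: list[tuple[ReadTriple, JunctionRead]] = []
    counts: Counter = Counter()
    for r in reads:
        jr, reason = select_and_trim(r, motifs, min_host_len)
        counts[reason] += 1
        if jr is not None:
            kept.append((r, jr))
    logger.info("junction trim: %s", dict(counts))
    return kept, counts
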