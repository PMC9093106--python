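"""Small DNA string utilities shared across the package.

Sequences are plain uppercase ``str`` over the alphabet ACGT. Anything more
structured (records, files) goes through Biopython in :mod:`retrosite.io`.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = "ACGT"
_VALID = frozenset(_ALPHABET)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Return *seq* uppercased, raising ``ValueError`` on non-ACGT characters."""
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} is empty")
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")
    return seq


def random_dna(rng: np.random.Generator, length: int, max_run: int = 30) -> str:
    """Uniform random ACGT string with no single-base run longer than ``max_run``.

    Long homopolymers would make every k-mer inside them ambiguous, so the
    toy-genome generator caps run length (a uniform draw essentially never
    produces a 30-mer run anyway; the cap makes it a guarantee).
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    codes = rng.integers(0, 4, size=length)
    seq = list(_ALPHABET[c] for c in codes)
    run = 1
    for i in range(1, length):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > max_run:
            choices = [b for b in _ALPHABET if b != seq[i]]
            seq[i] = choices[int(rng.integers(0, 3))]
            run = 1
    return "".join(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start offsets of ``needle`` in ``haystack``."""
    hits: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
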