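"""Clone copy-number estimation by distinct-amplicon counting.

Sister clones carrying the same integration site shear at different
positions during sonication, so the number of *different* fragment lengths
observed at a site estimates its clone copy number. Lengths can collide but
never split, so the estimate is a lower bound on the true count. Relative
abundance divides each site's copy number by the per-sample total over all
sites (reference and nonreference alike).
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Optional

import pandas as pd

from .mapper import Molecule


def copy_number(
    molecules: Iterable[Molecule],
    correction: Optional[Callable[[int], int]] = None,
) -> int:
    """Number of distinct amplicon lengths among one site's molecules.

    Lengths are compared as shear *endpoints* (junction +/- fragment length),
    which equals the distinct-fragment-length count whenever all molecules
    agree on the junction, and stays robust to the few-bp junction jitter a
    site cluster can contain (a jittered read shares its shear endpoint with
    its parent fragment and must not count as an extra clone).

    ``correction`` is a hook for a length-collision correction; the default
    is plain counting (identity).
    """
    ends = set()
    for m in molecules:
        if m.strand == "+":
            ends.add(m.junction_pos_1based + m.fragment_length - 1)
        else:
            ends.add(m.junction_pos_1based - m.fragment_length + 1)
    if not ends:
        raise ValueError("copy_number of an empty molecule set")
    n = len(ends)
    return correction(n) if correction is not None else n


def relative_abundance(copy_numbers: Mapping[str, int]) -> dict[str, float]:
    """Per-site fraction of one sample's total integration-site copies."""
    total = sum(copy_numbers.values())
    if total <= 0:
        raise ValueError("total copy number is zero")
    return {site: n / total for site, n in copy_numbers.items()}


def abundance_table(per_sample: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Long-form table of copy numbers and relative abundances.

    ``per_sample`` maps sample_id -> {site key -> copy number}. Within each
    sample the rel_abundance column sums to 1.
    """
    rows = []
    for sample in sorted(per_sample):
        copies = per_sample[sample]
        if not copies:
            continue
        rel = relative_abundance(copies)
        for site in sorted(copies):
            rows.append(
                {
                    "sample_id": sample,
                    "site": site,
                    "copy_number": copies[site],
                    "rel_abundance": rel[site],
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "site", "copy_number", "rel_abundance"])
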