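"""Bundled encodings of published integration-site tables.

Two presence/absence tables of nonreference HERV-K integration loci, with
GRCh38 coordinates and cytoband labels, plus a short list of known
polymorphic HERV-K insertions (K113, K20, K22) for cross-referencing:

``hela_inblc_sites``
    Loci found in HERV-K-reporter-transfected HeLa cells: 7 universal
    (HeLa and HeLa-inBLC) and 8 specific to HeLa-inBLC; absent from
    fibroblasts.
``ipsc_sites``
    Loci from a fibroblast/iPSC donor pair: 4 universal (fibroblast and
    both iPSC passages) and 3 iPSC-specific; absent from HeLa.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import KnownInsertionList, SiteMatrix, load_presence_tsv


def _path(name: str):
    return resources.files("retrosite.data").joinpath(name)


def hela_inblc_sites() -> SiteMatrix:
    """Presence matrix of the HeLa / HeLa-inBLC nonreference loci."""
    return load_presence_tsv(_path("hela_inblc_sites.tsv"))


def ipsc_sites() -> SiteMatrix:
    """Presence matrix of the fibroblast / iPSC nonreference loci."""
    return load_presence_tsv(_path("ipsc_sites.tsv"))


def known_insertions() -> KnownInsertionList:
    """Known polymorphic HERV-K insertions (K113 at 19p12, K20 at 12q12,
    K22 at 13q31.3)."""
    return KnownInsertionList.from_tsv(_path("known_insertions.tsv"))


def hela_inblc_frame() -> pd.DataFrame:
    return pd.read_csv(_path("hela_inblc_sites.tsv"), sep="\t")


def ipsc_frame() -> pd.DataFrame:
    return pd.read_csv(_path("ipsc_sites.tsv"), sep="\t")
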