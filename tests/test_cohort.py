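"""Cross-sample matrix building, classification, and known-site matching."""

import pytest

from retrosite import datasets
from retrosite.cohort import (
    EXCLUDED,
    NONREF_SPECIFIC,
    NONREF_UNIVERSAL,
    REFERENCE,
    KnownInsertion,
    KnownInsertionList,
    Locus,
    build_matrix,
    classify,
    count_category,
    match_known,
    uniqueness_filter,
)
from retrosite.simlib import ToyGenome, make_reference
from retrosite.sites import IntegrationSite


def site(chrom, pos, strand="+", sample=None, copies=1):
    s = IntegrationSite(chrom, pos, strand, 1, 1, 1.0)
    s.sample_id = sample
    s.copy_number = copies
    return s


class TestBuildMatrix:
    def test_nearby_junctions_merge(self):
        m = build_matrix(
            {"A": [site("c", 1000)], "B": [site("c", 1003)]}, merge_window=10
        )
        assert len(m.loci) == 1
        assert m.presence.loc[m.loci[0].key].all()
        assert m.loci[0].pos == 1000  # minimum member coordinate

    def test_distant_junctions_stay_separate(self):
        m = build_matrix({"A": [site("c", 1000), site("c", 1050)]}, merge_window=10)
        assert len(m.loci) == 2

    def test_strand_separates(self):
        m = build_matrix({"A": [site("c", 1000, "+"), site("c", 1000, "-")]})
        assert len(m.loci) == 2

    def test_empty_input(self):
        m = build_matrix({})
        assert m.loci == [] and m.presence.empty


GROUPS1 = {"ref": ["fibroblast"], "HeLa": ["HeLa"], "inBLC": ["HeLa-inBLC"]}
GROUPS2 = {"ref": ["HeLa"], "fibro": ["fibroblast"], "iPSC": ["iPS-p31", "iPS-p41"]}


class TestClassify:
    def test_hela_table_blocks(self):
        """The HeLa/HeLa-inBLC table: 7 universal + 8 inBLC-specific loci."""
        cls = classify(datasets.hela_inblc_sites(), GROUPS1, "ref")
        assert cls.counts() == {NONREF_UNIVERSAL: 7, NONREF_SPECIFIC: 8}
        n_spec = count_category(
            cls, lambda k, c: c.category == NONREF_SPECIFIC and c.witness == "inBLC"
        )
        assert n_spec == 8

    def test_ipsc_table_blocks(self):
        """Fibroblast/iPSC table: 4 universal + 3 iPSC-specific loci."""
        cls = classify(datasets.ipsc_sites(), GROUPS2, "ref")
        assert cls.counts() == {NONREF_UNIVERSAL: 4, NONREF_SPECIFIC: 3}
        assert count_category(
            cls, lambda k, c: c.category == NONREF_SPECIFIC and c.witness == "iPSC"
        ) == 3

    def test_reference_presence_dominates(self):
        m = build_matrix(
            {"ctrl": [site("c", 1000)], "x": [site("c", 1001)]}, merge_window=10
        )
        cls = classify(m, {"ref": ["ctrl"], "g": ["x"]}, "ref")
        assert cls[m.loci[0].key].category == REFERENCE

    def test_excluded_loci_carry_reason(self):
        m = build_matrix({"x": [site("c", 1000)]})
        key = m.loci[0].key
        cls = classify(
            m, {"ref": [], "g": ["x"]}, "ref", excluded={key: "indel_suspect"}
        )
        assert cls[key].category == EXCLUDED and cls[key].reason == "indel_suspect"

    def test_total_partition(self):
        cls = classify(datasets.hela_inblc_sites(), GROUPS1, "ref")
        assert sum(cls.counts().values()) == 15
        assert count_category(cls, lambda k, c: True) == 15
        assert count_category(cls, lambda k, c: False) == 0

    def test_sample_order_invariance(self):
        m = datasets.hela_inblc_sites()
        a = classify(m, GROUPS1, "ref")
        reordered = {"inBLC": ["HeLa-inBLC"], "ref": ["fibroblast"], "HeLa": ["HeLa"]}
        b = classify(m, reordered, "ref")
        assert {k: c.category for k, c in a.items()} == {
            k: c.category for k, c in b.items()
        }

    def test_unassigned_sample_rejected(self):
        m = build_matrix({"x": [site("c", 1000)]})
        with pytest.raises(ValueError):
            classify(m, {"ref": ["ctrl"]}, "ref")


class TestUniquenessFilter:
    def test_unique_flank_passes(self):
        g = make_reference(21, {"c": 20_000})
        assert uniqueness_filter(g, "c", 10_000, "+")

    def test_planted_repeat_fails(self):
        base = make_reference(21, {"c": 20_000})["c"]
        dup = base[10_000 - 1 : 10_000 - 1 + 50]  # the flank read at the junction
        g = ToyGenome({"c": base + "ACGT" + dup})
        assert not uniqueness_filter(g, "c", 10_000, "+")

    def test_repetitive_flank_fails(self):
        # a flank inside low-complexity sequence hits many places -> fail
        assert not uniqueness_filter(ToyGenome({"c": "A" * 60}), "c", 5, "+")

    def test_minus_strand_flank(self):
        g = make_reference(22, {"c": 20_000})
        assert uniqueness_filter(g, "c", 10_000, "-")


class TestMatchKnown:
    def test_cytoband_match(self):
        loci = [Locus("chr19:21658739", "chr19", 21_658_739, cytoband="19p12")]
        matches = match_known(loci, datasets.known_insertions())
        assert [(l.cytoband, e.name) for l, e in matches] == [("19p12", "K113")]

    def test_ipsc_universal_block_matches_k20_k22(self):
        m = datasets.ipsc_sites()
        cls = classify(m, GROUPS2, "ref")
        universal = [m.locus(k) for k, c in cls.items() if c.category == NONREF_UNIVERSAL]
        matches = match_known(universal, datasets.known_insertions())
        assert sorted(e.name for _, e in matches) == ["K20", "K22"]
        assert sorted(l.cytoband for l, _ in matches) == ["12q12", "13q31.3"]

    def test_coordinate_window_match(self):
        known = KnownInsertionList([KnownInsertion("X1", chrom="chr1", pos=5_000)])
        near = Locus("chr1:5050", "chr1", 5_050)
        far = Locus("chr1:5200", "chr1", 5_200)
        assert [l.key for l, _ in match_known([near, far], known, window=100)] == ["chr1:5050"]

    def test_empty_known_list(self):
        assert match_known([Locus("c:1", "c", 1)], KnownInsertionList([])) == []

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            KnownInsertionList([KnownInsertion("K1"), KnownInsertion("K1")])
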