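"""Fixer prediction, core gene-set constraints, CAZyme filtering, diversity."""

import numpy as np
import pytest

from gillsym.errors import DataError
from gillsym.gene_content import (
    ACCESSORY_NIF,
    ALL_NIF,
    ESSENTIAL_NIF,
    REGULATORY_NIF,
    CazymeCatalog,
    NifCatalog,
    core_gene_set,
    diversity_by_richness,
    lignocellulose_filter,
    parse_dbcan_overview,
    predict_fixer,
    shared_nif_core,
    sufficient_communities,
)

from conftest import make_pm

POOL = [f"sp{i}" for i in range(1, 8)]


class TestNifTiers:
    def test_tiers_partition_the_17_classes(self):
        assert len(ALL_NIF) == 17
        assert ESSENTIAL_NIF | REGULATORY_NIF | ACCESSORY_NIF == ALL_NIF
        assert not ESSENTIAL_NIF & REGULATORY_NIF
        assert not ESSENTIAL_NIF & ACCESSORY_NIF
        assert not REGULATORY_NIF & ACCESSORY_NIF
        assert ESSENTIAL_NIF == {"nifH", "nifD", "nifK", "nifE", "nifN", "nifB"}


class TestPredictFixer:
    @pytest.mark.parametrize("classes,expected", [
        (ALL_NIF, True),
        (ALL_NIF - {"nifJ"}, True),            # 16 classes, nifJ missing
        ({"nifJ"}, False),                      # accessory alone predicts nothing
        (ALL_NIF - {"nifH"}, False),            # one missing essential flips it
        (set(), False),
    ])
    def test_truth_table(self, classes, expected):
        assert predict_fixer(classes).is_fixer is expected

    def test_missing_essential_report(self):
        pred = predict_fixer(ALL_NIF - {"nifD", "nifK"})
        assert pred.missing_essential == {"nifD", "nifK"}

    def test_monotone_adding_classes_never_unfixes(self):
        rng = np.random.default_rng(21)
        classes = sorted(ALL_NIF)
        for _ in range(50):
            base = set(rng.choice(classes, size=rng.integers(0, 18), replace=False))
            extra = set(rng.choice(classes, size=rng.integers(0, 18), replace=False))
            if predict_fixer(base).is_fixer:
                assert predict_fixer(base | extra).is_fixer


class TestSharedNifCore:
    def test_three_fixers_share_16_classes(self):
        cat = NifCatalog({
            "sp1": ALL_NIF, "sp2": ALL_NIF, "sp4": ALL_NIF - {"nifJ"},
        })
        core = shared_nif_core(cat, ["sp1", "sp2", "sp4"])
        assert len(core) == 16 and "nifJ" not in core

    def test_single_taxon_identity_and_disjoint_empty(self):
        cat = NifCatalog({"a": {"nifH"}, "b": {"nifD"}})
        assert shared_nif_core(cat, ["a"]) == {"nifH"}
        assert shared_nif_core(cat, ["a", "b"]) == frozenset()

    def test_unknown_taxon_rejected(self):
        with pytest.raises(DataError):
            shared_nif_core(NifCatalog({"a": set()}), ["a", "zz"])


class TestSufficientCommunities:
    def test_antichain_reduction_drops_supersets(self):
        pm = make_pm([{"sp1"}, {"sp1", "sp4"}, {"sp2", "sp7"}], POOL)
        assert sufficient_communities(pm) == [
            frozenset({"sp1"}), frozenset({"sp2", "sp7"})]

    def test_study_style_binding_communities(self):
        pm = make_pm([{"sp1"}, {"sp4"}, {"sp2", "sp7"}, {"sp1", "sp3", "sp4"}], POOL)
        assert sufficient_communities(pm) == [
            frozenset({"sp1"}), frozenset({"sp4"}), frozenset({"sp2", "sp7"})]

    def test_single_community_is_itself(self):
        pm = make_pm([{"sp2", "sp5"}], POOL)
        assert sufficient_communities(pm) == [frozenset({"sp2", "sp5"})]

    def test_result_is_an_antichain(self):
        rng = np.random.default_rng(31)
        rows = [set(rng.choice(POOL, size=rng.integers(1, 5), replace=False))
                for _ in range(40)]
        out = sufficient_communities(make_pm(rows, POOL))
        for a in out:
            for b in out:
                assert not (a < b)

    def test_all_empty_is_an_error(self):
        with pytest.raises(DataError):
            sufficient_communities(make_pm([set(), set()], POOL))


class TestCoreGeneSet:
    def test_identity_and_union_intersection(self):
        cat = CazymeCatalog({"A": {"x", "y", "z"}, "B": {"x"}, "C": {"y", "w"}}, {})
        assert core_gene_set(cat, [{"A"}]).core == {"x", "y", "z"}
        assert core_gene_set(cat, [{"A"}, {"B", "C"}]).core == {"x", "y"}

    def test_disjoint_genesets_give_empty_core(self):
        cat = CazymeCatalog({"A": {"x"}, "B": {"y"}}, {})
        assert core_gene_set(cat, [{"A"}, {"B"}]).core == frozenset()

    def test_antitone_in_communities(self):
        rng = np.random.default_rng(41)
        universe = [f"g{i}" for i in range(30)]
        cat = CazymeCatalog({
            t: set(rng.choice(universe, size=15, replace=False))
            for t in ["A", "B", "C", "D"]
        }, {})
        base = core_gene_set(cat, [{"A"}, {"B", "C"}]).core
        more = core_gene_set(cat, [{"A"}, {"B", "C"}, {"D"}]).core
        assert more <= base

    def test_unknown_member_rejected(self):
        cat = CazymeCatalog({"A": {"x"}}, {})
        with pytest.raises(DataError):
            core_gene_set(cat, [{"A", "missing"}])


class TestLignocelluloseFilter:
    def test_tag_matching(self):
        cat = CazymeCatalog(
            {"A": {"GH5_2", "GH18_1", "AA2_1"}},
            {"GH5_2": {"cellulose"}, "GH18_1": {"chitin"}, "AA2_1": {"lignin"}})
        kept = lignocellulose_filter(cat, ["GH5_2", "GH18_1", "AA2_1"])
        assert kept == {"GH5_2", "AA2_1"}

    def test_unmapped_subfamilies_are_dropped_not_fatal(self):
        cat = CazymeCatalog({"A": {"GH1_1"}}, {})
        assert lignocellulose_filter(cat, ["GH1_1"]) == frozenset()

    def test_custom_tag_vocabulary(self):
        cat = CazymeCatalog({"A": {"GH18_1"}}, {"GH18_1": {"chitin"}})
        assert lignocellulose_filter(cat, ["GH18_1"], substrate_tags={"chitin"}) \
            == {"GH18_1"}


class TestDbcanOverview:
    HEADER = "Gene ID\tEC#\tHMMER\tdbCAN_sub\tDIAMOND\t#ofTools"

    def test_two_of_three_filter(self):
        lines = [
            self.HEADER,
            "g1\t-\tGH5(1-100)\tGH5_2(1-100)\tGH5\t3",
            "g2\t-\tGH6(1-50)\t-\t-\t1",
            "g3\t-\t-\tCE1_1(5-60)\tCE1\t2",
        ]
        subfams = parse_dbcan_overview(lines)
        assert "GH5_2" in subfams and "CE1_1" in subfams
        assert not any(s.startswith("GH6") for s in subfams)

    def test_coordinate_suffixes_stripped(self):
        lines = [self.HEADER, "g1\t-\tGH10(11-222)\tGH10_3(11-222)\tGH10\t3"]
        assert parse_dbcan_overview(lines) == {"GH10", "GH10_3"}

    def test_malformed_rows_skipped_but_all_malformed_is_error(self):
        lines = [self.HEADER, "too\tfew"]
        with pytest.raises(DataError):
            parse_dbcan_overview(lines)
        with pytest.raises(DataError):
            parse_dbcan_overview([])


class TestDiversityByRichness:
    def test_single_specimen_counts_lignocellulose_subfamilies(self):
        subs = {f"GH{i}_1": {"cellulose"} for i in range(5)}
        cat = CazymeCatalog({"sp1": set(subs)}, subs)
        pm = make_pm([{"sp1"}], POOL)
        div = diversity_by_richness(pm, cat)
        assert div.per_specimen.iloc[0] == 5

    def test_union_idempotence_for_identical_catalogs(self):
        subs = {f"GH{i}_1": {"xylan"} for i in range(8)}
        cat = CazymeCatalog({"sp1": set(subs), "sp2": set(subs)}, subs)
        pm = make_pm([{"sp1"}, {"sp1", "sp2"}], POOL)
        div = diversity_by_richness(pm, cat)
        assert div.per_specimen.tolist() == [8, 8]

    def test_disjoint_catalogs_scale_linearly_and_separate_groups(self):
        subs = {}
        taxa_sets = {}
        for t in POOL:
            s = {f"{t}_GH{i}": {"cellulose"} for i in range(10)}
            subs.update(s)
            taxa_sets[t] = set(s)
        cat = CazymeCatalog(taxa_sets, subs)
        rng = np.random.default_rng(51)
        rows = []
        for k in (1, 3):
            for _ in range(12):
                rows.append(set(rng.choice(POOL, size=k, replace=False)))
        pm = make_pm(rows, POOL)
        div = diversity_by_richness(pm, cat)
        assert set(div.by_richness[1]) == {10}
        assert set(div.by_richness[3]) == {30}
        assert div.comparison is not None
        assert div.comparison.letters["k=1"] != div.comparison.letters["k=3"]

    def test_missing_catalog_entry_names_taxon(self):
        cat = CazymeCatalog({"sp1": {"GH5_2"}}, {"GH5_2": {"cellulose"}})
        pm = make_pm([{"sp1", "sp2"}], POOL)
        with pytest.raises(DataError, match="sp2"):
            diversity_by_richness(pm, cat)

    def test_diversity_monotone_under_taxon_addition(self):
        subs = {f"GH{i}_1": {"cellulose"} for i in range(6)}
        subs.update({f"CE{i}_1": {"xylan"} for i in range(4)})
        cat = CazymeCatalog(
            {"sp1": {f"GH{i}_1" for i in range(6)},
             "sp2": {f"CE{i}_1" for i in range(4)}}, subs)
        d1 = diversity_by_richness(make_pm([{"sp1"}], POOL), cat).per_specimen.iloc[0]
        d2 = diversity_by_richness(make_pm([{"sp1", "sp2"}], POOL),
                                   cat).per_specimen.iloc[0]
        assert d2 >= d1
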