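import numpy as np
import pandas as pd
import pytest

from epireg.screen import ScreenConfig, collect_regulated_genes, \
    overlap_genes, pair_cpg_genes, pair_mirna_genes, region_frequency, \
    score_pairs


def _matrix(rows, cols, values):
    return pd.DataFrame(values, index=rows, columns=cols)


@pytest.fixture()
def toy_annot():
    return pd.DataFrame({
        "probe_id": ["cg1", "cg2", "cg3"],
        "gene": ["gA", "gB", "gC"],
        "island_relation": ["Island", "Shore", "Island"],
        "position_class": ["TSS200", "Body", "TSS1500"]})


class TestPairing:
    def test_candidate_count_and_absent_gene_excluded(self, toy_annot):
        n = 40
        rng = np.random.default_rng(0)
        meth = _matrix(["cg1", "cg2", "cg3"], [f"s{i}" for i in range(n)],
                       rng.random((3, n)))
        mrna = _matrix(["gA", "gB"], meth.columns, rng.random((2, n)))
        cand = pair_cpg_genes(meth, mrna, toy_annot)
        assert len(cand) == 2          # gC unmeasured -> excluded
        assert set(cand["gene"]) == {"gA", "gB"}

    def test_promoter_class_filter(self, toy_annot):
        n = 40
        rng = np.random.default_rng(0)
        meth = _matrix(["cg1", "cg2", "cg3"], [f"s{i}" for i in range(n)],
                       rng.random((3, n)))
        mrna = _matrix(["gA", "gB", "gC"], meth.columns, rng.random((3, n)))
        cfg = ScreenConfig(promoter_classes=("TSS200", "TSS1500"))
        cand = pair_cpg_genes(meth, mrna, toy_annot, cfg)
        assert set(cand["regulator"]) == {"cg1", "cg3"}

    def test_disjoint_samples_is_hard_error(self, toy_annot):
        meth = _matrix(["cg1"], ["s1", "s2"], [[0.1, 0.2]])
        mrna = _matrix(["gA"], ["t1", "t2"], [[1.0, 2.0]])
        with pytest.raises(ValueError, match="share no sample"):
            pair_cpg_genes(meth, mrna, toy_annot)

    def test_candidates_contain_planted_pairs(self, small_cohort):
        _cfg, (mrna, _mirna, meth, annot, _l, _s, truth) = small_cohort
        cand = pair_cpg_genes(meth, mrna, annot)
        got = set(zip(cand["regulator"], cand["gene"]))
        assert truth.true_met_pairs <= got

    def test_mirna_strict_three_way_intersection(self):
        n = 35
        rng = np.random.default_rng(1)
        mirna = _matrix(["m1", "m2"], [f"s{i}" for i in range(n)],
                        rng.random((2, n)))
        mrna = _matrix(["gA", "gB"], mirna.columns, rng.random((2, n)))
        lists = [("a", {("m1", "gA"), ("m2", "gB")}),
                 ("b", {("m1", "gA"), ("m2", "gB")}),
                 ("c", {("m1", "gA")})]
        cand = pair_mirna_genes(lists, mirna, mrna)
        assert set(zip(cand["regulator"], cand["gene"])) == {("m1", "gA")}

    def test_identical_lists_restricted_to_measured(self):
        n = 35
        rng = np.random.default_rng(1)
        mirna = _matrix(["m1"], [f"s{i}" for i in range(n)],
                        rng.random((1, n)))
        mrna = _matrix(["gA"], mirna.columns, rng.random((1, n)))
        pairs = {("m1", "gA"), ("m9", "gZ")}
        cand = pair_mirna_genes([("a", pairs)] * 3, mirna, mrna)
        assert set(zip(cand["regulator"], cand["gene"])) == {("m1", "gA")}

    def test_zero_decoy_overlap_intersection_equals_truth(self,
                                                          small_cohort):
        _cfg, (mrna, mirna, _meth, _a, lists, _s, truth) = small_cohort
        cand = pair_mirna_genes(lists, mirna, mrna)
        assert set(zip(cand["regulator"], cand["gene"])) \
            == truth.true_mir_pairs


class TestScoring:
    def test_closed_form_fisher_example(self):
        # r = -0.5 at n_eff = 103: z = atanh(-0.5), z_std = z*10
        n = 103
        rng = np.random.default_rng(7)
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y0 = -0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * e
        # rotate to exact sample correlation -0.5
        xs = (x - x.mean()) / x.std()
        resid = y0 - np.dot(y0, xs) / np.dot(xs, xs) * xs
        y = -0.5 * xs + np.sqrt(1 - 0.25) * resid / resid.std()
        meth = _matrix(["p"], [f"s{i}" for i in range(n)], [x])
        mrna = _matrix(["g"], meth.columns, [y])
        cand = pd.DataFrame({"regulator": ["p"], "gene": ["g"],
                             "kind": "CpG"})
        scored = score_pairs(cand, meth, mrna)
        row = scored.iloc[0]
        assert row["r"] == pytest.approx(-0.5, abs=1e-10)
        assert row["z"] == pytest.approx(np.arctanh(-0.5), abs=1e-10)
        assert row["z_std"] == pytest.approx(np.arctanh(-0.5) * 10,
                                             abs=1e-8)
        assert bool(row["significant"])

    def test_zero_correlation_not_significant(self):
        x = np.tile([1.0, -1.0], 20)
        y = np.tile([1.0, 1.0, -1.0, -1.0], 10)
        meth = _matrix(["p"], [f"s{i}" for i in range(40)], [x])
        mrna = _matrix(["g"], meth.columns, [y])
        cand = pd.DataFrame({"regulator": ["p"], "gene": ["g"],
                             "kind": "CpG"})
        row = score_pairs(cand, meth, mrna).iloc[0]
        assert row["z_std"] == pytest.approx(0.0, abs=1e-12)
        assert not row["significant"]

    def test_degenerate_pairs_flagged_invalid_not_raised(self):
        n = 40
        cols = [f"s{i}" for i in range(n)]
        x = np.arange(n, dtype=float)
        meth = _matrix(["perfect", "flat"], cols,
                       [x, np.ones(n)])
        mrna = _matrix(["g1", "g2"], cols, [-x, x])
        cand = pd.DataFrame({
            "regulator": ["perfect", "flat"], "gene": ["g1", "g2"],
            "kind": "CpG"})
        scored = score_pairs(cand, meth, mrna)
        assert not scored["valid"].any()
        assert not scored["significant"].any()

    def test_min_overlap_floor_on_missing_data(self):
        n = 40
        cols = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(2)
        x = rng.standard_normal(n)
        x[:15] = np.nan
        meth = _matrix(["p"], cols, [x])
        mrna = _matrix(["g"], cols, [rng.standard_normal(n)])
        cand = pd.DataFrame({"regulator": ["p"], "gene": ["g"],
                             "kind": "CpG"})
        row = score_pairs(cand, meth, mrna).iloc[0]
        assert row["n_eff"] == 25
        assert not row["valid"]

    def test_invariant_to_joint_sample_permutation(self, small_cohort):
        _cfg, (mrna, _mirna, meth, annot, _l, _s, _t) = small_cohort
        cand = pair_cpg_genes(meth, mrna, annot)
        a = score_pairs(cand, meth, mrna)
        perm = np.random.default_rng(0).permutation(mrna.columns)
        b = score_pairs(cand, meth.loc[:, perm], mrna.loc[:, perm])
        np.testing.assert_allclose(a["z_std"], b["z_std"], atol=1e-10)


class TestGeneCollection:
    def test_no_significant_pairs_gives_empty_set(self):
        scored = pd.DataFrame({
            "regulator": ["p1"], "gene": ["g1"], "kind": "CpG",
            "n_eff": [50.0], "r": [0.1], "z": [0.1], "z_std": [0.7],
            "valid": [True], "significant": [False]})
        genes, best = collect_regulated_genes(scored)
        assert genes == set() and best.empty

    def test_gene_with_two_significant_probes_counted_once(self):
        scored = pd.DataFrame({
            "regulator": ["p1", "p2"], "gene": ["g1", "g1"],
            "kind": "CpG", "n_eff": [50.0, 50.0], "r": [-0.5, -0.6],
            "z": [-0.55, -0.69], "z_std": [-3.7, -4.7],
            "valid": [True, True], "significant": [True, True]})
        genes, best = collect_regulated_genes(scored)
        assert genes == {"g1"}
        assert len(best) == 1 and best.iloc[0]["regulator"] == "p2"

    def test_gene_sensitivity_on_planted_cohort(self, std_cohort):
        _cfg, (mrna, _mirna, meth, annot, _l, _s, truth) = std_cohort
        scored = score_pairs(pair_cpg_genes(meth, mrna, annot), meth, mrna)
        genes, _best = collect_regulated_genes(scored)
        true_genes = {g for _p, g in truth.true_met_pairs}
        sens = len(genes & true_genes) / len(true_genes)
        assert sens >= 0.99


class TestRegionFrequency:
    def test_all_significant_in_island(self, toy_annot):
        scored = pd.DataFrame({
            "regulator": ["cg1"], "gene": ["gA"], "kind": "CpG",
            "n_eff": [50.0], "r": [-0.5], "z": [-0.55], "z_std": [-3.7],
            "valid": [True], "significant": [True]})
        freq = region_frequency(scored, toy_annot)
        island = freq.query(
            "dimension == 'island_relation' and level == 'Island'")
        assert island["prop_significant"].iloc[0] == 1.0
        # universe proportions ignore significance
        assert island["prop_universe"].iloc[0] == pytest.approx(2 / 3)

    def test_proportions_sum_to_one_per_dimension(self, small_cohort):
        _cfg, (mrna, _mirna, meth, annot, _l, _s, _t) = small_cohort
        scored = score_pairs(pair_cpg_genes(meth, mrna, annot), meth, mrna)
        freq = region_frequency(scored, annot)
        sums = freq.groupby("dimension")[
            ["prop_significant", "prop_universe"]].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_hand_counted_enrichment_on_ten_probe_fixture(self):
        annot = pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(10)],
            "gene": [f"g{i}" for i in range(10)],
            "island_relation": ["Island"] * 4 + ["Opensea"] * 6,
            "position_class": ["TSS200"] * 10})
        sig_flags = [True, True, True, False, True, False, False,
                     False, False, False]
        scored = pd.DataFrame({
            "regulator": annot["probe_id"], "gene": annot["gene"],
            "kind": "CpG", "n_eff": 50.0, "r": -0.5, "z": -0.55,
            "z_std": -3.7, "valid": True, "significant": sig_flags})
        freq = region_frequency(scored, annot)
        row = freq.query(
            "dimension == 'island_relation' and level == 'Island'").iloc[0]
        # 3/4 significant probes in Island vs 4/10 universe -> 1.875
        assert row["prop_significant"] == pytest.approx(0.75)
        assert row["enrichment"] == pytest.approx(0.75 / 0.4)


def test_overlap_counts():
    inter, counts = overlap_genes({"a", "b", "c"}, {"c", "d"})
    assert inter == {"c"}
    assert counts == {"met_only": 2, "mir_only": 1, "both": 1}
    assert overlap_genes({"a"}, {"b"})[0] == set()
    assert overlap_genes({"a"}, {"a"})[0] == {"a"}
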