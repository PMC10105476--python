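import numpy as np
import pandas as pd
import pytest

from epireg.drugs import DrugScreenConfig, compare_named_drugs, \
    filter_and_impute, predict_sensitivity, subtype_specific_drugs


def _auc(values, cells=None, drugs=None):
    values = np.asarray(values, float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    drugs = drugs or [f"d{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=cells, columns=drugs)


class TestFilterImpute:
    def test_strict_missingness_boundary(self):
        rng = np.random.default_rng(0)
        mat = _auc(rng.uniform(0.2, 0.9, (100, 3)))
        mat.iloc[:21, 0] = np.nan     # 21% -> removed
        mat.iloc[:20, 1] = np.nan     # 20% -> retained
        out = filter_and_impute(mat)
        assert list(out.columns) == ["d1", "d2"]
        assert out.notna().all().all()

    def test_unanimous_neighbors_determine_value(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.4, 0.6, (8, 4))
        mat = _auc(base)
        mat.iloc[:, 3] = 0.5
        mat.iloc[0, 3] = np.nan
        out = filter_and_impute(mat, DrugScreenConfig(knn_k=5))
        assert out.iloc[0, 3] == pytest.approx(0.5)

    def test_complete_matrix_returned_unchanged(self):
        mat = _auc(np.random.default_rng(2).uniform(0.2, 0.9, (10, 5)))
        out = filter_and_impute(mat)
        pd.testing.assert_frame_equal(out, mat)

    def test_observed_entries_never_altered_and_idempotent(self,
                                                          std_drug_panel):
        auc, _expr, _drugs = std_drug_panel
        out = filter_and_impute(auc)
        obs = auc[out.columns].notna()
        pd.testing.assert_frame_equal(out.where(obs), auc[out.columns])
        again = filter_and_impute(out)
        pd.testing.assert_frame_equal(again, out)

    def test_isolated_cell_line_falls_back_to_column_mean(self):
        mat = _auc([[0.5, 0.6, np.nan],
                    [np.nan, np.nan, 0.4],
                    [0.7, 0.8, np.nan],
                    [0.6, 0.7, np.nan],
                    [0.5, 0.5, np.nan]])
        out = filter_and_impute(
            mat, DrugScreenConfig(knn_k=1, missing_max=0.9))
        # row 1 shares no observed drug with any other line
        assert out.iloc[1, 0] == pytest.approx(np.nanmean(mat["d0"]))


class TestRidgePrediction:
    def test_closed_form_solution_on_tiny_instance(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(3)]
        cells = [f"c{i}" for i in range(5)]
        cexpr = pd.DataFrame(rng.standard_normal((3, 5)), index=genes,
                             columns=cells)
        y = rng.uniform(0.3, 0.8, 5)
        auc = pd.DataFrame({"d0": y}, index=cells)
        texpr = pd.DataFrame(rng.standard_normal((3, 4)), index=genes,
                             columns=[f"t{i}" for i in range(4)])
        lam = 2.5
        cfg = DrugScreenConfig(ridge_lambda_grid=(lam,), cv_folds=2,
                               min_shared_genes=3, seed=0)
        pred, info = predict_sensitivity(cexpr, auc, texpr, cfg)

        def zrows(m):
            a = m.to_numpy(float)
            return (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)

        xt = zrows(cexpr).T
        xq = zrows(texpr).T
        xc = xt - xt.mean(0)
        yc = y - y.mean()
        beta = np.linalg.solve(xc.T @ xc + lam * np.eye(3), xc.T @ yc)
        expected = (xq - xt.mean(0)) @ beta + y.mean()
        np.testing.assert_allclose(pred["d0"].to_numpy(), expected,
                                   atol=1e-8)

    def test_infinite_shrinkage_limit_predicts_training_mean(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        cells = [f"c{i}" for i in range(30)]
        cexpr = pd.DataFrame(rng.standard_normal((10, 30)), index=genes,
                             columns=cells)
        y = rng.uniform(0.3, 0.8, 30)
        auc = pd.DataFrame({"d0": y}, index=cells)
        texpr = pd.DataFrame(rng.standard_normal((10, 6)), index=genes)
        cfg = DrugScreenConfig(ridge_lambda_grid=(1e12,), cv_folds=3,
                               min_shared_genes=5, seed=0)
        pred, _info = predict_sensitivity(cexpr, auc, texpr, cfg)
        np.testing.assert_allclose(pred["d0"], y.mean(), atol=1e-6)

    def test_recovers_linear_signal_in_planted_genes(self):
        rng = np.random.default_rng(5)
        n_train, n_test, p = 300, 100, 40
        genes = [f"g{i}" for i in range(p)]
        x_all = rng.standard_normal((p, n_train + n_test))
        beta = np.zeros(p)
        beta[:10] = rng.uniform(0.05, 0.1, 10)
        y_all = 0.6 + beta @ x_all + 0.03 * rng.standard_normal(
            n_train + n_test)
        cells = [f"c{i}" for i in range(n_train)]
        tums = [f"t{i}" for i in range(n_test)]
        cexpr = pd.DataFrame(x_all[:, :n_train], index=genes, columns=cells)
        texpr = pd.DataFrame(x_all[:, n_train:], index=genes, columns=tums)
        auc = pd.DataFrame({"d0": y_all[:n_train]}, index=cells)
        cfg = DrugScreenConfig(min_shared_genes=10, cv_folds=5, seed=0)
        pred, _info = predict_sensitivity(cexpr, auc, texpr, cfg)
        r = np.corrcoef(pred["d0"], y_all[n_train:])[0, 1]
        assert r >= 0.8

    def test_constant_auc_flagged(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(5)]
        cells = [f"c{i}" for i in range(12)]
        cexpr = pd.DataFrame(rng.standard_normal((5, 12)), index=genes,
                             columns=cells)
        auc = pd.DataFrame({"d0": [0.5] * 12}, index=cells)
        texpr = pd.DataFrame(rng.standard_normal((5, 3)), index=genes)
        cfg = DrugScreenConfig(min_shared_genes=3, cv_folds=3)
        pred, info = predict_sensitivity(cexpr, auc, texpr, cfg)
        assert info.iloc[0]["constant"]
        np.testing.assert_allclose(pred["d0"], 0.5)


class TestSpecificityRule:
    def _pred(self, means, n_per=10):
        idx, labs, rows = [], [], []
        for s, m in enumerate(means, start=1):
            for i in range(n_per):
                idx.append(f"s{s}_{i}")
                labs.append(s)
                rows.append(m)
        pred = pd.DataFrame({"d0": rows}, index=idx)
        return pred, pd.Series(labs, index=idx)

    def test_ratio_just_above_threshold_assigns(self):
        pred, labels = self._pred([1.0, 1.04, 1.04, 1.04])
        res = subtype_specific_drugs(pred, labels)
        assert res.table.iloc[0]["assigned"] == 1   # log2(1.04) = 0.0566

    def test_ratio_below_threshold_does_not_assign(self):
        pred, labels = self._pred([1.0, 1.03, 1.03, 1.03])
        res = subtype_specific_drugs(pred, labels)
        assert res.table.iloc[0]["assigned"] is None  # log2(1.03) = 0.0426

    def test_equal_means_assign_nothing(self):
        pred, labels = self._pred([1.0, 1.0, 1.0, 1.0])
        res = subtype_specific_drugs(pred, labels)
        assert all(len(v) == 0 for v in res.assignments.values())

    def test_planted_drugs_recovered_exactly(self, std_cohort,
                                             std_drug_panel):
        _cfg, (*_omics, truth) = std_cohort
        auc, _expr, true_drugs = std_drug_panel
        complete = filter_and_impute(auc)
        res = subtype_specific_drugs(complete, truth.labels)
        planted = {(s, d) for s, ds in true_drugs.items() for d in ds}
        called = {(s, d) for s, ds in res.assignments.items() for d in ds}
        assert called == planted


class TestNamedDrugs:
    def test_planted_sensitive_subtype_has_lowest_mean(self, std_cohort,
                                                       std_drug_panel):
        _cfg, (*_omics, truth) = std_cohort
        auc, _expr, true_drugs = std_drug_panel
        complete = filter_and_impute(auc)
        s, drug = 1, sorted(true_drugs[1])[0]
        res = compare_named_drugs(complete, truth.labels, [drug])
        row = res.iloc[0]
        means = {t: row[f"mean_{t}"] for t in (1, 2, 3, 4)}
        assert min(means, key=means.get) == s
        assert row["p"] < 1e-6

    def test_missing_drug_warned_other_processed(self, std_cohort,
                                                 std_drug_panel):
        _cfg, (*_omics, truth) = std_cohort
        auc, _expr, _drugs = std_drug_panel
        complete = filter_and_impute(auc)
        with pytest.warns(UserWarning, match="not in the AUC"):
            res = compare_named_drugs(complete, truth.labels,
                                      ["nope", complete.columns[0]])
        assert len(res) == 1

    def test_single_subtype_is_error(self, std_drug_panel):
        auc, _expr, _drugs = std_drug_panel
        complete = filter_and_impute(auc)
        labels = pd.Series(1, index=complete.index)
        with pytest.raises(ValueError, match=">= 2 subtypes"):
            compare_named_drugs(complete, labels, [complete.columns[0]])
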