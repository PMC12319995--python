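"""Region time series, FC matrices, edge-wise GLM, and multiple-testing
correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import wmfunnet as w
from wmfunnet.images import BoldImage


def make_bold(data, tr=1.0):
    return BoldImage(np.asarray(data, float), np.eye(4), tr=tr)


def bh_step_up(p):
    """Brute-force Benjamini-Hochberg adjusted q-values (step-up with
    cumulative-minimum monotonicity)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestExtractAvgTs:
    def test_single_voxel_regions(self, rng):
        data = rng.normal(size=(2, 1, 1, 20))
        labels = np.array([[[1]], [[2]]])
        series, flagged = w.extract_avg_ts(make_bold(data), labels)
        np.testing.assert_allclose(series[0], data[0, 0, 0])
        np.testing.assert_allclose(series[1], data[1, 0, 0])
        assert not flagged

    def test_identical_member_voxels(self, rng):
        x = rng.normal(size=15)
        data = np.stack([x, x])[..., None, None, :].reshape(2, 1, 1, 15)
        labels = np.ones((2, 1, 1), int)
        series, _ = w.extract_avg_ts(make_bold(data), labels)
        np.testing.assert_allclose(series[0], x)

    def test_cancelling_voxels_give_zero_series(self, rng):
        x = rng.normal(size=15)
        data = np.stack([x, -x]).reshape(2, 1, 1, 15)
        labels = np.ones((2, 1, 1), int)
        series, _ = w.extract_avg_ts(make_bold(data), labels)
        np.testing.assert_allclose(series[0], 0, atol=1e-12)

    def test_empty_region_flagged(self, rng):
        data = rng.normal(size=(2, 1, 1, 10))
        labels = np.ones((2, 1, 1), int)
        with pytest.warns(UserWarning, match="empty"):
            series, flagged = w.extract_avg_ts(make_bold(data), labels, region_ids=[1, 5])
        assert flagged == [5]
        assert np.all(series[1] == 0)

    def test_no_regions_rejected(self, rng):
        data = rng.normal(size=(2, 1, 1, 10))
        with pytest.raises(ValueError):
            w.extract_avg_ts(make_bold(data), np.zeros((2, 1, 1), int))


class TestBandFilteredTs:
    def test_matched_midband_content_preserved(self):
        t = np.arange(500)
        x = np.sin(2 * np.pi * 0.05 * t)
        ts = w.TimeSeriesSet(np.tile(x, (1, 1, 1)), [1], tr=1.0)
        (out,) = w.band_filtered_ts(ts, [(0.01, 0.15)])
        mid = slice(100, -100)
        assert np.abs(out.data[0, 0, mid] - x[mid]).max() < 0.02

    def test_excluded_band_attenuates_oscillation(self):
        t = np.arange(500)
        x = np.sin(2 * np.pi * 0.1 * t)
        ts = w.TimeSeriesSet(np.tile(x, (1, 1, 1)), [1], tr=1.0)
        (out,) = w.band_filtered_ts(ts, [(0.01, 0.04)])
        assert np.abs(out.data[0, 0, 100:-100]).max() < 0.1

    def test_empty_band_list(self, rng):
        ts = w.TimeSeriesSet(rng.normal(size=(2, 3, 30)), [1, 2, 3], tr=1.0)
        assert w.band_filtered_ts(ts, []) == []


class TestFCMatrix:
    def test_identical_regions_fully_correlated(self, rng):
        x = rng.normal(size=40)
        ts = w.TimeSeriesSet(np.stack([x, x])[None], [1, 2], tr=1.0)
        fc = w.fc_matrix(ts)
        assert fc[0, 0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(fc[0]), 1.0)

    def test_negated_region_anticorrelated(self, rng):
        x = rng.normal(size=40)
        ts = w.TimeSeriesSet(np.stack([x, -x])[None], [1, 2], tr=1.0)
        assert w.fc_matrix(ts)[0, 0, 1] == pytest.approx(-1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(50):
            ts = w.TimeSeriesSet(rng.normal(size=(1, 4, 500)), [1, 2, 3, 4], tr=1.0)
            fc = w.fc_matrix(ts)[0]
            vals.extend(fc[np.triu_indices(4, 1)])
        assert abs(np.mean(vals)) < 0.01

    def test_rectangular_kind(self, rng):
        a = w.TimeSeriesSet(rng.normal(size=(2, 3, 30)), [1, 2, 3], tr=1.0)
        b = w.TimeSeriesSet(rng.normal(size=(2, 5, 30)), list(range(5)), tr=1.0)
        fc = w.fc_matrix(a, b)
        assert fc.shape == (2, 3, 5)

    def test_zero_variance_region_zeroed(self, rng):
        data = rng.normal(size=(1, 2, 30))
        data[0, 1] = 5.0
        ts = w.TimeSeriesSet(data, [1, 2], tr=1.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            fc = w.fc_matrix(ts)
        assert fc[0, 0, 1] == 0.0


class TestEdgeGLM:
    def make_group_fc(self, rng, n_per=15, R=4, delta=0.0, edge=(0, 1)):
        P = 2 * n_per
        fc = np.zeros((P, R, R))
        base = rng.normal(scale=0.3, size=(P, R, R))
        base = (base + np.swapaxes(base, 1, 2)) / 2
        fc += base
        fc[n_per:, edge[0], edge[1]] += delta
        fc[n_per:, edge[1], edge[0]] += delta
        fc = np.clip(fc, -0.99, 0.99)
        for p in range(P):
            np.fill_diagonal(fc[p], 1.0)
        ids = [f"s{i}" for i in range(P)]
        cov = pd.DataFrame({"id": ids, "group": np.repeat([0, 1], n_per)})
        return fc, cov, ids

    def test_matches_two_sample_t_closed_form(self, rng):
        fc, cov, ids = self.make_group_fc(rng, delta=0.4)
        stats = w.edge_glm(fc, cov, "group", participant_ids=ids, fisher_z=False)
        group = cov["group"].to_numpy()
        for _, row in stats.table.iterrows():
            i, j = int(row.row_region) - 1, int(row.col_region) - 1
            vals = fc[:, i, j]
            t_ref, p_ref = sps.ttest_ind(vals[group == 1], vals[group == 0], equal_var=True)
            assert row.t == pytest.approx(t_ref, abs=1e-8)
            assert row.p == pytest.approx(p_ref, abs=1e-8)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        fc, cov, ids = self.make_group_fc(rng)
        cov["age"] = rng.normal(size=len(cov))
        stats = w.edge_glm(fc, cov, "group", participant_ids=ids, fisher_z=False)
        row = stats.table.iloc[0]
        i, j = int(row.row_region) - 1, int(row.col_region) - 1
        X = sm.add_constant(cov[["group", "age"]].to_numpy())
        fit = sm.OLS(fc[:, i, j], X).fit()
        assert row.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert row.t == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert row.p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_edge_count_upper_triangle(self, rng):
        fc, cov, ids = self.make_group_fc(rng, R=10)
        stats = w.edge_glm(fc, cov, "group", participant_ids=ids)
        assert stats.n_total == 45  # n(n-1)/2

    def test_collinear_covariates_rejected(self, rng):
        fc, cov, ids = self.make_group_fc(rng)
        cov["group_copy"] = cov["group"]
        with pytest.raises(ValueError, match="rank"):
            w.edge_glm(fc, cov, "group", participant_ids=ids)

    def test_constant_predictor_rejected(self, rng):
        fc, cov, ids = self.make_group_fc(rng)
        cov["group"] = 1
        with pytest.raises(ValueError, match="constant"):
            w.edge_glm(fc, cov, "group", participant_ids=ids)

    def test_unmatched_ids_listed(self, rng):
        fc, cov, ids = self.make_group_fc(rng)
        with pytest.raises(ValueError, match="ghost"):
            w.edge_glm(fc, cov, "group", participant_ids=ids[:-1] + ["ghost"])

    def test_planted_edge_has_extreme_t(self, rng):
        fc, cov, ids = self.make_group_fc(rng, n_per=30, delta=0.3)
        stats = w.edge_glm(fc, cov, "group", participant_ids=ids)
        tab = stats.table
        best = tab.loc[tab.t.abs().idxmax()]
        assert {int(best.row_region), int(best.col_region)} == {1, 2}


class TestCorrectMultiple:
    def test_bh_worked_example(self):
        out = w.correct_multiple([0.001, 0.02, 0.03, 0.04], method="fdr", alpha=0.05)
        assert out["significant"].all()

    def test_all_ones_never_significant(self):
        for method in ("fdr", "bonferroni"):
            out = w.correct_multiple(np.ones(10), method=method)
            assert not out["significant"].any()

    def test_bonferroni_arithmetic(self):
        n_total = 10 * 9 // 2
        out = w.correct_multiple(np.full(n_total, 0.5), method="bonferroni",
                                 alpha=0.05, n_total=n_total)
        assert out["alpha_corrected"] == pytest.approx(0.05 / 45)

    def test_bh_equals_step_up_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            out = w.correct_multiple(p, method="fdr")
            np.testing.assert_array_equal(out["q"], bh_step_up(p))

    def test_bh_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q_ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(w.correct_multiple(p, "fdr")["q"], q_ref,
                                       rtol=1e-12)

    def test_bonferroni_subset_of_bh(self, rng):
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(2, 30))) ** 2
            bon = w.correct_multiple(p, method="bonferroni")["significant"]
            bh = w.correct_multiple(p, method="fdr")["significant"]
            assert np.all(bh[bon])  # every Bonferroni hit is a BH hit

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            w.correct_multiple([0.5, 1.5])


def test_null_bh_family_error_controlled():
    """With no planted effect and independent edges, the fraction of
    replicates with any BH-significant edge stays near alpha."""
    rng = np.random.default_rng(42)
    n_any = 0
    reps = 500
    for _ in range(reps):
        p = rng.uniform(size=45)
        out = w.correct_multiple(p, method="fdr", alpha=0.05)
        n_any += out["significant"].any()
    assert n_any / reps <= 0.07
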