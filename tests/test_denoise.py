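"""Denoising chain: volume discard, CSF regressors, Friston expansion,
nuisance regression, band-pass filtering, and tissue-separated smoothing."""

import numpy as np
import pytest

import wmfunnet as w
from wmfunnet.images import BoldImage, TissueProbMaps


def make_bold(data, tr=1.0):
    return BoldImage(np.asarray(data, float), np.eye(4) * np.diag([3, 3, 3, 1]), tr=tr)


class TestDiscardInitial:
    def test_indexing(self, rng):
        data = rng.normal(size=(4, 4, 4, 100))
        out = w.discard_initial(make_bold(data), 10)
        assert out.n_volumes == 90
        np.testing.assert_array_equal(out.data[..., 0], data[..., 10])

    def test_zero_is_identity(self, rng):
        bold = make_bold(rng.normal(size=(3, 3, 3, 5)))
        assert w.discard_initial(bold, 0) is bold

    def test_discarding_everything_rejected(self, rng):
        bold = make_bold(rng.normal(size=(3, 3, 3, 5)))
        with pytest.raises(ValueError):
            w.discard_initial(bold, 5)


class TestCsfMask:
    def test_strict_threshold(self):
        csf = np.zeros((3, 1, 1))
        csf[:, 0, 0] = [0.94, 0.95, 0.96]
        tpm = TissueProbMaps(np.zeros_like(csf), np.zeros_like(csf), csf)
        mask, flagged = w.build_csf_mask(tpm, 0.95)
        assert not flagged
        np.testing.assert_array_equal(mask[:, 0, 0], [False, False, True])

    def test_empty_mask_flagged(self):
        z = np.zeros((2, 2, 2))
        with pytest.warns(UserWarning, match="threshold"):
            mask, flagged = w.build_csf_mask(TissueProbMaps(z, z, z))
        assert flagged and not mask.any()

    def test_zero_threshold_includes_all_positive(self):
        csf = np.array([[[0.1, 0.0], [0.5, 0.9]]])
        tpm = TissueProbMaps(np.zeros_like(csf), np.zeros_like(csf), csf)
        mask, _ = w.build_csf_mask(tpm, 0.0)
        assert mask.sum() == 3


class TestCsfRegressors:
    def test_mean_of_identical_voxels(self, rng):
        series = rng.normal(size=30)
        data = np.tile(series, (2, 2, 2, 1))
        out = w.extract_csf_regressors(make_bold(data), np.ones((2, 2, 2), bool), "mean")
        np.testing.assert_allclose(out[:, 0], series)

    def test_mean_of_anticorrelated_pair(self, rng):
        x = rng.normal(size=20)
        data = np.zeros((2, 1, 1, 20))
        data[0, 0, 0] = x
        data[1, 0, 0] = -x + 1.0
        out = w.extract_csf_regressors(make_bold(data), np.ones((2, 1, 1), bool), "mean")
        np.testing.assert_allclose(out[:, 0], 0.5 * np.ones(20), atol=1e-12)

    def test_pca_recovers_planted_components(self, rng):
        T, n_vox = 100, 40
        comps = rng.normal(size=(T, 2))
        comps[:, 1] *= 0.5  # distinct variance so component order is fixed
        loadings = rng.normal(size=(2, n_vox))
        series = comps @ loadings + 0.01 * rng.normal(size=(T, n_vox))
        data = series.T.reshape(n_vox, 1, 1, T)
        scores = w.extract_csf_regressors(
            make_bold(data), np.ones((n_vox, 1, 1), bool), "pca", k=2
        )
        for j in range(2):
            r = np.abs(np.corrcoef(scores[:, j], comps[:, 0] if j == 0 else comps[:, 1]))[0, 1]
            # the top PCs span the planted components
            assert max(
                abs(np.corrcoef(scores[:, j], comps[:, i])[0, 1]) for i in range(2)
            ) > 0.99

    def test_pca_needs_enough_voxels(self, rng):
        data = rng.normal(size=(2, 1, 1, 10))
        with pytest.raises(ValueError, match="PCA"):
            w.extract_csf_regressors(make_bold(data), np.ones((2, 1, 1), bool), "pca", k=5)

    def test_none_mode_empty(self, rng):
        out = w.extract_csf_regressors(make_bold(rng.normal(size=(2, 2, 2, 10))),
                                       np.ones((2, 2, 2), bool), "none")
        assert out.shape == (10, 0)


class TestFriston24:
    def test_zero_motion(self):
        out = w.friston24(np.zeros((10, 6)))
        assert out.shape == (10, 24) and np.all(out == 0)

    def test_backward_difference_by_hand(self):
        m = np.zeros((3, 6))
        m[:, 0] = [0, 1, 1]
        out = w.friston24(m)
        np.testing.assert_array_equal(out[:, 12], [0, 1, 0])   # derivative of tx
        np.testing.assert_array_equal(out[:, 18], [0, 1, 0])   # squared derivative

    def test_always_24_columns(self, rng):
        for T in (2, 5, 50):
            assert w.friston24(rng.normal(size=(T, 6))).shape[1] == 24

    def test_wrong_width_rejected(self, rng):
        with pytest.raises(ValueError):
            w.friston24(rng.normal(size=(10, 5)))


class TestRegressNuisance:
    def test_perfect_fit_leaves_zero_residual(self, rng):
        T = 50
        col = rng.normal(size=T)
        design = w.build_nuisance_design(None, col[:, None])
        data = np.tile(3.0 * col + 1.0, (2, 2, 2, 1))
        out = w.regress_nuisance(make_bold(data), design)
        assert np.abs(out.data).max() < 1e-8 * np.abs(data).max()

    def test_intercept_only_demeans(self, rng):
        T = 30
        data = rng.normal(size=(2, 2, 2, T)) + 50
        design = w.NuisanceDesign(np.ones((T, 1)), ["intercept"])
        out = w.regress_nuisance(make_bold(data), design)
        np.testing.assert_allclose(out.data, data - data.mean(axis=3, keepdims=True), atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        T = 40
        design = w.build_nuisance_design(rng.normal(size=(T, 6)), rng.normal(size=(T, 2)))
        data = rng.normal(size=(3, 3, 3, T))
        out = w.regress_nuisance(make_bold(data), design)
        resid = out.data.reshape(-1, T)
        dots = resid @ design.matrix
        assert np.abs(dots).max() < 1e-8

    def test_degenerate_columns_dropped_with_warning(self, rng):
        T = 30
        mat = np.column_stack([rng.normal(size=T), np.zeros(T), np.ones(T)])
        design = w.NuisanceDesign(mat, ["good", "allzero", "intercept"])
        with pytest.warns(UserWarning, match="allzero"):
            w.regress_nuisance(make_bold(rng.normal(size=(2, 2, 2, T))), design)


class TestBandpass:
    def test_constant_series_removed(self):
        data = np.full((3, 3, 3, 200), 7.0)
        out = w.bandpass(make_bold(data))
        assert np.abs(out.data).max() < 1e-6

    def test_midband_sinusoid_preserved(self):
        t = np.arange(600)
        x = np.sin(2 * np.pi * 0.05 * t)
        data = np.tile(x, (1, 1, 1, 1))
        out = w.bandpass(make_bold(data))
        assert np.abs(out.data[0, 0, 0, 100:-100]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_sinusoid_rejected(self):
        t = np.arange(600)
        data = np.tile(np.sin(2 * np.pi * 0.45 * t), (1, 1, 1, 1))
        out = w.bandpass(make_bold(data))
        assert np.abs(out.data[0, 0, 0, 100:-100]).max() < 0.1

    def test_nyquist_violation_reports_limit(self):
        bold = make_bold(np.zeros((2, 2, 2, 50)), tr=2.0)
        with pytest.raises(ValueError, match="0.25"):
            w.bandpass(bold, 0.01, 0.3)

    def test_regress_then_bandpass_is_linear(self, rng):
        T = 80
        design = w.build_nuisance_design(rng.normal(size=(T, 6)), None)

        def f(data):
            out = w.regress_nuisance(make_bold(data), design)
            return w.bandpass(out).data

        x = rng.normal(size=(2, 2, 2, T))
        y = rng.normal(size=(2, 2, 2, T))
        a, b = 2.5, -1.3
        lhs = f(a * x + b * y)
        rhs = a * f(x) + b * f(y)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-8, atol=1e-8 * np.abs(rhs).max())


class TestSmoothByTissue:
    def make_tpm(self, shape=(10, 10, 10)):
        gm = np.zeros(shape)
        wm = np.zeros(shape)
        wm[:5] = 0.9
        gm[5:] = 0.9
        return TissueProbMaps(gm, wm, np.zeros(shape))

    def test_wm_impulse_never_reaches_gm(self):
        tpm = self.make_tpm()
        base = np.zeros((10, 10, 10, 2))
        bumped = base.copy()
        bumped[2, 5, 5, :] = 100.0  # impulse inside WM
        out_base, _ = w.smooth_by_tissue(make_bold(base), tpm)
        out_bump, _ = w.smooth_by_tissue(make_bold(bumped), tpm)
        gm_mask = tpm.gm > 0.5
        np.testing.assert_array_equal(out_base.data[gm_mask], out_bump.data[gm_mask])

    def test_constant_wm_field_preserved(self):
        tpm = self.make_tpm()
        data = np.zeros((10, 10, 10, 3))
        wm_mask = tpm.wm > 0.5
        data[wm_mask] = 42.0
        out, info = w.smooth_by_tissue(make_bold(data), tpm)
        np.testing.assert_allclose(out.data[wm_mask], 42.0, rtol=1e-6)

    def test_none_mode_identity(self, rng):
        bold = make_bold(rng.normal(size=(6, 6, 6, 3)))
        out, info = w.smooth_by_tissue(bold, self.make_tpm((6, 6, 6)), mode="none")
        assert out is bold and info["n_holes"] == 0

    def test_holes_counted(self, rng):
        shape = (8, 8, 8)
        gm = np.zeros(shape)
        wm = np.zeros(shape)
        wm[:3] = 0.9
        gm[5:] = 0.9  # voxels 3..4 in x belong to neither tissue
        tpm = TissueProbMaps(gm, wm, np.zeros(shape))
        data = np.abs(rng.normal(size=(*shape, 2))) + 1
        out, info = w.smooth_by_tissue(make_bold(data), tpm)
        assert info["n_holes"] == 2 * 8 * 8
        assert np.all(out.data[3:5] == 0)

    def test_mask_swap_symmetry(self, rng):
        """Relabeling which compartment is GM vs WM leaves the smoothed
        image unchanged (the two disjoint masks are treated identically)."""
        shape = (8, 8, 8)
        a = np.zeros(shape)
        b = np.zeros(shape)
        a[:4] = 0.9
        b[4:] = 0.9
        data = rng.normal(size=(*shape, 2))
        out1, _ = w.smooth_by_tissue(make_bold(data), TissueProbMaps(a, b, np.zeros(shape)))
        out2, _ = w.smooth_by_tissue(make_bold(data), TissueProbMaps(b, a, np.zeros(shape)))
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-12)


def test_denoise_chain_improves_latent_recovery():
    """Across seeded phantoms, the full denoising chain raises the
    correlation between each planted network's recovered average series
    and its latent time course, relative to the raw phantom."""
    import warnings

    gains = []
    for seed in range(10):
        spec = w.PhantomSpec(shape=(12, 12, 12), n_volumes=100, n_participants=1,
                             seed=seed, include_cc=False)
        ph = w.generate_phantom(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean, _ = w.preprocess(ph.bolds[0], ph.motion[0], ph.tpms[0], n_discard=10)
        lat = ph.wm_latents[0][:, 10:]
        for k in range(1, spec.k_true + 1):
            members = ph.wm_truth == k
            raw = ph.bolds[0].data[members].mean(axis=0)[10:]
            rec = clean.data[members].mean(axis=0)
            r_raw = np.corrcoef(raw, lat[k - 1])[0, 1]
            r_clean = np.corrcoef(rec, lat[k - 1])[0, 1]
            gains.append(r_clean - r_raw)
    assert np.mean(gains) > 0
    assert np.mean(np.array(gains) > 0) > 0.8
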