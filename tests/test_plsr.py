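"""NIPALS PLSR against OLS / reference-library / explicit-CV oracles."""

import numpy as np
import pytest

import hsimoist as hm
from conftest import tiny_spectrum_set


def _random_instance(seed=0, n=30, p=12, noise=0.05):
    rs = np.random.default_rng(seed)
    X = rs.normal(size=(n, p))
    beta = rs.normal(size=p)
    y = 55 + X @ beta + noise * rs.normal(size=n)
    return X, y


class TestFit:
    def test_perfect_single_band_relation_one_lv(self, rng):
        # with mutually orthogonal (centered) bands and y exactly linear in
        # one of them, a single latent variable reproduces y exactly
        n, p = 25, 10
        raw = rng.normal(size=(n, p))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q  # orthonormal centered columns
        y = 50 + 3.0 * X[:, 4]
        wl = np.arange(400.0, 400 + 5 * p, 5)
        res = hm.MoisturePLSR(X, np.clip(y, 1, 99), wl).fit(n_latent=1)
        assert res.n_latent == 1
        assert res.r2_cal == pytest.approx(1.0, abs=1e-10)

    def test_training_r2_is_one_when_y_linear_in_x(self, rng):
        # y exactly linear in the spectra: full-rank fit is exact
        X, y = _random_instance(seed=1, noise=0.0)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl).fit(n_latent=X.shape[1])
        assert res.r2_cal == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_equals_ols_oracle(self):
        X, y = _random_instance(seed=2)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl).fit(n_latent=X.shape[1])
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        ols_pred = Xc @ beta + y.mean()
        assert np.allclose(res.predict(X), ols_pred, atol=1e-8)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    @pytest.mark.parametrize("n_lv", [2, 4, 7])
    def test_coefficients_match_reference_library(self, seed, n_lv):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_instance(seed=seed, n=40, p=15)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl).fit(n_latent=n_lv)
        ref = sklearn.PLSRegression(n_components=n_lv, scale=False).fit(X, y)
        assert np.allclose(res.coefficients, ref.coef_.ravel(), atol=1e-6)
        assert np.allclose(res.predict(X), ref.predict(X).ravel(), atol=1e-6)

    def test_collapsed_form_equals_latent_form(self):
        X, y = _random_instance(seed=6)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        model = hm.MoisturePLSR(X, y, wl)
        res = model.fit(n_latent=5)
        dec = res.decomposition
        latent_pred = dec["T"] @ dec["q"] + y.mean()
        assert np.allclose(res.predict(X), latent_pred, atol=1e-8)

    def test_degenerate_constant_spectra_rejected(self):
        X = np.ones((10, 5))
        with pytest.raises(ValueError, match="variance"):
            hm.MoisturePLSR(X, np.linspace(40, 60, 10), np.arange(5.0)).fit(2)


class TestPredict:
    def test_mean_spectrum_predicts_mean_y(self):
        X, y = _random_instance(seed=7)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl).fit(n_latent=3)
        assert res.predict(X.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-8)

    def test_fittedvalues_self_consistent(self):
        X, y = _random_instance(seed=8)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl).fit(n_latent=4)
        assert np.allclose(res.fittedvalues, res.predict(X))

    def test_wavelength_grid_mismatch_rejected(self):
        X, y = _random_instance(seed=9)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl).fit(n_latent=2)
        with pytest.raises(ValueError, match="mismatch"):
            res.predict(X, wavelengths_nm=wl + 1.0)

    def test_domain_mismatch_rejected(self):
        X, y = _random_instance(seed=9)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl, domain="reflectance").fit(n_latent=2)
        with pytest.raises(ValueError, match="domain"):
            res.predict(X, domain="absorbance")

    def test_band_order_invariance(self):
        # permuting bands together with their wavelength labels is a pure
        # relabeling: predictions do not change
        X, y = _random_instance(seed=10)
        p = X.shape[1]
        wl = np.arange(p, dtype=float) * 5 + 400
        res = hm.MoisturePLSR(X, y, wl).fit(n_latent=3)
        perm = np.random.default_rng(0).permutation(p)
        res2 = hm.MoisturePLSR(X[:, perm], y, wl[perm]).fit(n_latent=3)
        assert np.allclose(res.predict(X), res2.predict(X[:, perm]), atol=1e-8)

    def test_sample_order_invariance(self):
        X, y = _random_instance(seed=11)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        perm = np.random.default_rng(1).permutation(len(y))
        res1 = hm.MoisturePLSR(X, y, wl).fit(n_latent=3)
        res2 = hm.MoisturePLSR(X[perm], y[perm], wl).fit(n_latent=3)
        assert np.allclose(res1.predict(X), res2.predict(X), atol=1e-8)

    def test_zero_variance_band_leaves_predictions_unchanged(self):
        X, y = _random_instance(seed=12)
        wl = np.arange(X.shape[1], dtype=float) * 5 + 400
        res1 = hm.MoisturePLSR(X, y, wl).fit(n_latent=3)
        X2 = np.hstack([X, np.full((len(y), 1), 0.7)])
        wl2 = np.append(wl, wl[-1] + 5)
        res2 = hm.MoisturePLSR(X2, y, wl2).fit(n_latent=3)
        assert np.allclose(
            res1.predict(X), res2.predict(np.hstack([X, np.full((len(y), 1), 0.7)])),
            atol=1e-8,
        )


class TestCrossValidation:
    def test_perfectly_linear_data_chooses_one_lv(self, rng):
        n = 20
        t = rng.normal(size=n)
        X = np.outer(t, rng.normal(size=8))
        y = 55 + 2 * t
        wl = np.arange(8.0) * 5 + 400
        cv = hm.MoisturePLSR(X, y, wl).cross_validate(max_lv=4)
        assert cv.chosen_lv == 1
        assert cv.rmsecv < 1e-8

    def test_loo_matches_explicit_refit_loop(self):
        data = tiny_spectrum_set(seed=13)
        chain = hm.PreprocessChain(["snv"])
        model = hm.MoisturePLSR.from_spectrum_set(data, chain)
        max_lv = 5
        cv = model.cross_validate(max_lv=max_lv, scheme="loo")

        n = data.n_samples
        preds = np.zeros((n, max_lv))
        for i in range(n):
            tr = [k for k in range(n) if k != i]
            for a in range(1, max_lv + 1):
                sub = hm.MoisturePLSR.from_spectrum_set(
                    data.subset(tr), hm.PreprocessChain(["snv"])
                )
                res = sub.fit(n_latent=a)
                preds[i, a - 1] = res.predict(data.spectra[i][None, :])[0]
        rmsecv = np.sqrt(np.mean((data.reference_moisture_pct[:, None] - preds) ** 2, axis=0))
        assert np.allclose(cv.rmsecv_by_lv, rmsecv, atol=1e-10)

    def test_leave_one_block_out_respects_blocks(self):
        data = tiny_spectrum_set(n_blocks=5, n_per_block=6, seed=14)
        model = hm.MoisturePLSR.from_spectrum_set(data)
        cv = model.cross_validate(max_lv=3, scheme="leave-one-block-out")
        assert len(cv.residuals) == data.n_samples

    def test_injected_shift_flagged_as_outlier(self):
        data = tiny_spectrum_set(n_blocks=6, n_per_block=5, seed=15)
        model = hm.MoisturePLSR.from_spectrum_set(data)
        base = model.cross_validate(max_lv=4)
        y2 = data.reference_moisture_pct.copy()
        y2[7] += 10 * base.rmsecv  # contaminate one reference value
        model2 = hm.MoisturePLSR(
            data.spectra, y2, data.wavelengths_nm, block_ids=data.block_ids
        )
        cv2 = model2.cross_validate(max_lv=4)
        assert cv2.outlier_flags[7]

    def test_chosen_lv_attains_minimum(self):
        data = tiny_spectrum_set(seed=16)
        cv = hm.MoisturePLSR.from_spectrum_set(data).cross_validate(max_lv=6)
        assert cv.rmsecv == pytest.approx(cv.rmsecv_by_lv.min())
        assert cv.chosen_lv == int(np.argmin(cv.rmsecv_by_lv)) + 1


def test_rmsecv_elbow_at_true_dimensionality(rng):
    # three independent constituents -> RMSECV collapses by the third LV
    n, p, k = 40, 25, 3
    conc = rng.uniform(0.5, 1.5, size=(n, k))
    profiles = rng.random((k, p)) + 0.2
    X = conc @ profiles
    y = 50 + 10 * conc[:, 0]
    wl = np.arange(p, dtype=float) * 5 + 400
    cv = hm.MoisturePLSR(X, np.clip(y, 1, 99), wl).cross_validate(max_lv=6)
    assert cv.rmsecv_by_lv[k - 1] / cv.rmsecv_by_lv[k - 2] < 0.5


def test_serialization_round_trip(tmp_path):
    data = tiny_spectrum_set(seed=17)
    res = hm.MoisturePLSR.from_spectrum_set(data, hm.PreprocessChain(["snv"])).fit(3)
    path = str(tmp_path / "model.json")
    res.to_json(path)
    back = hm.PLSRResults.from_json(path)
    assert np.allclose(back.predict(data.spectra), res.predict(data.spectra))
    assert back.n_latent == res.n_latent
    assert back.domain == res.domain
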