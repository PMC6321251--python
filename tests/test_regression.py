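import numpy as np
import pytest

from nirscal import (MathTreatment, SpectraSet, annotate_loadings,
                     apply_treatment, fit_mpls, fit_pls, loading_spectrum,
                     model_from_json, model_to_json, predict)
from nirscal.regression import RegressionError
from nirscal.validation import sec


def make_rank_r(rng, n=40, m=120, r=3, noise=0.0):
    """X of exact rank r with y an exact linear function of the scores."""
    scores = rng.normal(size=(n, r))
    comps = rng.normal(size=(r, m))
    X = scores @ comps + noise * rng.normal(size=(n, m))
    beta = rng.normal(size=r)
    y = scores @ beta
    return X, y


class TestPLS:
    def test_exact_recovery_rank_r(self, rng):
        X, y = make_rank_r(rng, r=4)
        model = fit_pls(X, y, 4)
        yhat = predict(model, X)
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 1 - 1e-8

    def test_single_component_loading_direction(self, rng):
        m = 150
        comp = np.exp(-((np.arange(m) - 60) / 10.0) ** 2)
        conc = rng.uniform(1, 3, size=30)
        X = np.outer(conc, comp)
        model = fit_pls(X, conc, 1)
        _, p = loading_spectrum(model, 1)
        cos = abs(p @ comp) / np.linalg.norm(comp)
        assert cos > 0.999

    def test_matches_reference_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(35, 80))
        y = rng.normal(size=35)
        for k in (1, 3, 6):
            ours = predict(fit_pls(X, y, k), X)
            ref = sklearn.PLSRegression(n_components=k, scale=False)
            ref.fit(X, y)
            theirs = ref.predict(X).ravel()
            np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_loadings_near_orthogonal_weights_orthonormal(self, rng):
        X, y = make_rank_r(rng, r=6, noise=0.3)
        model = fit_pls(X, y, 5)
        W = model.weights
        np.testing.assert_allclose(W @ W.T, np.eye(5), atol=1e-8)
        # residual sum of squares is monotone in the factor count
        for k in range(2, 6):
            r_k = np.sum((y - predict(model, X, n_factors=k)) ** 2)
            r_prev = np.sum((y - predict(model, X, n_factors=k - 1)) ** 2)
            assert r_k <= r_prev + 1e-10

    def test_sec_non_increasing_in_factors(self, default_study, snvdt_2552):
        prep = apply_treatment(default_study.spectra, snvdt_2552)
        y = default_study.truths["TPC"].values
        model = fit_mpls(prep.matrix, y, 12)
        secs = [sec(y, predict(model, prep.matrix, n_factors=k), k)
                for k in range(1, 13)]
        resid = [np.sum((y - predict(model, prep.matrix, n_factors=k)) ** 2)
                 for k in range(1, 13)]
        assert all(b <= a + 1e-10 for a, b in zip(resid, resid[1:]))

    def test_deterministic_refit_bit_identical(self, rng):
        X, y = make_rank_r(rng, r=3, noise=0.5)
        m1, m2 = fit_mpls(X, y, 4), fit_mpls(X, y, 4)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.scales, m2.scales)

    def test_rank_exceeded_rejected(self, rng):
        X, y = make_rank_r(rng, n=20, m=30, r=2)
        with pytest.raises(RegressionError):
            fit_pls(X, y, 10)


class TestMPLS:
    def test_unit_scales_reduce_to_pls(self, rng):
        X, y = make_rank_r(rng, r=4, noise=0.4)
        pls = fit_pls(X, y, 4)
        mpls_off = fit_mpls(X, y, 4, rescale_residuals=False)
        np.testing.assert_allclose(predict(mpls_off, X), predict(pls, X),
                                   atol=1e-6)

    def test_homoscedastic_residuals_equal_pls(self, rng):
        # with column-standardised X the pre-factor residual scales are all
        # exactly 1, so a single-factor MPLS fit coincides with PLS
        X = rng.normal(size=(60, 40))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        y = X[:, :5] @ rng.normal(size=5) + 0.1 * rng.normal(size=60)
        a = predict(fit_pls(X, y, 1), X)
        b = predict(fit_mpls(X, y, 1), X)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_noiseless_exact_recovery(self, rng):
        X, y = make_rank_r(rng, r=3)
        yhat = predict(fit_mpls(X, y, 3), X)
        assert np.max(np.abs(yhat - y)) < 1e-6 * max(1, np.max(np.abs(y)))

    def test_mean_spectrum_predicts_mean_y(self, rng):
        X, y = make_rank_r(rng, r=3, noise=0.5)
        model = fit_mpls(X, y, 3)
        np.testing.assert_allclose(predict(model, X.mean(axis=0)),
                                   [y.mean()], atol=1e-10)


class TestPredict:
    def test_training_set_consistency(self, rng):
        X, y = make_rank_r(rng, r=3, noise=0.2)
        model = fit_mpls(X, y, 3)
        np.testing.assert_allclose(predict(model, X), model.fitted_values,
                                   atol=1e-10)

    def test_permutation_equivariance(self, rng):
        X, y = make_rank_r(rng, r=3, noise=0.2)
        model = fit_mpls(X, y, 3)
        perm = rng.permutation(X.shape[0])
        np.testing.assert_allclose(predict(model, X[perm]),
                                   predict(model, X)[perm], atol=1e-12)

    def test_grid_mismatch_names_range(self, rng):
        X, y = make_rank_r(rng, r=2)
        model = fit_pls(X, y, 2, wavelengths=400 + 2.0 * np.arange(X.shape[1]))
        with pytest.raises(RegressionError, match="grid mismatch"):
            predict(model, X[:, :50])

    def test_snv_removed_artifact_leaves_predictions_unchanged(self, rng):
        # end-to-end: multiplicative+offset corruption of new spectra is
        # invisible after snv_dt preprocessing
        wl = 400.0 + 2.0 * np.arange(300)
        base = rng.normal(0.5, 0.05, size=(25, 300)).cumsum(axis=1) / 10
        y = rng.uniform(10, 30, size=25)
        t = MathTreatment(1, 4, 4, 1, "snv_dt")
        clean = SpectraSet(wl, base, tuple(f"S{i}" for i in range(25)))
        prep = apply_treatment(clean, t)
        model = fit_mpls(prep.matrix, y, 3)
        corrupted = SpectraSet(wl, 1.3 * base + 0.2,
                               tuple(f"S{i}" for i in range(25)))
        prep_c = apply_treatment(corrupted, t)
        np.testing.assert_allclose(predict(model, prep_c.matrix),
                                   predict(model, prep.matrix), atol=1e-8)


class TestLoadings:
    def test_unit_norm(self, rng):
        X, y = make_rank_r(rng, r=3, noise=0.2)
        model = fit_mpls(X, y, 3)
        for k in (1, 2, 3):
            _, p = loading_spectrum(model, k)
            assert abs(np.linalg.norm(p) - 1.0) < 1e-12
        with pytest.raises(RegressionError):
            loading_spectrum(model, 4)

    def test_single_band_extremum_near_band_center(self, rng):
        wl = 400.0 + 2.0 * np.arange(1050)
        comp = np.exp(-0.5 * ((wl - 1436.0) / 25.0) ** 2)
        conc = rng.uniform(1, 3, size=30)
        X = np.outer(conc, comp) + 1e-4 * rng.normal(size=(30, 1050))
        model = fit_pls(X, conc, 1, wavelengths=wl)
        wl_out, p = loading_spectrum(model, 1)
        assert abs(wl_out[np.argmax(np.abs(p))] - 1436.0) <= 10.0


class TestAnnotateLoadings:
    def _peak_loading(self, center_nm):
        wl = 400.0 + 2.0 * np.arange(1050)
        return np.exp(-0.5 * ((wl - center_nm) / 8.0) ** 2), wl

    def test_chlorophyll_band(self):
        p, wl = self._peak_loading(672.0)
        out = annotate_loadings(p, wl, top_k=1)
        assert out[0][2] == "chlorophyll (electronic)"

    def test_cellulose_band(self):
        p, wl = self._peak_loading(2278.0)
        out = annotate_loadings(p, wl, top_k=1)
        assert out[0][2] == "cellulose C-H stretch"

    def test_unassigned_outside_window(self):
        p, wl = self._peak_loading(1000.0)
        out = annotate_loadings(p, wl, top_k=1)
        assert out[0][2] == "unassigned"


class TestSerialization:
    def test_json_round_trip_bit_for_bit(self, rng, tmp_path):
        X, y = make_rank_r(rng, r=3, noise=0.3)
        model = fit_mpls(X, y, 3, wavelengths=400 + 2.0 * np.arange(X.shape[1]),
                         treatment=MathTreatment(1, 4, 4, 1, "snv_dt"),
                         analyte="TPC")
        path = tmp_path / "model.json"
        model_to_json(model, path)
        back = model_from_json(path)
        np.testing.assert_array_equal(predict(back, X), predict(model, X))
        assert back.analyte == "TPC" and back.treatment == model.treatment
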