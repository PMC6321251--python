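import numpy as np
import pytest

from nirscal import (GeneratorConfig, MathTreatment, apply_treatment,
                     center_outliers, classify_model, cross_validate,
                     generate_study, global_h, r_squared, rer, rpd, sec,
                     sep_bias_corrected)
from nirscal.validation import ValidationError


class TestSEC:
    def test_perfect_fit_zero(self):
        y = np.arange(10.0)
        assert sec(y, y, 3) == 0.0

    def test_constant_residual_closed_form(self):
        r = 0.8
        y = np.zeros(11)
        assert np.isclose(sec(y, y + r, 0), r * np.sqrt(11 / 10))

    def test_homogeneity(self, rng):
        y = rng.normal(size=20)
        yhat = y + rng.normal(size=20)
        assert np.isclose(sec(y, y + 2 * (yhat - y), 4),
                          2 * sec(y, yhat, 4))

    def test_degenerate_n(self):
        with pytest.raises(ValidationError):
            sec(np.ones(4), np.ones(4), 3)


class TestSEP:
    def test_pure_offset(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        s, b = sep_bias_corrected(y, y + 0.7)
        assert np.isclose(b, 0.7) and np.isclose(s, 0.0)

    def test_hand_computed(self):
        y = np.zeros(3)
        yhat = np.array([-1.0, 0.0, 1.0])
        s, b = sep_bias_corrected(y, yhat)
        assert np.isclose(b, 0.0) and np.isclose(s, 1.0)

    def test_translation_invariance(self, rng):
        y = rng.normal(size=15)
        yhat = y + rng.normal(size=15)
        s1, _ = sep_bias_corrected(y, yhat)
        s2, _ = sep_bias_corrected(y + 5.0, yhat + 5.0)
        assert np.isclose(s1, s2)


class TestRPDAndRER:
    def test_published_table_arithmetic(self):
        # external validation rows: SD/SEP for the two analytes
        assert round(rpd(1.85, 1.22), 2) == 1.52
        assert round(rpd(1.40, 0.77), 2) == 1.82
        # cross-validation row: SD/SECV
        assert round(rpd(3.06, 1.69), 2) == 1.81

    def test_rer_from_table_inputs(self):
        assert round(rer(10.0, 1.0), 2) == 10.00
        assert round(rer(11.66 - 5.02, 0.77), 2) == 8.62
        assert round(rer(27.97 - 20.77, 1.22), 2) == 5.90

    def test_identity_and_errors(self):
        assert rpd(1.3, 1.3) == 1.0
        with pytest.raises(ValidationError):
            rpd(1.0, 0.0)
        with pytest.raises(ValidationError):
            rer(0.0, 1.0)


class TestClassifyModel:
    @pytest.mark.parametrize("q2,rpd_p,rer_v,want", [
        (0.71, 1.82, 8.63, ("discriminate low/high", "screening", "below-10")),
        (0.40, 1.20, 5.00, ("low correlation", "unusable", "below-10")),
        (0.95, 3.50, 12.0, ("excellent", "excellent", "quantitative")),
        (0.55, 2.60, 9.0, ("rough prediction", "good", "below-10")),
        (0.85, 1.60, 10.0, ("good prediction", "screening", "quantitative")),
    ])
    def test_band_membership(self, q2, rpd_p, rer_v, want):
        assert classify_model(q2, rpd_p, rer_v) == want


class TestCrossValidate:
    def test_noiseless_rank3_selects_three_factors(self, rng):
        scores = rng.normal(size=(40, 3))
        X = scores @ rng.normal(size=(3, 60))
        y = scores @ np.array([1.0, -2.0, 0.5])
        curve = cross_validate(X, y, max_factors=8, n_groups=5, seed=3,
                               method="pls")
        assert curve.chosen_factors == 3
        assert curve.secv[2] < 1e-6 * np.std(y)

    def test_pure_noise_selects_few_factors(self, rng):
        X = rng.normal(size=(50, 40))
        y = rng.normal(size=50)
        curve = cross_validate(X, y, max_factors=10, n_groups=5, seed=11)
        assert curve.chosen_factors <= 3
        # beyond the early factors overfitting inflates SECV
        assert curve.secv[-1] >= curve.secv.min()

    def test_same_seed_identical_curve(self, rng):
        X = rng.normal(size=(30, 25))
        y = rng.normal(size=30)
        c1 = cross_validate(X, y, 6, 5, seed=9)
        c2 = cross_validate(X, y, 6, 5, seed=9)
        np.testing.assert_array_equal(c1.secv, c2.secv)
        assert c1.chosen_factors == c2.chosen_factors

    def test_small_fold_rejected(self):
        with pytest.raises(ValidationError):
            cross_validate(np.zeros((5, 4)), np.zeros(5), 2, n_groups=4)

    def test_secv_at_least_sec(self, default_study, snvdt_2552):
        # cross-validated error should not beat the calibration error
        from nirscal import fit_mpls, predict
        prep = apply_treatment(default_study.spectra, snvdt_2552)
        y = default_study.truths["TCC"].values
        curve = cross_validate(prep.matrix, y, 8, 5, seed=1)
        k = curve.chosen_factors
        model = fit_mpls(prep.matrix, y, k)
        s = sec(y, predict(model, prep.matrix), k)
        assert curve.secv[k - 1] >= s - 1e-12


class TestGlobalH:
    def test_matches_brute_force_mahalanobis(self, rng):
        X = rng.normal(size=(20, 50))
        gh, k = global_h(X, explained_variance=0.99)
        Xc = X - X.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        T = Xc @ Vt[:k].T
        Sinv = np.linalg.inv(np.cov(T, rowvar=False))
        d2 = np.einsum("ij,jk,ik->i", T, Sinv, T)
        np.testing.assert_allclose(gh, d2 / k, atol=1e-8)

    def test_mean_gh_near_one(self, rng):
        X = rng.normal(size=(200, 30))
        gh, _ = global_h(X)
        assert abs(gh.mean() - 1.0) < 0.15

    def test_mean_duplicate_not_flagged(self, rng):
        X = rng.normal(size=(30, 40))
        X[-1] = X[:-1].mean(axis=0)  # place a sample at the cloud centre
        rep = center_outliers(X, threshold=3.0)
        assert rep.gh[-1] < 0.5 and not rep.flagged[-1]

    def test_planted_outlier_flagged(self, rng):
        # a tight low-dimensional cloud with one sample displaced 10 sd
        # along the leading principal direction
        n, m = 60, 40
        X = (rng.normal(size=(n, 3)) @ rng.normal(size=(3, m))
             + rng.normal(scale=0.01, size=(n, m)))
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = Vt[0]
        sd1 = np.std(Xc @ pc1, ddof=1)
        X[0] += 10 * sd1 * pc1
        rep = center_outliers(X, threshold=3.0)
        assert rep.flagged[0]
        assert rep.sample_ids[0] in rep.flagged_ids

    def test_gh_nonnegative_on_study(self, default_study, snvdt_2552):
        prep = apply_treatment(default_study.spectra, snvdt_2552)
        rep = center_outliers(prep)
        assert np.all(rep.gh >= 0)
        assert abs(rep.gh.mean() - 1.0) < 0.2


class TestRSquared:
    def test_perfect_and_mean_prediction(self, rng):
        y = rng.normal(size=20)
        assert np.isclose(r_squared(y, y), 1.0)
        assert np.isclose(r_squared(y, np.full(20, y.mean())), 0.0)
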