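"""NLDR fitting, discrimination index, classification, hit rates."""

import numpy as np
import pandas as pd
import pytest

import nldrkit as nk
from nldrkit.model import (
    DIFFICULT,
    EASY,
    ConfusionTable,
    FitError,
    SingularCovarianceError,
    confusion,
    hit_rates,
    mahalanobis_sq,
    shared_covariance,
)

from conftest import make_cohort


class TestMahalanobis:
    def test_zero_at_mean(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert mahalanobis_sq([1.0, 2.0], [1.0, 2.0], sigma) == 0.0

    def test_euclidean_with_identity(self):
        assert mahalanobis_sq([3.0, 4.0], [0.0, 0.0], np.eye(2)) == pytest.approx(25.0)

    def test_matches_direct_solve_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 5))
        sigma = a @ a.T + 5 * np.eye(5)
        x, mu = rng.normal(size=5), rng.normal(size=5)
        expected = (x - mu) @ np.linalg.solve(sigma, x - mu)
        assert mahalanobis_sq(x, mu, sigma) == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis_sq([1.0, 2.0], [1.0], np.eye(2))


class TestFit:
    def test_priors_are_group_fractions(self, labeled):
        model = nk.fit_nldr(labeled, ("age", "area_pnf"))
        assert model.prior_difficult == pytest.approx(labeled.n_difficult / labeled.n)
        assert model.prior_easy + model.prior_difficult == pytest.approx(1.0)

    def test_identical_groups_give_constant_log_odds(self):
        # both workload groups hold the same duplicated points: the
        # Mahalanobis terms cancel and Ω(x) = log(π1/π0) everywhere
        rng = np.random.default_rng(3)
        block = rng.normal(size=(10, 2))
        x = np.vstack([block, block])
        time = np.r_[np.full(10, 100.0), np.full(10, 300.0)]
        lab = nk.dichotomize(make_cohort(x, time, columns=["age", "body_weight"]), 210.0)
        model = nk.fit_nldr(lab, ("age", "body_weight"))
        omega = model.discrimination_index(rng.normal(size=(25, 2)))
        np.testing.assert_allclose(omega, 0.0, atol=1e-12)  # log(10/10) = 0

    def test_constant_column_is_singular(self, labeled):
        df = labeled.cohort.df.copy()
        df["thick_scf"] = 5.0
        lab = nk.dichotomize(nk.Cohort(df=df), 210.0)
        with pytest.raises(SingularCovarianceError, match="thick_scf"):
            nk.fit_nldr(lab, ("age", "thick_scf"))

    def test_ridge_rescues_singularity(self, labeled):
        df = labeled.cohort.df.copy()
        df["thick_scf"] = 5.0
        lab = nk.dichotomize(nk.Cohort(df=df), 210.0)
        model = nk.fit_nldr(lab, ("age", "thick_scf"), ridge=1e-6)
        assert np.isfinite(model.weights).all()

    def test_singleton_group_rejected(self):
        x = np.arange(8, dtype=float).reshape(-1, 1)
        time = np.r_[np.full(7, 100.0), [300.0]]
        lab = nk.dichotomize(make_cohort(x, time, columns=["age"]), 210.0)
        with pytest.raises(FitError, match=">= 2"):
            nk.fit_nldr(lab, ("age",))

    def test_pooled_and_total_modes_differ(self, labeled):
        pooled = nk.fit_nldr(labeled, ("age", "area_pnf"), "pooled")
        total = nk.fit_nldr(labeled, ("age", "area_pnf"), "total")
        # (n-1)·total = (n-2)·pooled + (n0·n1/n)·ddᵀ with d = μ1 − μ0
        n, n0, n1 = labeled.n, labeled.n_easy, labeled.n_difficult
        d = total.mu_difficult - total.mu_easy
        reconstructed = ((n - 2) * pooled.sigma + (n0 * n1 / n) * np.outer(d, d)) / (n - 1)
        np.testing.assert_allclose(total.sigma, reconstructed, rtol=1e-10)
        assert not np.allclose(pooled.sigma, total.sigma)


class TestDiscriminationIndex:
    def _equal_prior_model(self, seed=5, p=3):
        rng = np.random.default_rng(seed)
        mu0, mu1 = rng.normal(size=p), rng.normal(size=p)
        a = rng.normal(size=(p, p))
        return nk.NLDRModel(subset=tuple(f"v{i}" for i in range(p)),
                            mu_easy=mu0, mu_difficult=mu1,
                            sigma=a @ a.T + p * np.eye(p),
                            n_easy=50, n_difficult=50)

    def test_zero_at_midpoint_with_equal_priors(self):
        m = self._equal_prior_model()
        mid = 0.5 * (m.mu_easy + m.mu_difficult)
        assert m.discrimination_index(mid) == pytest.approx(0.0, abs=1e-12)

    def test_negative_at_easy_mean(self):
        m = self._equal_prior_model()
        omega = m.discrimination_index(m.mu_easy)
        expected = -0.5 * mahalanobis_sq(m.mu_easy, m.mu_difficult, m.sigma)
        assert omega == pytest.approx(expected, rel=1e-9)
        assert omega < 0

    def test_quadratic_and_affine_forms_agree(self, labeled):
        subset = nk.NAMED_SETS["E"]
        model = nk.fit_nldr(labeled, subset)
        x = labeled.cohort.feature_matrix(subset)
        lo = np.log(model.prior_difficult / model.prior_easy)
        direct = np.array([
            lo - 0.5 * (mahalanobis_sq(xi, model.mu_difficult, model.sigma)
                        - mahalanobis_sq(xi, model.mu_easy, model.sigma))
            for xi in x
        ])
        np.testing.assert_allclose(model.discrimination_index(x), direct,
                                   rtol=1e-8, atol=1e-8)

    def test_missing_feature_named(self, labeled):
        model = nk.fit_nldr(labeled, ("age", "area_pnf"))
        with pytest.raises(ValueError, match="area_pnf"):
            model.discrimination_index([55.0, np.nan])

    def test_tie_resolves_to_easy(self):
        # identical group means with equal priors: Ω is exactly 0 everywhere
        m = nk.NLDRModel(subset=("v0",), mu_easy=np.array([1.0]),
                         mu_difficult=np.array([1.0]),
                         sigma=np.array([[2.0]]), n_easy=10, n_difficult=10)
        assert m.discrimination_index([7.0]) == 0.0
        assert m.classify([7.0]) == EASY

    def test_sign_rule(self, labeled):
        subset = ("area_pnf", "number_ra")
        model = nk.fit_nldr(labeled, subset)
        x = labeled.cohort.feature_matrix(subset)
        omega = model.discrimination_index(x)
        pred = model.classify(x)
        np.testing.assert_array_equal(pred == DIFFICULT, omega > 0)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_affine_invariance(self, seed):
        # Ω is unchanged by any invertible linear map + offset of the features
        rng = np.random.default_rng(seed)
        n, p = 60, 4
        x = np.vstack([rng.normal(0, 1, (40, p)), rng.normal(0.8, 1, (20, p))])
        time = np.r_[np.full(40, 100.0), np.full(20, 300.0)]
        cols = ["age", "body_weight", "body_height", "total_protein"]
        lab = nk.dichotomize(make_cohort(x, time, columns=cols), 210.0)
        m = nk.fit_nldr(lab, cols)
        omega = m.discrimination_index(x)

        L = rng.normal(size=(p, p)) + 3 * np.eye(p)
        b = rng.normal(size=p)
        xt = x @ L.T + b
        df2 = lab.cohort.df.copy()
        df2[cols] = xt
        lab2 = nk.dichotomize(nk.Cohort(df=df2), 210.0)
        m2 = nk.fit_nldr(lab2, cols)
        np.testing.assert_allclose(m2.discrimination_index(xt), omega,
                                   rtol=1e-8, atol=1e-8)

    def test_prior_shift_never_flips_difficult_to_easy(self, two_gaussian_cohort):
        lab, x = two_gaussian_cohort
        subset = ("age", "body_weight", "body_height")
        m = nk.fit_nldr(lab, subset)
        base = m.classify(x)
        for n1 in (m.n_difficult + 10, m.n_difficult + 60, m.n_difficult + 400):
            shifted = nk.NLDRModel(subset=subset, mu_easy=m.mu_easy,
                                   mu_difficult=m.mu_difficult, sigma=m.sigma,
                                   n_easy=m.n_easy, n_difficult=n1)
            pred = shifted.classify(x)
            assert not np.any((base == DIFFICULT) & (pred == EASY))


class TestConfusionAndRates:
    def test_table_from_predictions(self):
        pred = np.array([DIFFICULT, DIFFICULT, EASY, EASY, EASY])
        lab = np.array([DIFFICULT, EASY, DIFFICULT, EASY, EASY])
        t = confusion(pred, lab)
        assert t.as_tuple() == (1, 1, 1, 2)
        assert t.n == 5

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([DIFFICULT], [DIFFICULT, EASY])

    def test_back_calculated_study_table(self):
        # the unique nonnegative table with margins 21/107 that reproduces the
        # published four-demographic-variable column (verified by exhaustive
        # search over all tables in test_acceptance)
        r = hit_rates(ConfusionTable(5, 1, 16, 106))
        assert round(r.hrdc, 1) == 83.3
        assert round(r.hrec, 1) == 86.9
        assert round(r.sensitivity, 1) == 23.8
        assert round(r.specificity, 1) == 99.1
        assert round(r.total, 1) == 86.7

    def test_perfect_prediction_is_100_everywhere(self):
        r = hit_rates(ConfusionTable(21, 0, 0, 107))
        assert all(v == 100.0 for v in r.as_dict().values())

    def test_undefined_rate_reported_as_none(self):
        r = hit_rates(ConfusionTable(0, 0, 21, 107))
        assert r.hrdc is None
        assert r.total == pytest.approx(100 * 107 / 128)

    def test_perfect_total_for_any_labeling(self):
        rng = np.random.default_rng(8)
        lab = np.where(rng.random(50) < 0.3, DIFFICULT, EASY)
        assert hit_rates(confusion(lab, lab)).total == 100.0


class TestOracleEquivalence:
    def test_classify_matches_reference_lda(self, two_gaussian_cohort):
        """Predictions agree with scikit-learn's shared-covariance LDA.

        With empirical priors the reference pooled covariance differs from
        ours only by the (n−2)/n normalization, which cannot move the
        decision boundary direction; agreement is point-for-point on all
        200 donors whose |Ω| exceeds numerical noise.
        """
        from sklearn import discriminant_analysis as sklearn

        lab, x = two_gaussian_cohort
        subset = ("age", "body_weight", "body_height")
        m = nk.fit_nldr(lab, subset, "pooled")
        omega = m.discrimination_index(x)
        ours = omega > 0

        ref = sklearn.LinearDiscriminantAnalysis(solver="lsqr")
        ref.fit(x, lab.difficult.astype(int))
        theirs = ref.predict(x).astype(bool)
        clear = np.abs(omega) > 1e-9
        np.testing.assert_array_equal(ours[clear], theirs[clear])

        # discriminant directions are parallel
        w = m.weights
        cos = (w @ ref.coef_[0]) / (np.linalg.norm(w) * np.linalg.norm(ref.coef_[0]))
        assert cos == pytest.approx(1.0, abs=1e-10)


class TestSerialization:
    def test_model_round_trip_exact(self, labeled, tmp_path):
        model = nk.fit_nldr(labeled, nk.NAMED_SETS["E"])
        path = tmp_path / "model.json"
        model.save(path)
        back = nk.NLDRModel.load(path)
        assert back.subset == model.subset
        np.testing.assert_array_equal(back.mu_easy, model.mu_easy)
        np.testing.assert_array_equal(back.mu_difficult, model.mu_difficult)
        np.testing.assert_array_equal(back.sigma, model.sigma)
        assert (back.n_easy, back.n_difficult) == (model.n_easy, model.n_difficult)
        assert back.covariance_mode == model.covariance_mode
        x = labeled.cohort.feature_matrix(model.subset)
        np.testing.assert_array_equal(back.discrimination_index(x),
                                      model.discrimination_index(x))
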