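"""Partial R2, group profiles, the three-stage individual-level error against
a literal step-by-step oracle, splines, and classification metrics."""

import numpy as np
import pandas as pd
import pytest

from pgsport.distance import assign_bins, select_reference_bins
from pgsport.evaluate import (
    build_covariates,
    choose_threshold,
    classification_metrics,
    fit_density_spline,
    group_profile,
    individual_error,
    partial_r2,
    precision_recall_profile,
    stratified_profile,
    variance_explained,
)


def partial_corr_oracle(y, pgs, covariates):
    """Residual-correlation identity: squared correlation of y and PGS after
    residualizing both on the covariates."""
    n = len(y)
    C = np.column_stack([np.ones(n), covariates])
    H = C @ np.linalg.pinv(C)
    ry = y - H @ y
    rp = pgs - H @ pgs
    return float(np.corrcoef(ry, rp)[0, 1] ** 2)


class TestPartialR2:
    def test_orthogonal_pgs_gives_zero(self, rng):
        n = 50
        covar = rng.normal(size=(n, 2))
        y = covar @ [1.0, -2.0] + rng.normal(size=n)
        C = np.column_stack([np.ones(n), covar])
        resid_y = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        pgs = rng.normal(size=n)
        pgs -= np.column_stack([C, resid_y]) @ np.linalg.lstsq(
            np.column_stack([C, resid_y]), pgs, rcond=None
        )[0]  # orthogonal to covariates and to the reduced-model residual
        assert partial_r2(y, pgs, covar) == pytest.approx(0.0, abs=1e-12)

    def test_exact_fit_gives_one(self, rng):
        n = 40
        covar = rng.normal(size=(n, 2))
        pgs = rng.normal(size=n)
        y = covar @ [0.5, 1.0] + 2.0 * pgs
        assert partial_r2(y, pgs, covar) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_squared_partial_correlation(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        covar = rng.normal(size=(n, 3))
        pgs = rng.normal(size=n)
        y = covar @ rng.normal(size=3) + 0.5 * pgs + rng.normal(size=n)
        assert partial_r2(y, pgs, covar) == pytest.approx(
            partial_corr_oracle(y, pgs, covar), abs=1e-10
        )

    def test_perfect_reduced_model_rejected(self, rng):
        covar = rng.normal(size=(30, 1))
        y = 3.0 * covar[:, 0]
        with pytest.raises(ValueError):
            partial_r2(y, rng.normal(size=30), covar)


def _pheno(rng, n):
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age": rng.integers(40, 71, size=n).astype(float),
            "array_label": np.where(rng.random(n) < 0.8, "axiom", "bileve"),
        }
    )


class TestGroupProfile:
    def test_reference_bin_mean_relative_is_one(self, rng):
        n = 600
        pheno = _pheno(rng, n)
        pgs = rng.normal(size=n)
        y = 0.5 * pgs + rng.normal(size=n)
        bins = assign_bins(rng.exponential(size=n) + 1, 100)
        ref = select_reference_bins(bins, 2)
        prof = group_profile(bins, y, pgs, pheno, ref)
        assert prof["relative"][ref].mean() == pytest.approx(1.0, abs=1e-12)
        assert ((prof["value"] >= 0) & (prof["value"] <= 1)).all()

    def test_homogeneous_bins_scatter_around_one(self, rng):
        n = 4000
        pheno = _pheno(rng, n)
        pgs = rng.normal(size=n)
        y = 0.6 * pgs + rng.normal(size=n)
        bins = assign_bins(rng.normal(size=n), 500)  # distance unrelated to y
        ref = select_reference_bins(bins, 2, target=0.0)
        prof = group_profile(bins, y, pgs, pheno, ref)
        assert prof["relative"].std() < 0.4
        assert abs(prof["relative"].mean() - 1.0) < 0.3


def individual_error_literal_oracle(y, pheno, distance, bins, pgs, ref_bins,
                                    degree=20):
    """Step-by-step transcription of the three-stage residualization with a
    generic least-squares routine."""
    n = len(y)
    age = pheno["age"].to_numpy(float)
    sex = pheno["sex"].to_numpy(float)
    X = np.empty(n)
    for b in range(bins.n_bins):
        mem = bins.members(b)
        cols = [np.ones(len(mem)), age[mem] ** 2, sex[mem],
                age[mem] * sex[mem], age[mem] ** 2 * sex[mem]]
        arrays = pheno["array_label"].to_numpy()[mem]
        labels, counts = np.unique(arrays, return_counts=True)
        for lab, cnt in zip(labels[1:], counts[1:]):  # dummies, first = base
            if cnt > 1 and counts[0] > 1:
                cols.append((arrays == lab).astype(float))
        D = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(D, y[mem], rcond=None)
        X[mem] = y[mem] - D @ coef
    lo, hi = distance.min(), distance.max()
    t = 2 * (distance - lo) / (hi - lo) - 1
    V = np.polynomial.legendre.legvander(t, degree)
    D2 = np.column_stack([V, sex, sex * distance])
    coef, *_ = np.linalg.lstsq(D2, X, rcond=None)
    Z = X - D2 @ coef
    D3 = np.column_stack([np.ones(n), pgs])
    coef, *_ = np.linalg.lstsq(D3, Z, rcond=None)
    err = (Z - D3 @ coef) ** 2
    ref_members = np.isin(bins.bin_index, ref_bins)
    return err / err[ref_members].mean()


class TestIndividualError:
    def test_matches_literal_three_regression_oracle(self, rng):
        n = 200
        pheno = _pheno(rng, n)
        distance = rng.uniform(1, 4, size=n)
        bins = assign_bins(distance, 100)
        ref = np.array([0])
        pgs = rng.normal(size=n)
        y = 0.4 * pgs + 0.1 * pheno["sex"].to_numpy() + rng.normal(size=n)
        res = individual_error(y, pheno, distance, bins, pgs, ref)
        oracle = individual_error_literal_oracle(
            y, pheno, distance, bins, pgs, ref
        )
        np.testing.assert_allclose(res.standardized, oracle, atol=1e-8)
        assert res.standardized[np.isin(bins.bin_index, ref)].mean() == (
            pytest.approx(1.0, abs=1e-10)
        )

    def test_trait_equal_to_covariates_gives_zero_error(self, rng):
        n = 300
        pheno = _pheno(rng, n)
        pheno["array_label"] = "axiom"
        age = pheno["age"].to_numpy(float)
        sex = pheno["sex"].to_numpy(float)
        y = 2.0 + 0.01 * age**2 + 0.3 * sex
        distance = rng.uniform(1, 4, size=n)
        bins = assign_bins(distance, 150)
        res = individual_error(y, pheno, distance, bins, rng.normal(size=n),
                               np.array([0]))
        # Y is an exact covariate combination: Z vanishes and so do the
        # squared errors (up to round-off on a trait of magnitude ~50)
        assert np.max(np.abs(res.Z)) < 1e-8
        assert res.unstandardized.max() < 1e-18

    def test_noise_pgs_leaves_errors_as_z_deviations(self, rng):
        n = 400
        pheno = _pheno(rng, n)
        distance = rng.uniform(1, 4, size=n)
        bins = assign_bins(distance, 200)
        pgs = rng.normal(size=n)  # unrelated to the trait
        y = rng.normal(size=n)
        res = individual_error(y, pheno, distance, bins, pgs, np.array([0, 1]))
        # the step-3 regression on a noise PGS explains almost nothing, so
        # Zhat is close to the constant mean(Z) and the errors are close to
        # the squared deviations of Z around its mean
        assert np.corrcoef(res.Z, pgs)[0, 1] ** 2 < 0.1
        np.testing.assert_allclose(
            res.unstandardized, (res.Z - res.Zhat) ** 2, atol=1e-12
        )
        np.testing.assert_allclose(
            res.unstandardized, (res.Z - res.Z.mean()) ** 2,
            atol=3 * res.Z.std() ** 2,
        )


class TestDensitySpline:
    def test_constant_y_has_zero_r2(self, rng):
        x = rng.uniform(size=200)
        fit = fit_density_spline(x, np.full(200, 3.0), n_knots=4)
        assert fit.r2 == 0.0
        np.testing.assert_allclose(fit.fitted, 3.0, atol=1e-8)

    def test_cubic_signal_fit_exactly(self, rng):
        x = rng.uniform(-1, 1, size=300)
        y = 2 + x - 0.5 * x**2 + 0.25 * x**3
        fit = fit_density_spline(x, y, n_knots=6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_equal_counts_between_knots(self, rng):
        x = rng.exponential(size=800)
        y = rng.normal(size=800)
        fit = fit_density_spline(x, y, n_knots=8)
        edges = np.concatenate([[-np.inf], fit.knots, [np.inf]])
        counts = np.histogram(x, edges)[0]
        assert len(counts) == 9
        assert all(abs(c - 800 / 9) <= 1 for c in counts)

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(ValueError):
            fit_density_spline(np.arange(5.0), np.arange(5.0), n_knots=8)


class TestClassification:
    def test_direct_formula_evaluation(self):
        m = classification_metrics(
            np.array([1, 1, 1, 0, 1, 1, 0, 0], bool),
            np.array([1, 1, 1, 1, 0, 0, 0, 0], bool),
        )
        assert (m.tp, m.fp, m.fn) == (3, 1, 2)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classification(self):
        labels = np.array([1, 0, 1, 0], bool)
        m = classification_metrics(labels, labels)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_no_true_cases_gives_nan_recall(self):
        m = classification_metrics(np.zeros(4, bool), np.array([1, 0, 0, 0], bool))
        assert np.isnan(m.recall)

    def test_f1_harmonic_mean_bound(self, rng):
        for _ in range(30):
            labels = rng.random(40) < 0.4
            pred = rng.random(40) < 0.5
            m = classification_metrics(labels, pred)
            if np.isnan(m.f1):
                continue
            lo = min(m.precision, m.recall)
            assert m.f1 <= 2 * lo / (1 + lo) + 1e-12


class TestThreshold:
    def test_matches_exhaustive_oracle(self, rng):
        pgs = rng.normal(size=500)
        labels = rng.random(500) < 0.2 + 0.3 * (pgs > 0.5)
        best, best_f1 = None, -1
        for pct in range(5, 100, 5):
            thr = np.percentile(pgs, pct)
            m = classification_metrics(labels, pgs >= thr)
            if not np.isnan(m.f1) and m.f1 >= best_f1:
                best, best_f1 = pct, m.f1
        assert choose_threshold(pgs, labels) == best

    def test_perfect_separation(self, rng):
        n = 1000
        pgs = rng.normal(size=n)
        labels = pgs >= np.percentile(pgs, 70)  # prevalence 0.30
        pct = choose_threshold(pgs, labels)
        assert pct == 70
        thr = np.percentile(pgs, pct)
        assert classification_metrics(labels, pgs >= thr).f1 == 1.0

    def test_liability_threshold_tracks_prevalence(self, rng):
        n = 20000
        pgs = rng.normal(size=n)
        liab = 2.5 * pgs + rng.normal(size=n)  # strong score
        labels = liab > np.quantile(liab, 0.75)  # prevalence 0.25
        assert abs(choose_threshold(pgs, labels) - 75) <= 10

    def test_constant_pgs_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold(np.ones(10), np.array([0, 1] * 5, bool))


class TestPrecisionRecallProfile:
    def test_counts_partition_each_bin(self, rng):
        n = 600
        pgs = rng.normal(size=n)
        labels = rng.random(n) < 0.2
        bins = assign_bins(rng.exponential(size=n), 200)
        prof = precision_recall_profile(bins, pgs, labels, 75,
                                        rng.normal(size=1000))
        totals = prof[["tp", "fp", "fn", "tn"]].sum(axis=1)
        assert (totals == 200).all()


class TestVarianceExplained:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=500)
        err = 2 + 3 * x
        r2, ci = variance_explained(err, x, "linear", n_bootstrap=20)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_independent_measure_explains_nothing(self, rng):
        err = rng.exponential(size=10000)
        x = rng.normal(size=10000)
        r2, ci = variance_explained(err, x, "linear", n_bootstrap=50)
        assert r2 < 0.005
        assert ci[0] < 0.005

    def test_discretized_recovers_step_function(self, rng):
        x = rng.uniform(0, 10, size=2000)
        err = np.floor(x / 2)  # constant within each equal-width fifth
        r2, _ = variance_explained(err, x, "discretized", n_bootstrap=10)
        assert r2 > 0.99

    def test_spline_method_runs(self, rng):
        x = rng.normal(size=800)
        err = x**2 + rng.normal(size=800)
        r2, ci = variance_explained(err, x, "spline", n_bootstrap=10,
                                    n_knots=8)
        assert 0 < r2 <= 1 and ci[0] <= r2 + 0.2


class TestStratifiedProfile:
    def test_strata_sizes_differ_by_at_most_one(self, rng):
        n = 1003
        err = rng.exponential(size=n)
        measure = rng.normal(size=n)
        ranks = pd.Series(measure).rank(method="first").to_numpy()
        strata = np.ceil(ranks * 5 / n).astype(int)
        sizes = np.bincount(strata)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_single_stratum_equals_global_spline(self, rng):
        n = 500
        err = rng.exponential(size=n)
        distance = rng.exponential(size=n) + 1
        out = stratified_profile(err, rng.normal(size=n), 1, distance)
        from pgsport.evaluate import fit_density_spline

        direct = fit_density_spline(distance, err, n_knots=8)
        np.testing.assert_allclose(out[0][1].fitted, direct.fitted, atol=1e-10)

    def test_variance_gradient_orders_strata(self, rng):
        n = 5000
        measure = rng.normal(size=n)
        ranks = pd.Series(measure).rank(method="first").to_numpy()
        strata = np.ceil(ranks * 5 / n).astype(int)
        err = rng.normal(size=n) ** 2 * strata  # noisier in high strata
        distance = rng.exponential(size=n) + 1
        out = stratified_profile(err, measure, 5, distance)
        means = [fit.fitted.mean() for _, fit in out]
        assert means[-1] > means[0]
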