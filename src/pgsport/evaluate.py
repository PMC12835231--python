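"""Portability evaluation.

Group-level partial-R2 profiles across genetic-distance bins with a
reference-bin baseline, the three-stage individual-level squared prediction
error, precision/recall portability for binary traits with an F1-optimal
GWAS-set percentile threshold, density-knot cubic spline fits, and
variance-in-prediction-error-explained comparisons across candidate
predictors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

from .distance import BinAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionError",
    "ClassificationMetrics",
    "SplineFit",
    "partial_r2",
    "build_covariates",
    "group_profile",
    "individual_error",
    "fit_density_spline",
    "choose_threshold",
    "classification_metrics",
    "precision_recall_profile",
    "variance_explained",
    "stratified_profile",
]


@dataclass
class PredictionError:
    """Per-individual squared prediction error and its components."""

    unstandardized: np.ndarray  # (Z - Zhat)^2
    standardized: np.ndarray  # divided by the reference-bin baseline
    baseline: float
    Y: np.ndarray
    Yhat: np.ndarray
    X: np.ndarray
    Xhat: np.ndarray
    Z: np.ndarray
    Zhat: np.ndarray


@dataclass
class ClassificationMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else np.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if np.isnan(p) or np.isnan(r) or p + r == 0:
            return np.nan if np.isnan(p) or np.isnan(r) else 0.0
        return 2 * p * r / (p + r)


@dataclass
class SplineFit:
    knots: np.ndarray  # interior knots
    coefficients: np.ndarray
    fitted: np.ndarray  # aligned with the input order
    r2: float


def _lstsq_fit(y: np.ndarray, D: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return D @ coef


def partial_r2(y, pgs, covariates=None) -> float:
    """(SSE_reduced - SSE_full) / SSE_reduced for the nested linear models
    y ~ covariates (reduced) and y ~ covariates + PGS (full).  Equals the
    squared partial correlation between y and the PGS given the covariates.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    full = np.column_stack([C, np.asarray(pgs, dtype=float)])
    if n < full.shape[1] + 2:
        raise ValueError("too few observations for partial R2")
    sse_red = float(((y - _lstsq_fit(y, C)) ** 2).sum())
    scale = float((y**2).sum())
    if sse_red <= 1e-14 * max(scale, 1.0):
        raise ValueError("reduced model fits perfectly; partial R2 undefined")
    sse_full = float(((y - _lstsq_fit(y, full)) ** 2).sum())
    return max(0.0, (sse_red - sse_full) / sse_red)


def build_covariates(
    pheno: pd.DataFrame,
    include_array: bool = True,
    include_age_main: bool = True,
    extra: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standard covariate design: age, age^2, sex, age*sex, age^2*sex and
    (optionally) genotyping-array dummies; ``include_age_main=False`` drops
    the main age term (the convention of the per-bin residualization stage).
    """
    age = pheno["age"].to_numpy(dtype=float)
    sex = pheno["sex"].to_numpy(dtype=float)
    cols = {}
    if include_age_main:
        cols["age"] = age
    cols["age2"] = age**2
    cols["sex"] = sex
    cols["age_sex"] = age * sex
    cols["age2_sex"] = age**2 * sex
    df = pd.DataFrame(cols, index=pheno.index)
    if include_array and "array_label" in pheno:
        dummies = pd.get_dummies(pheno["array_label"], prefix="array",
                                 drop_first=True, dtype=float)
        df = pd.concat([df, dummies], axis=1)
    if extra is not None:
        extra = np.asarray(extra, dtype=float)
        for k in range(extra.shape[1]):
            df[f"extra{k}"] = extra[:, k]
    return df


def _bin_covariate_matrix(cov_df: pd.DataFrame, pheno_bin: pd.DataFrame) -> np.ndarray:
    """Drop array dummies backed by a single individual in this bin, plus any
    zero-variance column, so the per-bin design stays full rank."""
    sub = cov_df.copy()
    if "array_label" in pheno_bin:
        counts = pheno_bin["array_label"].value_counts()
        if (counts <= 1).any():  # array type represented by one individual
            sub = sub.drop(
                columns=[c for c in sub.columns if c.startswith("array_")]
            )
    keep = [c for c in sub.columns if np.asarray(sub[c]).std() > 0]
    return sub[keep].to_numpy(dtype=float)


def group_profile(
    bins: BinAssignment,
    y: np.ndarray,
    pgs: np.ndarray,
    pheno: pd.DataFrame,
    reference_bins: np.ndarray,
) -> pd.DataFrame:
    """Partial R2 of the PGS within each genetic-distance bin, normalized by
    the mean over the reference bins.

    Returns a DataFrame (bin, median_distance, value, relative) with the
    baseline stored in ``df.attrs['baseline']``.
    """
    y = np.asarray(y, dtype=float)
    pgs = np.asarray(pgs, dtype=float)
    cov_df = build_covariates(pheno)
    values = np.full(bins.n_bins, np.nan)
    for b in range(bins.n_bins):
        members = bins.members(b)
        C = _bin_covariate_matrix(cov_df.iloc[members], pheno.iloc[members])
        if len(members) < C.shape[1] + 3:
            logger.warning("bin %d too small for the covariate model; NA", b)
            continue
        try:
            values[b] = partial_r2(y[members], pgs[members], C)
        except ValueError:
            logger.warning("partial R2 undefined in bin %d; NA", b)
    baseline = float(np.nanmean(values[reference_bins]))
    out = pd.DataFrame(
        {
            "bin": np.arange(bins.n_bins),
            "median_distance": bins.bin_median_distance,
            "value": values,
            "relative": values / baseline,
        }
    )
    out.attrs["baseline"] = baseline
    return out


def _orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal degree-``degree`` polynomial basis (including constant).

    A raw power-basis Vandermonde at degree 20 is numerically singular over
    a right-skewed distance distribution, so the polynomial is parameterized
    in Legendre polynomials on the min-max-mapped domain [-1, 1] and then
    QR-orthonormalized; only fitted values are ever used, never
    coefficients."""
    lo, hi = x.min(), x.max()
    t = 2 * (x - lo) / (hi - lo if hi > lo else 1.0) - 1
    V = np.polynomial.legendre.legvander(t, degree)
    Q, _ = np.linalg.qr(V)
    return Q


def individual_error(
    y: np.ndarray,
    pheno: pd.DataFrame,
    distance: np.ndarray,
    bins: BinAssignment,
    pgs: np.ndarray,
    reference_bins: np.ndarray,
    poly_degree: int = 20,
) -> PredictionError:
    """Three-stage individual-level squared prediction error.

    1. Within each bin, regress the raw trait Y on array type + age^2 + sex
       + age*sex + age^2*sex (array dropped where a bin has a single
       individual of an array type); X = Y - Yhat.
    2. Globally regress X on a ``poly_degree``-degree polynomial in genetic
       distance + sex + sex*distance; Z = X - Xhat.
    3. Regress Z on the PGS in a univariate regression; the unstandardized
       squared prediction error is (Z - Zhat)^2, standardized by its mean
       over reference-bin members.
    """
    y = np.asarray(y, dtype=float)
    pgs = np.asarray(pgs, dtype=float)
    distance = np.asarray(distance, dtype=float)
    n = len(y)
    cov_df = build_covariates(pheno, include_age_main=False)

    Yhat = np.empty(n)
    for b in range(bins.n_bins):
        members = bins.members(b)
        C = _bin_covariate_matrix(cov_df.iloc[members], pheno.iloc[members])
        D = np.column_stack([np.ones(len(members)), C])
        Yhat[members] = _lstsq_fit(y[members], D)
    X = y - Yhat

    sex = pheno["sex"].to_numpy(dtype=float)
    P = _orthogonal_poly(distance, poly_degree)
    D2 = np.column_stack([P, sex, sex * distance])
    Xhat = _lstsq_fit(X, D2)
    Z = X - Xhat

    D3 = np.column_stack([np.ones(n), pgs])
    Zhat = _lstsq_fit(Z, D3)
    err = (Z - Zhat) ** 2

    ref_members = np.isin(bins.bin_index, reference_bins)
    baseline = float(err[ref_members].mean())
    if baseline <= 0:
        raise ValueError("reference-bin baseline error is zero")
    return PredictionError(
        unstandardized=err,
        standardized=err / baseline,
        baseline=baseline,
        Y=y, Yhat=Yhat, X=X, Xhat=Xhat, Z=Z, Zhat=Zhat,
    )


def _density_knots(x_sorted: np.ndarray, n_knots: int) -> np.ndarray:
    """Interior knots at equal-count quantiles: n_knots knots cut the sample
    into n_knots + 1 intervals of (near) equal occupancy."""
    qs = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(x_sorted, qs)
    uniq = np.unique(knots)
    if len(uniq) < len(knots):
        warnings.warn("duplicate knots merged (heavy ties in x)", stacklevel=2)
    # keep knots strictly inside the data range
    return uniq[(uniq > x_sorted[0]) & (uniq < x_sorted[-1])]


def fit_density_spline(x, y, n_knots: int = 8) -> SplineFit:
    """Least-squares cubic B-spline of y on x with interior knots placed so
    that equal numbers of points fall between consecutive knots.  R2 of a
    constant y is 0 by convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if len(np.unique(xs)) <= n_knots + 4:
        raise ValueError("too few distinct x values for the requested knots")
    knots = _density_knots(xs, n_knots)
    # LSQUnivariateSpline needs strictly increasing x; average y over ties
    xu, inv = np.unique(xs, return_inverse=True)
    if len(xu) < len(xs):
        w = np.bincount(inv).astype(float)
        yu = np.bincount(inv, weights=ys) / w
        spl = LSQUnivariateSpline(xu, yu, knots, k=3, w=np.sqrt(w))
    else:
        spl = LSQUnivariateSpline(xs, ys, knots, k=3)
    fitted = np.empty_like(y)
    fitted[order] = spl(xs)
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - fitted) ** 2).sum())
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    return SplineFit(knots=knots, coefficients=spl.get_coeffs(),
                     fitted=fitted, r2=r2)


def classification_metrics(labels, predicted) -> ClassificationMetrics:
    labels = np.asarray(labels, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    return ClassificationMetrics(
        tp=int((labels & predicted).sum()),
        fp=int((~labels & predicted).sum()),
        fn=int((labels & ~predicted).sum()),
        tn=int((~labels & ~predicted).sum()),
    )


def choose_threshold(pgs_gwas, labels_gwas, grid_step: int = 5) -> int:
    """The GWAS-set PGS percentile (on a grid of ``grid_step`` increments)
    that maximizes F1 for classifying GWAS individuals as cases when their
    PGS is at or above the percentile value.  Ties go to the higher
    percentile (fewer predicted positives)."""
    pgs = np.asarray(pgs_gwas, dtype=float)
    labels = np.asarray(labels_gwas, dtype=bool)
    if pgs.std() == 0:
        raise ValueError("degenerate (constant) PGS")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present in the GWAS set")
    best_pct, best_f1 = None, -np.inf
    for pct in range(grid_step, 100, grid_step):
        thr = np.percentile(pgs, pct)
        f1 = classification_metrics(labels, pgs >= thr).f1
        if np.isnan(f1):
            continue
        if f1 >= best_f1:
            best_f1, best_pct = f1, pct
    return best_pct


def precision_recall_profile(
    bins: BinAssignment,
    pgs: np.ndarray,
    labels: np.ndarray,
    percentile: float,
    pgs_gwas: np.ndarray,
) -> pd.DataFrame:
    """Per-bin precision/recall/F1 against a fixed GWAS-set PGS percentile
    threshold.  Bins with no predicted cases get NaN precision; bins with no
    true cases get NaN recall (both logged)."""
    thr = np.percentile(np.asarray(pgs_gwas, dtype=float), percentile)
    pgs = np.asarray(pgs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rows = []
    for b in range(bins.n_bins):
        members = bins.members(b)
        m = classification_metrics(labels[members], pgs[members] >= thr)
        if m.tp + m.fp == 0:
            logger.info("bin %d: no predicted cases; precision NA", b)
        if m.tp + m.fn == 0:
            logger.info("bin %d: no true cases; recall NA", b)
        rows.append(
            {
                "bin": b,
                "median_distance": bins.bin_median_distance[b],
                "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold_percentile"] = percentile
    out.attrs["threshold_value"] = float(thr)
    return out


def _fit_measure(err: np.ndarray, x: np.ndarray, method: str,
                 n_knots: int = 16) -> float:
    """R2 of squared prediction error on a measure, by one of three models."""
    if method == "linear":
        D = np.column_stack([np.ones(len(x)), x])
        fitted = _lstsq_fit(err, D)
    elif method == "discretized":
        edges = np.linspace(x.min(), x.max(), 6)  # 5 equal-width bins
        which = np.clip(np.digitize(x, edges[1:-1]), 0, 4)
        counts = np.bincount(which, minlength=5)
        while (counts == 0).any():  # merge an empty bin into its neighbor
            warnings.warn("empty width-bin merged with neighbor", stacklevel=3)
            empty = int(np.where(counts == 0)[0][0])
            which[which >= max(empty, 1)] -= 1
            counts = np.bincount(which)
        means = np.bincount(which, weights=err) / np.bincount(which)
        fitted = means[which]
    elif method == "spline":
        fitted = fit_density_spline(x, err, n_knots=n_knots).fitted
    else:
        raise ValueError(f"unknown method: {method!r}")
    sst = float(((err - err.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    return 1.0 - float(((err - fitted) ** 2).sum()) / sst


def variance_explained(
    error: PredictionError | np.ndarray,
    measure: np.ndarray,
    method: str = "linear",
    n_bootstrap: int = 1000,
    seed: int = 0,
    n_knots: int = 16,
) -> tuple[float, tuple[float, float]]:
    """R2 of squared prediction error explained by a measure, with a 95%
    central percentile-bootstrap confidence interval over individuals.

    ``method`` is 'linear' (OLS), 'discretized' (five equal-width bins with
    one predicted value each) or 'spline' (cubic, ``n_knots`` density knots).
    """
    err = error.standardized if isinstance(error, PredictionError) else np.asarray(error, dtype=float)
    x = np.asarray(measure, dtype=float)
    r2 = _fit_measure(err, x, method, n_knots)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    n = len(err)
    for i in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            boots[i] = _fit_measure(err[idx], x[idx], method, n_knots)
        except ValueError:
            boots[i] = np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return r2, (float(lo), float(hi))


def stratified_profile(
    error: PredictionError | np.ndarray,
    strata_measure: np.ndarray,
    n_strata: int,
    distance: np.ndarray,
    n_knots: int = 8,
) -> list:
    """Split individuals into ``n_strata`` equal-size strata of a measure
    (e.g. a deprivation index) and fit the squared-error-vs-distance density
    spline within each.  Returns a list of (stratum label, SplineFit or
    None)."""
    err = error.standardized if isinstance(error, PredictionError) else np.asarray(error, dtype=float)
    x = np.asarray(strata_measure, dtype=float)
    ranks = pd.Series(x).rank(method="first").to_numpy()
    strata = np.ceil(ranks * n_strata / len(x)).astype(int)
    out = []
    for s in range(1, n_strata + 1):
        mask = strata == s
        try:
            fit = fit_density_spline(distance[mask], err[mask], n_knots=n_knots)
        except ValueError:
            logger.warning("stratum %d too small for spline; NA", s)
            fit = None
        out.append((s, fit))
    return out
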