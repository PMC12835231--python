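"""Marginal association testing, greedy LD clumping, and
clumping-and-thresholding (C+T) polygenic scores.

The linear scan is implemented with Frisch–Waugh–Lovell residualization:
trait and every dosage column are residualized on the covariates once, after
which each variant's effect, standard error and p-value equal those of the
per-variant joint OLS fit exactly.  Binary traits use per-variant logistic
regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PGSModel",
    "ClumpThresholdScorer",
    "marginal_gwas",
    "logistic_gwas",
    "ld_r2",
    "clump",
    "build_pgs",
    "score_pgs",
]


@dataclass
class PGSModel:
    """Index variants and weights of a clumping-and-thresholding score."""

    index_variants: list  # ordered variant ids
    weights: np.ndarray  # effect estimates, per effect allele
    effect_alleles: list
    p_threshold: float
    clump_params: tuple = (0.01, 0.2, 250.0)  # (p1, r2, window_kb)

    @property
    def n_variants(self) -> int:
        return len(self.index_variants)


def _design(covariates, n: int) -> np.ndarray:
    """Covariate design with intercept; accepts None, array or DataFrame."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of C (via QR)."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def marginal_gwas(dosages, y, covariates=None, variant_ids=None) -> pd.DataFrame:
    """Per-variant least-squares association of a continuous trait.

    Returns a DataFrame with columns variant, beta, se, p, freq, n.  Variants
    that are monomorphic or collinear with the covariates get NaN estimates
    and are logged.
    """
    X = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    C = _design(covariates, n)
    df_resid = n - C.shape[1] - 1
    if df_resid < 1:
        raise ValueError("not enough observations for the covariate model")
    y_r = _residualize(y[:, None], C)[:, 0]
    G_r = _residualize(X, C)
    gss = (G_r**2).sum(axis=0)
    raw_ss = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    bad = gss <= np.maximum(1e-12, 1e-10 * np.maximum(raw_ss, 1.0))
    if bad.any():
        logger.info("skipping %d monomorphic/collinear variants", int(bad.sum()))
    gss_safe = np.where(bad, 1.0, gss)
    beta = (G_r * y_r[:, None]).sum(axis=0) / gss_safe
    sse = (y_r**2).sum() - beta**2 * gss_safe
    se = np.sqrt(np.maximum(sse, 0.0) / df_resid / gss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df_resid)
    beta[bad] = se[bad] = p[bad] = np.nan
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "variant": list(variant_ids),
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "effect_allele": "alt",
            "freq": X.mean(axis=0) / 2.0,
            "n": n,
        }
    )


def logistic_gwas(dosages, disease, covariates=None, variant_ids=None) -> pd.DataFrame:
    """Per-variant logistic regression; beta is the log-odds per effect
    allele.  Variants with separation or non-convergence are flagged NaN."""
    import statsmodels.api as sm

    X = np.asarray(dosages, dtype=float)
    y = np.asarray(disease, dtype=float)
    n, m = X.shape
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("both case and control classes must be present")
    C = _design(covariates, n)
    null_fit = sm.Logit(y, C).fit(disp=0)
    start = np.append(null_fit.params, 0.0)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    for j in range(m):
        g = X[:, j]
        if g.std() == 0:
            continue
        design = np.column_stack([C, g])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                fit = sm.Logit(y, design).fit(
                    disp=0, start_params=start, maxiter=100
                )
            if not fit.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            beta[j] = fit.params[-1]
            se[j] = fit.bse[-1]
            p[j] = fit.pvalues[-1]
        except Exception:
            logger.info("logistic fit failed for variant %d (separation?)", j)
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "variant": list(variant_ids),
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "effect_allele": "alt",
            "freq": X.mean(axis=0) / 2.0,
            "n": n,
        }
    )


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance dosage vector")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def clump(
    stats_df: pd.DataFrame,
    dosages,
    positions,
    chromosomes,
    p1: float = 0.01,
    r2_max: float = 0.2,
    window_kb: float = 250.0,
) -> list:
    """Greedy LD clumping.

    Repeatedly take the unclaimed variant with the smallest p-value below
    ``p1`` as an index variant, then claim every unclaimed variant on the
    same chromosome within ``window_kb`` whose squared dosage correlation
    with the index reaches ``r2_max``.  P-value ties are broken by smaller
    standard error, then variant id.  Returns the ordered list of index
    variant ids.
    """
    X = np.asarray(dosages, dtype=float)
    pos = np.asarray(positions, dtype=float)
    chrom = np.asarray(chromosomes)
    pvals = stats_df["p"].to_numpy()
    ses = stats_df["se"].to_numpy()
    ids = stats_df["variant"].to_numpy()
    window = window_kb * 1000.0

    candidates = np.where(~np.isnan(pvals) & (pvals < p1))[0]
    # deterministic processing order: p, then se, then variant id
    order = candidates[
        np.lexsort((ids[candidates], ses[candidates], pvals[candidates]))
    ]
    claimed = np.zeros(len(pvals), dtype=bool)
    index = []
    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)
    for j in order:
        if claimed[j]:
            continue
        claimed[j] = True
        index.append(ids[j])
        near = np.where(
            ~claimed & (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window)
        )[0]
        if len(near) == 0:
            continue
        ok = sd[near] > 0
        if sd[j] > 0 and ok.any():
            r = (Xc[:, near[ok]].T @ Xc[:, j]) / (len(X) * sd[near[ok]] * sd[j])
            hit = near[ok][r**2 >= r2_max]
            claimed[hit] = True
    return index


def build_pgs(
    index_variants: list,
    stats_df: pd.DataFrame,
    p_threshold: float = 1e-5,
    clump_params: tuple = (0.01, 0.2, 250.0),
) -> PGSModel:
    """Retain index variants with p below the inclusion threshold; weights
    are the marginal effect estimates."""
    s = stats_df.set_index("variant")
    kept = [v for v in index_variants if s.loc[v, "p"] < p_threshold]
    if not kept:
        warnings.warn("empty PGS model: no index variant passes the threshold",
                      stacklevel=2)
    return PGSModel(
        index_variants=kept,
        weights=s.loc[kept, "beta"].to_numpy(dtype=float),
        effect_alleles=list(s.loc[kept, "effect_allele"]) if kept else [],
        p_threshold=p_threshold,
        clump_params=clump_params,
    )


def score_pgs(
    dosages,
    model: PGSModel,
    variant_ids,
    effect_alleles=None,
    average: bool = False,
) -> np.ndarray:
    """PGS_i = sum_j beta_j * dosage_ij over the model's index variants.

    The weighted allele-count sum is the default dialect (the one a PGS
    variance decomposition over index-SNP heterozygosities assumes);
    ``average=True`` divides by twice the number of model variants.  Variants
    whose stored effect allele differs from the target data's are counted on
    the flipped dosage 2 - d, with a logged count.
    """
    X = np.asarray(dosages, dtype=float)
    col = {v: j for j, v in enumerate(variant_ids)}
    missing = [v for v in model.index_variants if v not in col]
    if missing:
        raise KeyError(f"model variants absent from genotypes: {missing}")
    if model.n_variants == 0:
        warnings.warn("scoring with an empty PGS model; all scores zero",
                      stacklevel=2)
        return np.zeros(X.shape[0])
    idx = np.array([col[v] for v in model.index_variants])
    D = X[:, idx]
    if effect_alleles is not None:
        alleles = np.asarray(list(effect_alleles))[idx]
        flip = alleles != np.asarray(model.effect_alleles)
        if flip.any():
            logger.info("flipped %d variants to the model effect allele",
                        int(flip.sum()))
            D = np.where(flip, 2.0 - D, D)
    score = D @ model.weights
    if average:
        score = score / (2 * model.n_variants)
    return score


class ClumpThresholdScorer(BaseEstimator, RegressorMixin):
    """Clumping-and-thresholding polygenic score as a fit/predict estimator.

    ``fit(X, y)`` runs the marginal GWAS (linear for continuous y, logistic
    when ``binary=True``) with the supplied covariates, greedily clumps by
    p-value and local LD, and keeps index variants below ``p_threshold``.
    ``predict(X)`` returns the weighted allele-count score.

    Parameters follow the conventional C+T settings: clump_p1=0.01,
    clump_r2=0.2, clump_kb=250, p_threshold=1e-5.
    """

    def __init__(
        self,
        clump_p1: float = 0.01,
        clump_r2: float = 0.2,
        clump_kb: float = 250.0,
        p_threshold: float = 1e-5,
        binary: bool = False,
        average: bool = False,
    ):
        self.clump_p1 = clump_p1
        self.clump_r2 = clump_r2
        self.clump_kb = clump_kb
        self.p_threshold = p_threshold
        self.binary = binary
        self.average = average

    def fit(self, X, y, *, covariates=None, positions=None, chromosomes=None,
            variant_ids=None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if positions is None:
            positions = np.arange(m) * 1_000_000  # effectively unlinked
        if chromosomes is None:
            chromosomes = np.ones(m, dtype=int)
        run = logistic_gwas if self.binary else marginal_gwas
        self.summary_ = run(X, y, covariates=covariates, variant_ids=variant_ids)
        index = clump(
            self.summary_, X, positions, chromosomes,
            p1=self.clump_p1, r2_max=self.clump_r2, window_kb=self.clump_kb,
        )
        self.model_ = build_pgs(
            index, self.summary_, p_threshold=self.p_threshold,
            clump_params=(self.clump_p1, self.clump_r2, self.clump_kb),
        )
        self.variant_ids_ = list(self.summary_["variant"])
        self.n_features_in_ = m
        return self

    def predict(self, X) -> np.ndarray:
        return score_pgs(
            X, self.model_, self.variant_ids_, average=self.average
        )
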