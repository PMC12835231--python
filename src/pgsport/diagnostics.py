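"""Trait-architecture diagnostics.

Heterozygosity of index SNPs by effect-size strata across genetic-distance
bins, per-bin PGS variance relative to the reference bins (with its trend on
distance), per-SNP heritability, and re-estimation of index-SNP effects in
close/far subsets of the prediction sample (relative effect ratios and
sign-flip fractions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import BinAssignment, GeneticDistancePCA
from .gwas import PGSModel, marginal_gwas

logger = logging.getLogger(__name__)

__all__ = [
    "heterozygosity",
    "snp_heritability",
    "stratify_effects",
    "het_by_bin",
    "pgs_variance_by_bin",
    "reestimate_effects",
]

STRATA_LABELS = ("small", "medium", "large")


def heterozygosity(p):
    """Hardy–Weinberg heterozygosity 2p(1-p)."""
    p = np.asarray(p, dtype=float)
    return 2 * p * (1 - p)


def snp_heritability(p, beta_hat):
    """Trait variance explained by one SNP: 2p(1-p) * beta^2."""
    return heterozygosity(p) * np.asarray(beta_hat, dtype=float) ** 2


def stratify_effects(model: PGSModel) -> pd.Series:
    """Label index SNPs small/medium/large by terciles of squared effect
    estimate; ties broken by variant id; sizes equal up to 1 (earlier
    terciles take the remainder)."""
    if model.n_variants < 3:
        raise ValueError("need at least 3 index SNPs to stratify")
    ids = np.asarray(model.index_variants)
    b2 = model.weights**2
    order = np.lexsort((ids, b2))
    parts = np.array_split(order, 3)
    labels = np.empty(model.n_variants, dtype=object)
    for lab, part in zip(STRATA_LABELS, parts):
        labels[part] = lab
    return pd.Series(labels, index=ids, name="stratum")


def _effect_freqs(dosages: np.ndarray) -> np.ndarray:
    return dosages.mean(axis=0) / 2.0


def het_by_bin(
    dosages: np.ndarray,
    variant_ids,
    model: PGSModel,
    bins: BinAssignment,
    strata: pd.Series,
) -> pd.DataFrame:
    """Mean index-SNP heterozygosity per (bin, effect-size stratum), from
    effect-allele frequencies among bin members."""
    col = {v: j for j, v in enumerate(variant_ids)}
    idx = np.array([col[v] for v in model.index_variants])
    rows = []
    for b in range(bins.n_bins):
        members = bins.members(b)
        p_b = _effect_freqs(np.asarray(dosages, dtype=float)[members][:, idx])
        het = heterozygosity(p_b)
        for lab in STRATA_LABELS:
            mask = (strata.to_numpy() == lab)
            rows.append(
                {
                    "bin": b,
                    "median_distance": bins.bin_median_distance[b],
                    "stratum": lab,
                    "mean_het": float(het[mask].mean()) if mask.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    if sxx == 0:  # a single bin (or all-equal medians) has no trend
        return float("nan")
    return float((xc * (y - y.mean())).sum() / sxx)


def pgs_variance_by_bin(
    pgs: np.ndarray,
    bins: BinAssignment,
    reference_bins: np.ndarray,
) -> pd.DataFrame:
    """Per-bin sample variance of the PGS relative to the mean variance over
    reference bins, with the OLS slope of relative variance on bin median
    distance in ``df.attrs['slope']``."""
    pgs = np.asarray(pgs, dtype=float)
    var = np.array([pgs[bins.members(b)].var(ddof=1) for b in range(bins.n_bins)])
    ref = float(var[np.asarray(reference_bins)].mean())
    rel = var / ref
    out = pd.DataFrame(
        {
            "bin": np.arange(bins.n_bins),
            "median_distance": bins.bin_median_distance,
            "variance": var,
            "relative": rel,
        }
    )
    out.attrs["slope"] = _ols_slope(bins.bin_median_distance, rel)
    return out


def reestimate_effects(
    dosages: np.ndarray,
    y: np.ndarray,
    covariates,
    model: PGSModel,
    variant_ids,
    subset_mask: np.ndarray,
    n_pcs: int = 20,
    rng_seed: int = 0,
) -> dict:
    """Re-estimate index-SNP effects within a subset of samples and compare
    them with the original GWAS estimates.

    The subset GWAS adjusts for ``n_pcs`` principal components recomputed on
    the subset's own genotype matrix (on top of the supplied covariates).
    Returns per-SNP ratios beta_subset / beta_gwas, their mean and SD, and
    the sign-flip fraction.  Index SNPs with a zero original estimate are
    excluded from ratios with a log entry.
    """
    subset_mask = np.asarray(subset_mask, dtype=bool)
    X = np.asarray(dosages, dtype=float)[subset_mask]
    y_s = np.asarray(y, dtype=float)[subset_mask]
    C = None if covariates is None else np.asarray(covariates, dtype=float)[subset_mask]

    if n_pcs > 0:
        freq = X.mean(axis=0) / 2.0
        poly = (freq > 0) & (freq < 1)
        est = GeneticDistancePCA(n_components=min(n_pcs, min(X.shape[0], int(poly.sum())) - 1))
        est.fit(X[:, poly], gwas_mask=np.ones(X.shape[0], dtype=bool))
        pcs = est.coords_
        C = pcs if C is None else np.column_stack([C, pcs])

    stats_sub = marginal_gwas(X, y_s, covariates=C, variant_ids=variant_ids)
    s = stats_sub.set_index("variant")
    beta_sub = s.loc[model.index_variants, "beta"].to_numpy(dtype=float)
    beta_orig = model.weights

    ok = beta_orig != 0
    if (~ok).any():
        logger.info("excluding %d index SNPs with zero original effect",
                    int((~ok).sum()))
    ok &= ~np.isnan(beta_sub)
    ratios = beta_sub[ok] / beta_orig[ok]
    flips = np.sign(beta_sub[ok]) != np.sign(beta_orig[ok])
    return {
        "ratios": ratios,
        "mean_ratio": float(ratios.mean()),
        "sd_ratio": float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan,
        "sign_flip_fraction": float(flips.mean()),
        "n_snps": int(ok.sum()),
    }
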