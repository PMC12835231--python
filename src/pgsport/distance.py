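"""Genetic distance from the GWAS sample.

Joint PCA of the standardized genotype matrix, eigenvalue-weighted Euclidean
distance of each individual from the centroid of GWAS-sample coordinates,
standardization so the GWAS-sample mean distance is 1, per-individual
Weir–Cockerham FST as the slower gold standard the distance proxies,
percentile filtering, and equal-size distance binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticDistancePCA",
    "PCAModel",
    "DistanceResult",
    "BinAssignment",
    "compute_pca",
    "genetic_distance",
    "standardize_distances",
    "wc_fst",
    "wc_fst_individual",
    "percentile_filter",
    "assign_bins",
    "select_reference_bins",
]


@dataclass
class PCAModel:
    """Loadings, eigenvalues and the GWAS-sample centroid of a joint PCA."""

    loadings: np.ndarray  # (M, K)
    eigenvalues: np.ndarray  # (K,), nonincreasing
    centroid: np.ndarray  # (K,)
    freq_ref: np.ndarray  # (M,) standardization frequencies
    n_components: int


@dataclass
class DistanceResult:
    raw: np.ndarray
    standardized: np.ndarray
    gwas_mean_raw: float


@dataclass
class BinAssignment:
    bin_index: np.ndarray  # per individual
    bin_size: int
    bin_median_distance: np.ndarray  # per bin
    order: np.ndarray  # sort permutation used

    @property
    def n_bins(self) -> int:
        return len(self.bin_median_distance)

    def members(self, b: int) -> np.ndarray:
        return np.where(self.bin_index == b)[0]


class GeneticDistancePCA(BaseEstimator, TransformerMixin):
    """Eigenvalue-weighted PC distance from the GWAS-sample centroid.

    Fit performs a single joint PCA of the variant-standardized dosage
    matrix (GWAS + prediction samples together; dosages are centred and
    scaled per variant by the full-sample allele frequency, (d - 2p) /
    sqrt(2p(1-p))).  ``transform`` maps dosages to standardized genetic
    distance — the weighted Euclidean distance sqrt(sum_k w_k (x_k - c_k)^2)
    with weights w_k proportional to eigenvalues, divided by the GWAS-sample
    mean raw distance so the GWAS mean is 1.

    Parameters
    ----------
    n_components : int, default 40
        Number of retained PCs, K.

    Attributes (after fit)
    ----------------------
    loadings_ : (M, K) variant loadings.
    eigenvalues_ : (K,) nonincreasing eigenvalues of the standardized
        genotype covariance.
    centroid_ : (K,) mean coordinates of GWAS-sample individuals.
    coords_ : (N, K) PC coordinates of the fitted samples.
    gwas_mean_raw_ : float, the standardization divisor.
    """

    def __init__(self, n_components: int = 40):
        self.n_components = n_components

    def fit(self, X, y=None, *, gwas_mask):
        X = np.asarray(X, dtype=float)
        gwas_mask = np.asarray(gwas_mask, dtype=bool)
        n, m = X.shape
        if self.n_components < 1 or self.n_components > min(n, m):
            raise ValueError("n_components must lie in [1, min(N, M)]")
        if not gwas_mask.any():
            raise ValueError("gwas_mask selects no samples")
        p = X.mean(axis=0) / 2.0
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("monomorphic variant reached PCA; run variant QC first")
        S = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
        k = self.n_components
        if min(n, m) <= 3000:
            U, s, Vt = np.linalg.svd(S, full_matrices=False)
            U, s, Vt = U[:, :k], s[:k], Vt[:k]
        else:
            U, s, Vt = randomized_svd(S, n_components=k, n_iter=7, random_state=0)
        self.freq_ref_ = p
        self.eigenvalues_ = s**2 / (n - 1)
        self.loadings_ = Vt.T
        self.coords_ = U * s
        self.centroid_ = self.coords_[gwas_mask].mean(axis=0)
        self.gwas_mask_ = gwas_mask
        raw = genetic_distance(self.coords_, self.model_)
        self.gwas_mean_raw_ = float(raw[gwas_mask].mean())
        if self.gwas_mean_raw_ == 0:
            raise ValueError("GWAS-sample mean raw distance is zero")
        self.n_features_in_ = m
        return self

    @property
    def model_(self) -> PCAModel:
        return PCAModel(
            loadings=self.loadings_,
            eigenvalues=self.eigenvalues_,
            centroid=self.centroid_,
            freq_ref=self.freq_ref_,
            n_components=self.n_components,
        )

    def coordinates(self, X) -> np.ndarray:
        """Project dosages onto the fitted PC axes."""
        X = np.asarray(X, dtype=float)
        p = self.freq_ref_
        return (X - 2 * p) / np.sqrt(2 * p * (1 - p)) @ self.loadings_

    def transform(self, X) -> np.ndarray:
        """Standardized genetic distance of each sample in X."""
        raw = genetic_distance(self.coordinates(X), self.model_)
        return raw / self.gwas_mean_raw_

    def fit_distances(self, X, gwas_mask) -> DistanceResult:
        """Fit and return distances of the fitted samples themselves."""
        self.fit(X, gwas_mask=gwas_mask)
        raw = genetic_distance(self.coords_, self.model_)
        return standardize_distances(raw, gwas_mask)


def compute_pca(G, n_components: int, gwas_mask: np.ndarray | None = None):
    """Functional wrapper: fitted GeneticDistancePCA for a GenotypeMatrix."""
    if gwas_mask is None:
        gwas_mask = G.gwas_mask
    est = GeneticDistancePCA(n_components=n_components)
    est.fit(G.dosages, gwas_mask=gwas_mask)
    return est


def genetic_distance(coords: np.ndarray, model: PCAModel) -> np.ndarray:
    """sqrt(sum_k w_k (x_k - c_k)^2) with w_k = lambda_k / sum(lambda)."""
    lam = np.asarray(model.eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("negative eigenvalue")
    w = lam / lam.sum()
    x = np.atleast_2d(np.asarray(coords, dtype=float))
    if x.shape[1] != len(model.centroid):
        raise ValueError("coordinate/centroid length mismatch")
    d = np.sqrt(((x - model.centroid) ** 2 * w).sum(axis=1))
    return d if np.asarray(coords).ndim > 1 else float(d[0])


def standardize_distances(raw: np.ndarray, gwas_mask: np.ndarray) -> DistanceResult:
    """Divide raw distances by the GWAS-sample mean raw distance."""
    raw = np.asarray(raw, dtype=float)
    gwas_mask = np.asarray(gwas_mask, dtype=bool)
    if not gwas_mask.any():
        raise ValueError("gwas_mask selects no samples")
    mean_raw = float(raw[gwas_mask].mean())
    if mean_raw == 0:
        raise ValueError("GWAS mean raw distance is zero")
    return DistanceResult(raw=raw, standardized=raw / mean_raw, gwas_mean_raw=mean_raw)


def _wc_components(n_i, p_i, h_i):
    """Per-locus Weir–Cockerham (1984) variance components a, b, c.

    n_i: (r,) diploid sample sizes; p_i: (r, L) allele frequencies;
    h_i: (r, L) observed heterozygote proportions.
    """
    n_i = np.asarray(n_i, dtype=float)
    r = len(n_i)
    nbar = n_i.mean()
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    w = (n_i / (r * nbar))[:, None]
    pbar = (w * p_i).sum(axis=0)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (w * h_i).sum(axis=0)
    a = (nbar / n_c) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_fst(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Multi-locus Weir–Cockerham FST between two diploid samples,
    ratio-of-sums estimator sum(a) / sum(a + b + c) over loci."""
    A = np.atleast_2d(np.asarray(dosages_a, dtype=float))
    B = np.atleast_2d(np.asarray(dosages_b, dtype=float))
    n_i = np.array([A.shape[0], B.shape[0]])
    p_i = np.vstack([A.mean(axis=0) / 2, B.mean(axis=0) / 2])
    h_i = np.vstack([(A == 1).mean(axis=0), (B == 1).mean(axis=0)])
    poly = ~((p_i == 0).all(axis=0) | (p_i == 1).all(axis=0))
    if not poly.any():
        raise ValueError("all variants monomorphic in both groups")
    a, b, c = _wc_components(n_i, p_i[:, poly], h_i[:, poly])
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("undefined FST: zero total variance")
    return float(a.sum() / denom)


def wc_fst_individual(ind_dosages: np.ndarray, sample_dosages: np.ndarray) -> float:
    """FST treating one individual (two chromosomes) as a population versus
    a reference sample."""
    return wc_fst(np.atleast_2d(ind_dosages), sample_dosages)


def percentile_filter(result: DistanceResult, gwas_mask: np.ndarray, q: float) -> np.ndarray:
    """Mask of prediction-sample individuals whose standardized distance
    exceeds the q-th percentile of GWAS-sample standardized distances
    (linear-interpolation percentile)."""
    if not 0 <= q <= 100:
        raise ValueError("q must lie in [0, 100]")
    gwas_mask = np.asarray(gwas_mask, dtype=bool)
    cutoff = np.percentile(result.standardized[gwas_mask], q)
    return ~gwas_mask & (result.standardized > cutoff)


def assign_bins(
    distances: np.ndarray,
    bin_size: int,
    sample_ids: np.ndarray | None = None,
) -> BinAssignment:
    """Sort individuals by distance (ties broken by sample id, stable) and
    cut into consecutive equal-size bins; any remainder is absorbed by the
    final, largest-distance bin."""
    distances = np.asarray(distances, dtype=float)
    n = len(distances)
    if bin_size > n:
        raise ValueError("bin_size exceeds number of individuals")
    if sample_ids is None:
        sample_ids = np.arange(n)
    order = np.lexsort((np.asarray(sample_ids), distances))
    n_bins = n // bin_size
    if n % bin_size:
        logger.warning(
            "%d individuals do not fill a bin; absorbed into the last bin",
            n % bin_size,
        )
    bin_of_rank = np.minimum(np.arange(n) // bin_size, n_bins - 1)
    bin_index = np.empty(n, dtype=int)
    bin_index[order] = bin_of_rank
    medians = np.array(
        [np.median(distances[bin_index == b]) for b in range(n_bins)]
    )
    return BinAssignment(
        bin_index=bin_index,
        bin_size=bin_size,
        bin_median_distance=medians,
        order=order,
    )


def select_reference_bins(
    bins: BinAssignment, n_ref: int, target: float = 1.0
) -> np.ndarray:
    """The n_ref bins whose median distance is closest to the target (the
    standardized GWAS-sample mean, 1, by default)."""
    if n_ref > bins.n_bins:
        raise ValueError("n_ref exceeds number of bins")
    order = np.argsort(np.abs(bins.bin_median_distance - target), kind="stable")
    return np.sort(order[:n_ref])
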