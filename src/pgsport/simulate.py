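"""Synthetic structured-biobank generator.

Produces genotypes, causal effects, phenotypes and binary disease labels with
the statistical structure a polygenic-score portability analysis assumes:

* a GWAS panel drawn from a "home" deme plus prediction panels spanning a
  continuum of genetic divergence (Balding–Nichols allele-frequency model,
  one drift parameter per deme, optionally with 50/50 admixed individuals
  between adjacent demes);
* an additive polygenic trait with small covariate effects (sex, age, age^2,
  interactions, genotyping-array offset) and environmental noise whose
  variance can increase with socioeconomic deprivation;
* a liability-threshold binary disease;
* an optional "immune-like" regime in which causal effects turn over in
  diverged demes and effect sizes are coupled to allele frequency in the
  home deme (large effects sit at low heterozygosity, and turned-over large
  effects drift back toward intermediate frequency far away).

All randomness flows from a single integer seed through one
``numpy.random.Generator``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "TruthSet",
    "COVARIATE_EFFECTS",
    "simulate_frequencies",
    "simulate_effects",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_disease",
    "simulate_biobank",
]

#: Fixed small covariate effect sizes (trait units). Chosen so the combined
#: covariate variance is ~1-2% of the trait variance and the PGS signal
#: dominates. Age is centred at 55 before use.
COVARIATE_EFFECTS = {
    "sex": 0.10,
    "age": 0.005,
    "age2": 1e-4,
    "age_sex": 0.002,
    "age2_sex": 5e-5,
    "array": 0.05,
}

_AGE_CENTER = 55.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic biobank.

    Defaults define the package's reference study conditions: a 4,000-person
    GWAS deme, six prediction demes on an FST continuum from 0.001 to 0.2
    plus admixed individuals between adjacent demes, 1,200 unlinked variants
    of which 240 are causal, and a trait with narrow-sense heritability 0.5.
    """

    n_gwas: int = 4000
    n_pred_per_deme: tuple = (1000, 700, 700, 700, 700, 700)
    deme_fst: tuple = (0.001, 0.005, 0.02, 0.05, 0.1, 0.2)
    m_variants: int = 1200
    m_causal: int = 240
    h2: float = 0.5
    ses_var_slope: float = 0.0
    turnover_rate: float = 0.0
    effect_freq_coupling: bool = False
    liability_prevalence: float = 0.1
    n_admixed_per_pair: int = 200
    covariate_scale: float = 1.0
    ld_block_size: int = 1
    ld_flip_prob: float = 0.02
    far_deme_start: int | None = None
    seed: int = 0

    def __post_init__(self):
        self.n_pred_per_deme = tuple(int(n) for n in self.n_pred_per_deme)
        self.deme_fst = tuple(float(f) for f in self.deme_fst)
        if len(self.n_pred_per_deme) != len(self.deme_fst):
            raise ValueError("n_pred_per_deme and deme_fst must have equal length")
        if any(not (0 <= f < 1) for f in self.deme_fst):
            raise ValueError("deme_fst values must lie in [0, 1)")
        if any(b >= a for a, b in zip(self.deme_fst[1:], self.deme_fst[:-1])):
            raise ValueError("deme_fst must be strictly increasing")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if self.m_causal > self.m_variants:
            raise ValueError("m_causal cannot exceed m_variants")
        if not 0 <= self.turnover_rate <= 1:
            raise ValueError("turnover_rate must lie in [0, 1]")
        if not 0 < self.liability_prevalence < 1:
            raise ValueError("liability_prevalence must lie in (0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    @property
    def n_demes(self) -> int:
        return len(self.deme_fst)

    @property
    def far_demes(self) -> tuple:
        """Demes subject to effect turnover (default: upper half by drift)."""
        start = self.far_deme_start
        if start is None:
            start = self.n_demes // 2
        return tuple(range(start, self.n_demes))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Generative ground truth: frequencies and (per-deme) causal effects."""

    ancestral_freqs: np.ndarray  # (M,)
    deme_freqs: np.ndarray  # (D, M), all entries in (0, 1)
    causal_index: np.ndarray | None = None  # (m_causal,)
    base_effects: np.ndarray | None = None  # (m_causal,)
    deme_effects: np.ndarray | None = None  # (D, m_causal); row 0 == base

    def effects_for_deme(self, d: int) -> np.ndarray:
        return self.deme_effects[d]

    def to_frame(self) -> pd.DataFrame:
        m = self.ancestral_freqs.shape[0]
        df = pd.DataFrame({"ancestral_freq": self.ancestral_freqs})
        for d in range(self.deme_freqs.shape[0]):
            df[f"freq_deme{d}"] = self.deme_freqs[d]
        beta = np.zeros(m)
        if self.causal_index is not None:
            df["causal"] = np.isin(np.arange(m), self.causal_index)
            beta[self.causal_index] = self.base_effects
        df["base_effect"] = beta
        return df


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix with variant metadata and sample origins."""

    dosages: np.ndarray  # (N, M) ints in {0,1,2}
    sample_ids: np.ndarray  # (N,) unique strings
    variant_meta: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    deme_label: np.ndarray  # (N,) strings: "gwas", "deme{d}", "admix{a}-{b}"

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.deme_label) != n:
            raise ValueError("sample annotation length mismatch")
        if len(self.variant_meta) != m:
            raise ValueError("variant_meta length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def gwas_mask(self) -> np.ndarray:
        return self.deme_label == "gwas"

    def subset_variants(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            sample_ids=self.sample_ids,
            variant_meta=self.variant_meta.iloc[idx].reset_index(drop=True),
            deme_label=self.deme_label,
        )

    def subset_samples(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[mask],
            sample_ids=self.sample_ids[mask],
            variant_meta=self.variant_meta,
            deme_label=self.deme_label[mask],
        )


def _default_variant_meta(m: int) -> pd.DataFrame:
    """Evenly spread variants over 22 chromosome labels, 10 kb apart."""
    per_chrom = int(np.ceil(m / 22))
    idx = np.arange(m)
    chrom = 1 + idx // per_chrom
    pos = 10_000 * (idx % per_chrom + 1)
    return pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in idx],
            "chrom": chrom.astype(int),
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "G",
        }
    )


def _block_roots(m: int, block: int) -> np.ndarray:
    """Index of the root variant for each variant under block structure."""
    return (np.arange(m) // block) * block


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TruthSet:
    """Draw ancestral and per-deme allele frequencies (Balding–Nichols).

    Ancestral frequencies are Uniform(0.05, 0.95); each deme's frequency is a
    Beta draw about the ancestral value, Beta(p(1-c)/c, (1-p)(1-c)/c) with
    dispersion c.  ``deme_fst[d]`` is the *target pairwise* Weir–Cockerham
    FST between the GWAS deme and deme d: since two demes drawn with
    dispersions c0 and cd have expected pairwise FST (c0 + cd)/2, the GWAS
    deme uses c0 = deme_fst[0] and deme d > 0 uses cd = 2*deme_fst[d] - c0.
    c = 0 reproduces the ancestral frequency exactly.  With
    ``ld_block_size > 1`` only block-root variants get independent draws;
    members inherit the root frequency attenuated by the flip noise used at
    genotype time.
    """
    rng = config.rng() if rng is None else rng
    m, block = config.m_variants, config.ld_block_size
    roots = _block_roots(m, block)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    p_anc = p_anc[roots]  # block members share the root's ancestral frequency

    c0 = config.deme_fst[0]
    d_freqs = np.empty((config.n_demes, m))
    for d, f in enumerate(config.deme_fst):
        c = c0 if d == 0 else min(2 * f - c0, 0.999)
        if c <= 0.0:
            d_freqs[d] = p_anc
            continue
        a = p_anc * (1 - c) / c
        b = (1 - p_anc) * (1 - c) / c
        d_freqs[d] = rng.beta(a, b)
    # block members: same realized root frequency, then flip-noise attenuation
    if block > 1:
        eps = config.ld_flip_prob
        member = np.arange(m) != roots
        d_freqs[:, member] = d_freqs[:, roots[member]] * (1 - 2 * eps) + eps
        p_anc = p_anc.copy()
        p_anc[member] = p_anc[roots[member]] * (1 - 2 * eps) + eps
    d_freqs = np.clip(d_freqs, 1e-6, 1 - 1e-6)
    return TruthSet(ancestral_freqs=p_anc, deme_freqs=d_freqs)


def simulate_effects(
    config: SimulationConfig,
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Draw causal effects; optionally apply frequency coupling and turnover.

    Base effects are i.i.d. Normal with variance h2 / sum(2p(1-p)) over
    causal variants, so the expected genetic variance equals h2.

    With ``effect_freq_coupling`` the frequency rows of causal variants are
    permuted so that larger |effect| pairs with lower ancestral
    heterozygosity (a power-preserving coupling: detectability scales with
    2p(1-p) * beta^2).  With ``turnover_rate`` t, each causal effect in each
    far deme is independently redrawn with probability t; if coupling is on,
    redrawn top-tercile |effect| variants additionally have their far-deme
    frequencies resampled toward 0.5, releasing the coupling.
    """
    rng = config.rng() if rng is None else rng
    m_c = config.m_causal
    causal = np.sort(rng.choice(config.m_variants, size=m_c, replace=False))
    p_c = truth.ancestral_freqs[causal]
    het_sum = np.sum(2 * p_c * (1 - p_c))
    sigma_beta = np.sqrt(config.h2 / het_sum) if config.h2 > 0 else 0.0
    base = rng.normal(0.0, 1.0, size=m_c) * sigma_beta

    if config.effect_freq_coupling:
        # permute frequency rows among causal variants: largest |effect|
        # receives the lowest-heterozygosity frequency row
        order_eff = np.argsort(-np.abs(base), kind="stable")
        het = 2 * p_c * (1 - p_c)
        order_het = np.argsort(het, kind="stable")
        perm = np.empty(m_c, dtype=int)
        perm[order_eff] = order_het
        truth.ancestral_freqs[causal] = p_c[perm]
        truth.deme_freqs[:, causal] = truth.deme_freqs[:, causal[perm]]

    d_eff = np.tile(base, (config.n_demes, 1))
    far = [d for d in config.far_demes if d > 0]
    if config.turnover_rate > 0:
        if not far:
            warnings.warn(
                "effect turnover requested but there are no far demes; no-op",
                stacklevel=2,
            )
        else:
            large = np.abs(base) >= np.quantile(np.abs(base), 2 / 3)
            for d in far:
                redraw = rng.random(m_c) < config.turnover_rate
                d_eff[d, redraw] = rng.normal(0.0, sigma_beta, size=redraw.sum())
                if config.effect_freq_coupling:
                    resample = redraw & large
                    truth.deme_freqs[d, causal[resample]] = rng.uniform(
                        0.4, 0.6, size=resample.sum()
                    )

    truth.causal_index = causal
    truth.base_effects = base
    truth.deme_effects = d_eff
    return truth


def _draw_group(
    rng: np.random.Generator,
    n: int,
    freq1: np.ndarray,
    freq2: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Draw n diploid dosage rows; the two alleles may come from different
    demes (admixture).  Block members copy the root's alleles with per-allele
    flip noise, creating local dosage correlation for clumping to act on."""
    m, block = config.m_variants, config.ld_block_size
    if block == 1:
        return (
            rng.binomial(1, freq1, size=(n, m)) + rng.binomial(1, freq2, size=(n, m))
        ).astype(np.int8)
    roots = _block_roots(m, block)
    eps = config.ld_flip_prob
    out = np.empty((n, m), dtype=np.int8)
    for alleles, freq in ((0, freq1), (1, freq2)):
        a = rng.binomial(1, freq[roots], size=(n, m)).astype(np.int8)
        flips = rng.random((n, m)) < eps
        member = np.arange(m) != roots
        a[:, member] = np.where(
            flips[:, member], 1 - a[:, roots[member]], a[:, roots[member]]
        )
        if alleles == 0:
            out[:] = a
        else:
            out += a
    return out


def simulate_genotypes(
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Binomial(2, deme frequency) dosages for GWAS, prediction and admixed
    samples.  Row layout: GWAS deme first, then prediction demes in order,
    then admixed pairs."""
    rng = config.rng() if rng is None else rng
    blocks = []
    labels = []
    ids = []

    def add(n, f1, f2, label, prefix):
        if n == 0:
            return
        blocks.append(_draw_group(rng, n, f1, f2, config))
        labels.extend([label] * n)
        start = len(ids)
        ids.extend(f"{prefix}{start + i + 1:06d}" for i in range(n))

    add(config.n_gwas, truth.deme_freqs[0], truth.deme_freqs[0], "gwas", "s")
    for d, n in enumerate(config.n_pred_per_deme):
        add(n, truth.deme_freqs[d], truth.deme_freqs[d], f"deme{d}", "s")
    if config.n_admixed_per_pair > 0:
        for d in range(config.n_demes - 1):
            add(
                config.n_admixed_per_pair,
                truth.deme_freqs[d],
                truth.deme_freqs[d + 1],
                f"admix{d}-{d + 1}",
                "s",
            )
    return GenotypeMatrix(
        dosages=np.vstack(blocks),
        sample_ids=np.asarray(ids),
        variant_meta=_default_variant_meta(config.m_variants),
        deme_label=np.asarray(labels),
    )


def _effect_vector(label: str, truth: TruthSet) -> np.ndarray:
    if label == "gwas":
        return truth.deme_effects[0]
    if label.startswith("deme"):
        return truth.deme_effects[int(label[4:])]
    if label.startswith("admix"):
        a, b = label[5:].split("-")
        return 0.5 * (truth.deme_effects[int(a)] + truth.deme_effects[int(b)])
    raise ValueError(f"unknown deme label: {label}")


def genetic_values(G: GenotypeMatrix, truth: TruthSet) -> np.ndarray:
    """Per-sample additive genetic value under the deme-specific effects."""
    gc = G.dosages[:, truth.causal_index].astype(float)
    out = np.empty(G.n_samples)
    for label in np.unique(G.deme_label):
        mask = G.deme_label == label
        out[mask] = gc[mask] @ _effect_vector(label, truth)
    return out


def simulate_phenotypes(
    G: GenotypeMatrix,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trait = genetic value + covariate terms + heteroscedastic noise.

    Environmental variance is (1 - h2) scaled by
    (1 + ses_var_slope * (ses_stratum - 1)) where ses_stratum is the sample's
    deprivation quintile (1 = least deprived), so at ses_var_slope = 0 the
    population heritability is approximately h2.
    """
    rng = config.rng() if rng is None else rng
    n = G.n_samples
    g = genetic_values(G, truth)

    sex = rng.integers(0, 2, size=n)
    age = rng.integers(40, 71, size=n).astype(float)
    array_label = np.where(rng.random(n) < 0.9, "axiom", "bileve")
    ses_index = rng.normal(0.0, 1.0, size=n)
    ses_stratum = (
        pd.qcut(pd.Series(ses_index), 5, labels=False, duplicates="drop").to_numpy() + 1
    )
    income_stratum = 6 - ses_stratum  # more deprived -> lower income

    ac = age - _AGE_CENTER
    ce = COVARIATE_EFFECTS
    covar = config.covariate_scale * (
        ce["sex"] * sex
        + ce["age"] * ac
        + ce["age2"] * ac**2
        + ce["age_sex"] * ac * sex
        + ce["age2_sex"] * ac**2 * sex
        + ce["array"] * (array_label == "bileve")
    )

    sigma2_e = max(1.0 - config.h2, 0.0)
    sigma2_i = sigma2_e * (1.0 + config.ses_var_slope * (ses_stratum - 1))
    noise = rng.normal(0.0, 1.0, size=n) * np.sqrt(sigma2_i)
    trait = g + covar + noise

    return pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "trait": trait,
            "sex": sex,
            "age": age,
            "array_label": array_label,
            "ses_index": ses_index,
            "ses_stratum": ses_stratum,
            "income_stratum": income_stratum,
            "genetic_value": g,
        }
    )


def simulate_disease(
    pheno: pd.DataFrame,
    config: SimulationConfig,
    liability_col: str = "trait",
) -> pd.DataFrame:
    """Liability-threshold disease: case iff liability exceeds the
    (1 - prevalence) normal quantile of the liability distribution (mean and
    SD estimated from the sample, so realized case counts carry binomial
    noise around N * prevalence)."""
    from scipy import stats

    prev = config.liability_prevalence
    if not 0 < prev < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    liab = pheno[liability_col].to_numpy()
    thresh = liab.mean() + stats.norm.ppf(1 - prev) * liab.std(ddof=1)
    out = pheno.copy()
    out["disease"] = (liab > thresh).astype(int)
    return out


def simulate_biobank(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, TruthSet, pd.DataFrame]:
    """Run the full generator with one seeded generator; returns genotypes,
    ground truth, and a phenotype table including disease status."""
    rng = config.rng()
    truth = simulate_frequencies(config, rng)
    truth = simulate_effects(config, truth, rng)
    G = simulate_genotypes(truth, config, rng)
    pheno = simulate_phenotypes(G, truth, config, rng)
    pheno = simulate_disease(pheno, config)
    return G, truth, pheno
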