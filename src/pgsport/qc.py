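"""Sample- and variant-level quality control with an auditable removal ledger.

Filters are applied sequentially and each removed unit is counted at the
first filter that removes it, so per-step removals are disjoint and sum
exactly to the total — the accounting convention under which a biobank QC
report's per-step counts add up to its stated total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "QCLedger",
    "FilterConfig",
    "filter_samples",
    "filter_variants",
    "hwe_exact_test",
    "ledger_total",
]

#: Default sample-exclusion flags, in application order.
SAMPLE_FLAG_ORDER = (
    "withdrawn",
    "aneuploidy",
    "sex_mismatch",
    "het_miss_outlier",
    "high_missingness",
    "related",
)


@dataclass
class QCLedger:
    """Ordered record of sequential filter steps."""

    initial_count: int
    steps: list = field(default_factory=list)  # (name, removed, remaining)

    def add_step(self, name: str, removed: int) -> None:
        remaining = (self.steps[-1][2] if self.steps else self.initial_count) - removed
        if remaining < 0:
            raise ValueError(f"step {name!r} removes more units than remain")
        self.steps.append((name, int(removed), int(remaining)))

    @property
    def removed_total(self) -> int:
        return sum(s[1] for s in self.steps)

    @property
    def remaining(self) -> int:
        return self.initial_count - self.removed_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "removed", "remaining"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "initial": self.initial_count,
                "steps": [
                    {"filter": n, "removed": r, "remaining": k}
                    for n, r, k in self.steps
                ],
                "removed_total": self.removed_total,
                "remaining": self.remaining,
            },
            indent=2,
        )


def ledger_total(ledger: QCLedger) -> tuple[int, int]:
    """(total removed, remaining) — the ledger's conservation identity."""
    return ledger.removed_total, ledger.remaining


@dataclass
class FilterConfig:
    """Thresholds for variant filters and sample-flag application order."""

    hwe_p_min: float = 1e-10
    maf_min: float = 1e-4  # kept iff minor allele frequency strictly > this
    missing_max: float = 0.02
    excluded_regions: tuple = ()  # (chrom, start, end), 1-based closed
    sample_flag_columns: tuple = SAMPLE_FLAG_ORDER

    def __post_init__(self):
        for name, v in (("hwe_p_min", self.hwe_p_min), ("maf_min", self.maf_min),
                        ("missing_max", self.missing_max)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for chrom, start, end in self.excluded_regions:
            if start > end:
                raise ValueError(f"malformed region {(chrom, start, end)}")


def filter_samples(table: pd.DataFrame, config: FilterConfig):
    """Apply boolean exclusion flags in order; each sample is removed (and
    counted) at the first flag set for it.  Returns (kept sample ids, ledger).
    """
    for col in config.sample_flag_columns:
        if col not in table.columns:
            raise KeyError(f"missing sample flag column: {col!r}")
    ledger = QCLedger(initial_count=len(table))
    alive = np.ones(len(table), dtype=bool)
    for col in config.sample_flag_columns:
        hit = alive & table[col].to_numpy(dtype=bool)
        ledger.add_step(col, int(hit.sum()))
        alive &= ~hit
    kept = table.loc[alive, "sample_id"].to_numpy()
    return kept, ledger


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    P-value is the sum of probabilities, over all heterozygote counts
    compatible with the observed allele counts, of outcomes no more probable
    than the observed one (no mid-p adjustment; matches the exact test of
    Wigginton, Cutler & Abecasis 2005).
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_Aa)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _in_regions(chrom, pos, regions) -> np.ndarray:
    hit = np.zeros(len(chrom), dtype=bool)
    for c, start, end in regions:
        hit |= (chrom == c) & (pos >= start) & (pos <= end)
    return hit


def filter_variants(G, config: FilterConfig, gwas_mask: np.ndarray | None = None):
    """Sequential variant filters: region exclusion, Hardy–Weinberg exact
    test, then minor-allele-frequency floor (the latter two computed on
    GWAS-deme samples only).  Returns (kept variant indices, ledger)."""
    meta = G.variant_meta
    if gwas_mask is None:
        gwas_mask = G.gwas_mask
    if not gwas_mask.any():
        raise ValueError("empty GWAS sample for variant QC")
    ledger = QCLedger(initial_count=G.n_variants)
    alive = np.ones(G.n_variants, dtype=bool)

    hit = _in_regions(meta["chrom"].to_numpy(), meta["pos"].to_numpy(),
                      config.excluded_regions) & alive
    ledger.add_step("excluded_region", int(hit.sum()))
    alive &= ~hit

    d = G.dosages[gwas_mask]
    n_aa = (d == 2).sum(axis=0)
    n_Aa = (d == 1).sum(axis=0)
    n_AA = (d == 0).sum(axis=0)
    hwe_p = np.ones(G.n_variants)
    for j in np.where(alive)[0]:
        hwe_p[j] = hwe_exact_test(n_AA[j], n_Aa[j], n_aa[j])
    hit = alive & (hwe_p < config.hwe_p_min)
    ledger.add_step("hwe", int(hit.sum()))
    alive &= ~hit

    freq = d.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    hit = alive & ~(maf > config.maf_min)
    ledger.add_step("maf", int(hit.sum()))
    alive &= ~hit

    if not alive.any():
        raise ValueError("all variants removed by QC")
    kept = np.where(alive)[0]
    logger.info("variant QC kept %d of %d variants", len(kept), G.n_variants)
    return kept, ledger
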