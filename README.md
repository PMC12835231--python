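# pgsport

**Polygenic-score portability as a function of genetic distance from the
GWAS sample.**

Polygenic scores (PGS) built by genome-wide association in one population
lose predictive accuracy when applied to individuals genetically distant
from the discovery sample. `pgsport` implements a complete evaluation
pipeline for this phenomenon, driven by a synthetic structured-biobank
generator so that every stage can be exercised, tested and calibrated
without access to restricted cohort data. It is aimed at statistical
geneticists who want a transparent, reproducible reference implementation of
the group-level and individual-level portability measures, and at method
developers who need a simulation harness with known ground truth.

## What it computes

**Genetic distance.** A joint PCA of the variant-standardized dosage matrix
(GWAS + prediction samples); each individual's distance from the GWAS
sample is the eigenvalue-weighted Euclidean distance from the centroid *c*
of GWAS individuals in PC space,

d(x) = sqrt( Σₖ wₖ (xₖ − cₖ)² ),  wₖ = λₖ / Σₙ λₙ,  k = 1…K (default K = 40),

divided by the mean distance among GWAS individuals so that the GWAS-sample
mean is 1. The distance is a fast proxy for per-individual Weir–Cockerham
F_ST against the GWAS sample, which the package also computes exactly.

**C+T polygenic scores.** Marginal association (linear, or logistic for
binary disease) with covariates, greedy LD clumping (p < 0.01, r² ≥ 0.2,
250 kb windows), inclusion threshold p < 1e−5, and weighted allele-count
scoring — exposed as the sklearn-style estimator `ClumpThresholdScorer`
(`fit`/`predict`), as is the distance transformer `GeneticDistancePCA`
(`fit`/`transform`).

**Portability profiles.** Prediction individuals are sorted into
equal-size genetic-distance bins. Group-level accuracy per bin is the
partial R² of the PGS,
R²_partial = (SSE_reduced − SSE_full) / SSE_reduced, normalized by the mean
over the reference bins (the 10% of bins whose median distance is closest
to the GWAS mean). Individual-level accuracy is a three-stage squared
prediction error: residualize the trait on covariates within each bin, then
globally on a 20-degree polynomial in distance (+ sex and sex×distance),
then regress the residual on the PGS; (Z − Ẑ)² is standardized by the
reference-bin mean. Binary traits get per-bin precision/recall/F1 at the
F1-optimal GWAS-set PGS percentile. Cubic splines with density-placed knots
summarize trends; R² comparisons (linear / discretized / spline, with
bootstrap CIs) ask whether genetic distance or socioeconomic measures
explain more of the variance in prediction error.

**Architecture diagnostics.** Index-SNP heterozygosity by effect-size
tercile across distance bins, per-bin PGS variance relative to the
reference bins, per-SNP heritability 2p(1−p)β̂², and re-estimation of
index-SNP effects in close/far subsets (effect-ratio means ± SD and
sign-flip fractions) — the signatures that separate a neutral additive
architecture from an "immune-like" one in which allelic effects turn over
with divergence.

**Synthetic biobank.** Balding–Nichols allele frequencies over a GWAS deme
plus prediction demes spanning a divergence continuum (calibrated so the
realized pairwise F_ST against the GWAS deme matches the configured
targets), optional 50/50 admixed individuals, additive polygenic traits
with covariate effects and SES-dependent environmental variance,
liability-threshold disease, optional synthetic LD blocks, and an optional
effect-turnover regime with frequency–effect coupling.

## Worked example

```python
from pgsport import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, output_dir="demo_out")
res = run_pipeline(cfg)

prof = res["profile"]
far = prof["median_distance"] >= prof["median_distance"].quantile(0.8)
print(f"index SNPs in PGS:          {res['scorer'].model_.n_variants}")
print(f"bins / reference bins:      {len(prof)} / {len(res['reference_bins'])}")
print(f"baseline partial R2:        {prof.attrs['baseline']:.4f}")
print(f"relative accuracy, far 20%: {prof['relative'][far].mean():.3f}")
print(f"PGS-variance slope:         {res['pgs_variance'].attrs['slope']:.4f}")
ratios = res["effect_ratios"]
print(f"far-set mean effect ratio:  {ratios['far']['mean_ratio']:.3f}")
print(f"far-set sign-flip fraction: {ratios['far']['sign_flip_fraction']:.3f}")
```

Output:

```
index SNPs in PGS:          36
bins / reference bins:      55 / 6
baseline partial R2:        0.2535
relative accuracy, far 20%: 0.771
PGS-variance slope:         -0.0323
far-set mean effect ratio:  0.849
far-set sign-flip fraction: 0.028
```

Under the default neutral architecture (heritability 0.5, six demes out to
F_ST 0.2) the PGS explains ~25% of residual trait variance in bins near the
GWAS sample; relative accuracy decays to ~0.77 in the farthest fifth of
bins, driven by the decline in index-SNP heterozygosity (the PGS-variance
slope on distance is slightly negative), while re-estimated allelic effects
in the far subset remain close to the discovery estimates (mean ratio 0.85,
under 3% sign flips — the small attenuation is winner's-curse shrinkage of
the discovery estimates). Switching the generator to the turnover regime
(`simulation=dict(turnover_rate=0.9, effect_freq_coupling=True)`) inverts
these diagnostics: group accuracy collapses toward zero with distance while
PGS variance and large-effect-SNP heterozygosity *increase*, and far-subset
effect ratios shrink toward zero with sign flips near what independent
redraws would give.

The same pipeline is available from the shell:

```bash
pgsport run-all --seed 1 --output-dir demo_out
```

writing per-stage TSV/JSON tables (distances, bins, GWAS summary, PGS
model and scores, accuracy profiles, per-individual errors, diagnostics)
with the seed and a config hash in every header.

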