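# Methods

This note documents the models and procedures implemented in `pgsport`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## The portability question

A polygenic score is a weighted sum of allele counts,
PGS_i = Σ_j β̂_j g_ij, with weights estimated by GWAS in a discovery
sample. Its predictive accuracy in a target individual depends on how that
individual's genotype distribution relates to the discovery sample's: under
a neutral, additive architecture with fixed environmental variance, the
decay of accuracy with divergence is driven largely by the decline in
heterozygosity (hence genetic variance tagged) at the index SNPs and is
well indexed by F_ST. Trait-specific deviations from that expectation —
accuracy collapsing much faster than divergence, or PGS variance *rising*
with distance — point at architecture: effects that differ across
populations, or ascertainment coupling between effect size and allele
frequency. The package measures both the accuracy profiles and the
architecture diagnostics that separate these explanations.

## Genetic distance

All samples (GWAS + prediction) enter one PCA of the standardized dosage
matrix, (g − 2p)/√(2p(1−p)) with p the full-sample allele frequency; there
is no projection step, so prediction-sample structure contributes to the
axes. An individual's raw distance is the eigenvalue-weighted Euclidean
distance of its PC coordinates from the centroid of GWAS-sample
coordinates, with weights w_k = λ_k/Σλ (K = 40 components by default;
configurable). Distances are reported divided by the GWAS-sample mean, so
the GWAS mean is exactly 1. Weighting by eigenvalues makes the measure
insensitive to how many trailing, noise-dominated PCs are retained, and the
standardized scale is comparable across runs.

Per-individual F_ST against the GWAS sample is computed with the
Weir–Cockerham (1984) estimator, treating the individual's two chromosomes
as one population, as the ratio of summed variance components
Σa / Σ(a+b+c) over loci. On the default simulated continuum the Pearson
correlation between standardized distance and per-individual F_ST is ~0.9,
weakest at intermediate distances — the same qualitative behavior that
motivates using the cheap PC distance as the working scale.

Prediction individuals are sorted by distance (ties broken by sample id)
and cut into equal-size bins; a remainder smaller than one bin is absorbed
by the last (farthest) bin with a logged warning. Reference bins are the
`ref_fraction` (default 10%) of bins whose median distance is closest to 1.
An optional filter restricts analysis to individuals beyond a percentile
(default 97.5th, linear-interpolation definition) of the GWAS-sample
distance distribution; the default pipeline bins all prediction individuals
because several downstream analyses (error-variance comparisons) are
defined on the full prediction set.

## GWAS, clumping, scoring

The linear scan residualizes the trait and all dosage columns on the
covariate design once (QR-based Frisch–Waugh–Lovell), which reproduces each
per-variant joint OLS fit exactly at a fraction of the cost; standard
errors use the full-model residual degrees of freedom. Binary traits use
per-variant logistic regression (statsmodels), with separation and
non-convergence flagged as missing. GWAS covariates are the first 20 PCs
plus age, age², sex, age×sex, age²×sex; the asymmetry with the 40 PCs used
for distance is deliberate and mirrors standard practice of adjusting GWAS
for fewer components than are informative about fine structure.

Clumping is greedy: repeatedly take the smallest-p unclaimed variant with
p below the clumping threshold (default 0.01) as an index SNP and claim all
unclaimed variants within 250 kb on the same chromosome with dosage
r² ≥ 0.2. P-value ties are broken by smaller standard error, then variant
id, making the output invariant to input row order. The PGS keeps index
SNPs with p < 1e−5 and scores by the weighted allele-count **sum** (not the
per-allele average): the sum is the dialect under which
var(PGS) ≈ Σ_j 2p_j(1−p_j)β̂_j² holds at linkage equilibrium, which the
diagnostics rely on. A flag provides the average dialect. Allele mismatches
between a stored model and target genotypes are resolved by flipping the
dosage (2 − d), counted and logged.

## Accuracy measures

**Group level.** Within each bin, partial R² of the PGS from the nested
OLS fits y ~ covariates (+ PGS); covariates here are array type, age, age²,
sex, age×sex, age²×sex. The partial R² equals the squared partial
correlation (tested to 1e−10). In bins where an array type is represented
by a single individual, the array covariate is dropped for that bin. Each
bin's value is divided by the mean over reference bins, so reference-bin
relative accuracy averages exactly 1.

**Individual level.** Three stages: (1) per bin, residualize the raw trait
on array + age² + sex + age×sex + age²×sex (note: no main age term — the
bin-level residualization convention this implements); (2) globally,
residualize on a 20-degree polynomial in standardized distance plus sex and
sex×distance; (3) regress the residual Z on the PGS univariately. The
squared residual (Z − Ẑ)² is the unstandardized error, divided by its mean
over reference-bin members. The degree-20 polynomial is fitted on a
QR-orthonormalized Legendre basis over the min-max-mapped domain: a raw
power basis at degree 20 is numerically singular over a right-skewed
distance distribution. Coefficients are never interpreted — only fitted
values — so the basis choice is a pure conditioning device; the
implementation matches a literal three-regression least-squares oracle to
1e−8 on well-conditioned fixtures.

**Binary traits.** An individual is called positive when its PGS reaches a
fixed percentile of the *GWAS-set* PGS distribution (weak inequality at the
threshold). The percentile is chosen on a 5%-step grid (5–95) to maximize
F1 in the GWAS set, ties going to the higher percentile (fewer predicted
positives). Per bin, precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean; bins with no predicted (or no true) cases get missing
precision (recall), logged.

**Trend summaries.** Cubic least-squares B-splines with n interior knots at
equal-count quantiles (j/(n+1), j = 1…n), so each of the n+1 inter-knot
intervals holds an equal share of points (±1). The R² of a fit to constant
y is defined as 0 (the 0/0 case), which the null fixtures of the
variance-explained comparison need. That comparison fits squared prediction
error on a measure by (1) OLS, (2) a discretized predictor over 5
equal-width bins (empty bins merged into a neighbor with a warning), and
(3) a 16-knot density spline, reporting R² with a 95% central percentile
bootstrap over individuals (1,000 replicates by default, seeded).

## Architecture diagnostics

Index SNPs are split into effect-size terciles by β̂² (ties by variant id;
when the count is not divisible by 3 the lower terciles take the extra
SNPs, e.g. 10 → 4/3/3). Per bin and stratum, mean heterozygosity 2p_b(1−p_b)
from bin-member allele frequencies; per bin, the unbiased (n−1) sample
variance of the PGS relative to the reference-bin mean, with the OLS slope
of relative variance on bin median distance as the summary. Close/far
effect re-estimation reruns the marginal GWAS within each subset, adjusting
for 20 PCs recomputed on the subset's own genotype matrix, and reports
β̂_subset/β̂_gwas means ± SD and the sign-flip fraction across index SNPs.
The close/far cut is configurable; the pipeline defaults to the median
prediction-sample distance (the conventional cut of 10 standardized units
presumes a biobank-scale distance range that a desk-scale simulation does
not reach). Out-of-sample ratios sit slightly below 1 even under fully
persistent effects — winner's-curse inflation of the discovery estimates —
which the tests document rather than correct.

## The synthetic biobank

The generator emulates the statistical structure the analysis assumes, not
any particular cohort:

- **Frequencies.** Ancestral frequencies Uniform(0.05, 0.95) (keeping
  causal variants comfortably polymorphic at desk-scale GWAS power); deme
  frequencies are Balding–Nichols Beta draws. `deme_fst[d]` is the target
  *pairwise* Weir–Cockerham F_ST between the GWAS deme and deme d: because
  two demes drawn about a common ancestor with dispersions c₀ and c_d have
  expected pairwise F_ST (c₀+c_d)/2, deme d is drawn with
  c_d = 2·deme_fst[d] − c₀. Realized F_ST matches targets within a few
  percent up to ~0.1 and saturates mildly by 0.2.
- **Defaults** (the package's reference study conditions): GWAS deme of
  4,000; prediction demes of 1,000 + 5×700 at F_ST targets 0.001–0.2 plus
  200 admixed individuals per adjacent deme pair (a 50/50 dosage mixture),
  giving a graded distance continuum with clear modes; 1,200 unlinked
  variants, 240 causal; h² = 0.5. Bins of 100 individuals (55 bins), 10%
  reference bins. These sizes keep a full pipeline run near ten seconds so
  regime tests can average over seeds.
- **Trait.** Additive genetic value plus fixed small covariate effects
  (documented in `COVARIATE_EFFECTS`; combined variance ~1–2% of the trait)
  plus Gaussian noise with variance (1−h²)·(1 + slope·(SES stratum − 1)).
  Effect variance is calibrated as h²/Σ 2p(1−p) over causal ancestral
  frequencies, so realized heritability tracks the target within ±0.05 at
  n = 20,000. Disease is a liability threshold at the (1 − prevalence)
  normal quantile of the trait's estimated distribution, so case counts
  carry binomial noise around N·prevalence.
- **Turnover regime.** With probability `turnover_rate`, each causal
  effect is independently redrawn in each "far" deme (the upper half of the
  deme list by default). With `effect_freq_coupling`, frequency rows are
  permuted among causal variants so larger |effect| pairs with lower
  ancestral heterozygosity (power-preserving ascertainment coupling), and
  redrawn top-tercile-|effect| variants have their far-deme frequencies
  resampled toward 0.5 — releasing the coupling with divergence. This
  reproduces, qualitatively, the immune-like signature: group accuracy
  collapsing while PGS variance and large-effect heterozygosity rise with
  distance, far-subset effect ratios near 0 and elevated sign flips.
- **LD.** Variants are exchangeable given frequency by default; an
  optional block structure (members copy a root variant's alleles with
  flip noise) creates local dosage correlation so clumping has work to do.
  It is not a coalescent model: no recombination-distance decay, no
  realistic allele-frequency/LD joint distribution.

Passing regime tests therefore show that the *measurement machinery*
recovers architectures it was pointed at; they do not show that any real
trait has such an architecture, and absolute accuracy values at desk scale
(e.g. baseline partial R² ≈ 0.25 with 240 causal variants) are not
comparable to biobank-scale values for real polygenic traits.

## QC ledger

Filters apply sequentially and each removed unit is counted at the first
filter that removes it, so per-step removals are disjoint and sum exactly
to the total — the accounting convention under which published per-step
counts add to a published total. Sample flags apply in the order withdrawn,
aneuploidy, sex mismatch, heterozygosity/missingness outlier, high
missingness, relatedness (relatedness arrives as a precomputed flag;
kinship inference is out of scope). Variant filters: region exclusion
(1-based closed intervals), the exact conditional Hardy–Weinberg test
(no mid-p; tested against a full-enumeration rational-arithmetic oracle to
1e−12 for totals ≤ 200) at p < 1e−10, then minor allele frequency strictly
greater than 0.01%, both computed on GWAS-deme samples. Re-running the
filters on a kept set removes nothing.

## Numerical and interface choices

- Single integer seed per run; every stochastic component draws from one
  `numpy.random.Generator`; outputs embed the seed and a config hash.
- Percentiles/quantiles use the linear-interpolation (type-7) definition.
- Sorting ties break on sample or variant id, everywhere, for bit-for-bit
  reproducibility at fixed seed and platform.
- PCA uses a full SVD up to min(N, M) ≤ 3,000 and seeded randomized SVD
  beyond; eigenvalues are those of the standardized-genotype covariance.
- File formats: PLINK .raw-style dosage TSV, minimal PLINK 1 .bed/.bim/.fam
  codec (SNP-major, A1 = effect allele), VCF via cyvcf2 (biallelic GT
  records; multi-allelic skipped with a count; missing genotypes
  mean-imputed with a count). Internal variant indices are 0-based,
  file positions 1-based.

## Known limitations

- No LD realism (see above); clumping correctness is established by oracle
  equivalence, not by realistic LD ascertainment.
- The distance scale is not anchored to any external reference panel, so
  absolute distances are comparable only within a run.
- Logistic GWAS is fit per variant and is the slowest stage at scale;
  disease analyses can be disabled per run (`run_disease: false`).
- Winner's curse is documented, not corrected; no shrinkage/Bayesian PGS
  methods are implemented.
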