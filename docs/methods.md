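# Methods

This note records the models, parameter choices and numerical conventions
behind `metabotype`, and what the synthetic cohort does and does not
emulate.

## The analysis model

The pipeline treats a cohort as (i) a replicate-level feature-intensity
table per chromatography mode (HILIC-positive, C18-negative), (ii) a
level-1 metabolite identification library, (iii) a pathway-membership map
(GMT), and (iv) a clinical table with baseline covariates and survival
outcomes. The scientific claim it operationalizes is that unsupervised
structure in standardized circulating metabolite profiles defines patient
subtypes that are prognostic of survival, with the association concentrated
in ever-smokers and independent of HPV status.

### Preprocessing

Stage order is fixed: replicate-CV filter → triplicate median summarization
→ log₂ → empirical-Bayes batch correction → missingness filter → k-NN
imputation → Z-score standardization → library matching → mode pooling.
Conventions that matter:

- The CV of a (feature, sample) cell uses only observed replicates and
  needs at least two; the per-feature value is the median over samples with
  a defined CV. The removal bound is **inclusive** (median CV ≥ 0.75
  removed); a feature with no computable CV fails the filter.
- Summarization requires ≥ 2 of 3 observed replicates, otherwise the cell
  is missing; no replicate values are ever fabricated.
- Batch correction is the standard parametric empirical-Bayes location/scale
  adjustment on summarized log₂ intensities: per-feature standardization
  against the batch-mean model, per-batch location (normal prior) and scale
  (inverse-gamma prior, moment-matched) estimates shrunk via the usual
  coupled posterior-mean iteration (convergence 10⁻⁴), back-transformed to
  the log scale. Missing entries are ignored in estimation and stay
  missing. The implementation agrees with the Bioconductor reference
  (`sva::ComBat`, parametric, no covariates) to ~10⁻⁵ on complete data — a
  cross-check in the test suite. A `shrink=False` variant performs the
  plain location/scale adjustment (population-variance convention), under
  which removal of a pure additive batch shift is exact and the operation
  is idempotent to machine precision; with shrinkage those identities hold
  only approximately, which is inherent to empirical Bayes, not an
  implementation artifact.
- The missingness filter is **strict** (> 20% missing removed; exactly 20%
  is retained) — deliberately asymmetric to the CV filter's inclusive
  bound, following the source conventions for each.
- k-NN imputation (default k = 10, the value being otherwise unstated):
  sample-to-sample Euclidean distances over co-observed features, computed
  once on the pre-imputation matrix; a missing cell becomes the unweighted
  mean of the feature over the k nearest samples that observed it, with a
  feature-median fallback (warned) when no usable neighbor exists. The
  bespoke implementation exists because these semantics (unscaled
  co-observed distances, frozen before imputation) differ from
  scikit-learn's `KNNImputer`, which rescales distances by the shared
  missingness pattern.
- Z-scoring uses the sample SD (n−1 denominator). Matching tolerances are
  inclusive (≤ 10 ppm, ≤ 30 s); ties break by smaller ppm error, then
  smaller retention-time error; when several features hit one library
  entry only the best ppm match is kept so metabolite columns stay unique.

### Clustering and model selection

"Ward.D" is implemented as the Lance–Williams recurrence with Ward
coefficients applied to the **unsquared** Euclidean distances — the classic
`hclust(..., "ward.D")` dialect, which the test suite checks against both a
naive recompute-all oracle and R's `hclust` itself. `ward.D2` (recurrence
on squared distances, square-rooted heights) is available but non-default.
Merge ties break toward the smallest (left, right) node-id pair, making the
tree fully deterministic.

BIC and AIC for a hard partition are not standard; the sum-of-squares
criteria `W + ln(n)·k·p` and `W + 2·k·p` (W = total within-cluster sum of
squares, p = number of metabolites) are used, matching common
clustering-software practice, and the formula is recorded in the output.
Silhouette terms of singleton clusters are 0; a zero Dunn denominator gives
+∞ and is flagged. Model selection is a majority vote of the six metrics
(minimize BIC/AIC/entropy, maximize silhouette/Dunn/Calinski–Harabasz) with
ties broken toward smaller k (parsimony). AIC is the sixth metric because
only five are named in the source description of a six-metric vote; all six
votes are surfaced rather than hiding the choice.

Sensitivity clusterings: best-of-restarts Lloyd k-means (k-means++ starts),
and unsupervised random-forest clustering — a synthetic contrast set drawn
by permuting each metabolite independently, a real-vs-synthetic forest,
proximity = fraction of trees co-terminating two real samples, Ward tree on
√(1 − proximity).

Cluster letters: after cutting, clusters are named A, B, … by descending
grand-mean standardized level, so the metabolically elevated cluster is
always subtype A. This is the only labeling rule; nothing about survival
enters it.

### Differential ranking and enrichment

Wilcoxon rank-sum tests are exact (full enumeration) when the combined
sample size is ≤ 12 without ties, else the midrank normal approximation
with tie-corrected variance and continuity correction — the only practical
path at n = 209. Benjamini–Hochberg adjustment is the standard step-up.
Selection is threshold-driven (adjusted p < 10⁻⁵), with the implied
selected fraction reported because a "top fraction" description of the same
cut is inherently arbitrary.

Enrichment is the uncorrected Pearson χ² (df = 1, upper tail) on the 2×2
hit table against the assayed background — *not* Yates-corrected, a choice
pinned down by the worked example χ²(186, 38, 6, 4) = 8.15, p = 0.004
(the continuity-corrected value would be ≈ 5.9). Direction
(enriched/depleted about the expected hit count mT/N) is reported separately
from the two-sided p, and any expected cell below 1 flags the row.

The null p-value of this test is discrete (the hit count takes ~20 values
at study scale), so its raw Kolmogorov–Smirnov distance from uniform is
dominated by jump sizes no matter how good the statistic. Calibration is
therefore defined jump-aware — the uniform diagonal must pass within every
CDF jump interval to 0.02 — together with a rejection-rate check at the
0.05 level (±0.02). Measured: diagonal misses ≤ 0.002 and rejection ~0.047
for tables with all cell expectations ≥ 5.

### Survival

Kaplan–Meier, log-rank, Cox and time-varying Cox fits are delegated to
`lifelines` (Efron tie handling — the better approximation under heavy
ties; the source is silent on this). The package owns covariate encoding
(one-hot, first vocabulary level as reference), the model ladder
(unadjusted; age/sex/HPV[+smoking in the full cohort]; fully adjusted with
race, BMI, alcohol, marital status, tumor site and stage, treatment, ECOG,
feeding tube, comorbidity, albumin, hemoglobin, NLR, PLR), missing-covariate
row dropping with counts, and the stratification scheme (full cohort,
never-smokers, ever-smokers, ever-smokers × HPV-related/unrelated). Strata
ladders drop dummy levels that are constant within the stratum; monotone
likelihoods are flagged and refit with a small ridge rather than silently
diverging.

The proportional-hazards check episode-splits each subject at the observed
event times and adds a covariate × t term (linear t by default, log t as an
option; the functional form is otherwise unstated) to a counting-process
Cox model; the Wald p of the interaction is returned. Its level is
calibrated at 0.05 ± 0.02 under proportional hazards in the acceptance
suite.

Three-year status: dead = event at or before 3 years; alive = followed past
3 years; censored before 3 years is excluded (and counted) — the honest
treatment when early censoring is rare. The three logistic models
(HPV-only, subtype-only, HPV+subtype) are compared by training-data ROC/AUC
with Mann–Whitney tie handling.

## The synthetic cohort

The generator encodes the target study conditions; its defaults are the
conditions, not tuning knobs.

- **Cohort**: n = 209; latent subtype A prevalence 0.41, independent of all
  covariates except age (per-subtype means 61.7 / 57.6 years, SD 10);
  smoking never/former/current = 0.39/0.33/0.28; HPV-related 0.48; the
  remaining categorical frequencies and lab means/SDs follow the cohort
  description table; 5% of lab values missing at random so the fully
  adjusted Cox model drops a realistic number of subjects.
- **Metabolome**: 186 library metabolites (125 HILIC+, 61 C18−) plus 20
  unidentified features. Latent log₂ abundance = feature baseline
  (U(14, 24)) + subtype shift + unit-variance noise with exchangeable
  within-pathway correlation (0.5 in the four co-regulated signal pathways,
  0.1 in null pathways — consistent with a near-zero metabolite-wide median
  pairwise correlation alongside a few highly correlated groups). Subtype
  effect sizes were back-computed from the printed per-metabolite Z-score
  pattern: pathway shifts 0.75–1.15 SD (fatty-acid 1.0, acetyl transfer
  0.75, arginine/proline 0.9, galactose 1.15, applied to 4/3/5/3 members
  respectively), 24 diffuse differential metabolites at U(0.75, 1.2), and a
  40-metabolite weak tail at U(0.3, 0.7) because differential expression
  does not stop abruptly at a selection threshold. An observed standardized
  group separation d corresponds to latent shift δ via
  d = δ / √(1 + p(1−p)δ²), p = 0.41 — the identity the effect-size
  fidelity test checks at large n.
- **Technical layer**: three replicates per sample with per-feature
  log-normal CV heterogeneity around a median of 0.10 (level-1 metabolites
  are analytically well behaved; a high-CV tail lives among the
  unidentified features and exercises the CV filter); four batches with
  additive (SD 0.4 log₂) and multiplicative (log-SD 0.1) effects;
  missing-not-at-random detection, logistic in the sample-level log₂ value
  about a per-feature detection threshold (rate 0.015, slope 6), calibrated
  so a default run imputes ~2.4% of cells (< 3%).
- **Survival**: exponential event times with group hazard
  λ = −ln(0.863)/3 × HR, where HR is 3.0 for subtype-A ever-smokers, 1.0
  for subtype-A never-smokers, and never-smokers carry a 0.6 baseline
  multiplier (so S_B(3) ≈ 0.915 among never-smokers). Progression is an
  independent exponential at 0.5× the mortality hazard and PFS =
  min(progression, death), which guarantees PFS ≤ OS; administrative
  censoring is U(2.5, 8) years (≈ 9% of censored subjects below the 3-year
  horizon) and a 9.6% loss-to-followup fraction is flagged completely at
  random. With censoring disabled the closed forms S_B(3) = 0.863 and
  S_A(3) = 0.863³ ≈ 0.643 are recovered to ±0.005 at n = 100,000.

What the generator does **not** emulate: raw chromatograms or spectra,
adduct structure beyond a label, retention-time drift, nutritional decline
or cachexia dynamics, correlated covariate structure (all covariates except
age are independent of subtype by design), and real biological pathway
topology. Passing tests therefore demonstrate that the pipeline recovers
the statistical structure it assumes — planted subtypes, planted
enrichment, a planted subtype × smoking hazard interaction — not that any
particular real cohort clusters this way.

## Problem sizes and seeds

All randomness flows from one integer seed through independent numbered
streams per stage, so regenerating one layer never perturbs another; the
whole pipeline is byte-reproducible given a config. Suite sizes used by the
tests and the acceptance script: 10 seeds for subtype recovery (k chosen by
majority vote each run; median adjusted Rand index vs planted labels
≥ 0.8), 25 seeds for hazard-ratio recovery (median ever-smoker HR within
[2.2, 4.1]; never-smoker CI covering 1 in ≥ 80%), 1,000 replicates each for
the Wilcoxon and proportional-hazards level checks, 10,000 draws for the
enrichment null. Large-n checks use 50,000 (marginals, hazard rates) or
100,000 (closed-form survival points) patients on the clinical layer only,
which is cheap because no metabolome is generated there.

## Known limitations

- The empirical-Bayes batch adjustment assumes normal location and
  inverse-gamma scale effects; heavy-tailed batch artifacts will be
  under-corrected.
- Sum-of-squares BIC/AIC are heuristics, not likelihood-based criteria; they
  are deliberately paired with four geometry-based metrics in the vote.
- The χ² enrichment p is an approximation to the hypergeometric tail; at
  expected hit counts below ~5 rows are flagged rather than switched to an
  exact test, keeping the statistic uniform across the table.
- Cox ladders in small strata with the full covariate set are close to
  saturated (tens of events vs ~25 parameters); wide intervals and flagged
  refits are expected there, and mirror the behavior of the equivalent
  analysis on real cohorts of this size.
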