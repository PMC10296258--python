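# metabotype

Prognostic metabolic subtyping of plasma metabolomics cohorts.

Head and neck squamous cell carcinoma (HNSCC) patients differ widely in
outcome, and the usual prognostic factors (HPV status, stage, smoking) leave
much of that variation unexplained. Untargeted LC-MS plasma metabolomics
offers a non-invasive window on systemic metabolism: clustering patients on
their pre-treatment circulating metabolite profiles can reveal *metabolic
subtypes* with different survival — information a blood draw can supply
before treatment begins. `metabotype` implements that analysis end to end
for statisticians and translational researchers:

1. **Preprocessing** of replicate-level feature intensities: median
   replicate-CV filtering (features with median CV ≥ 0.75 removed),
   triplicate median summarization (≥ 2 observed replicates required),
   empirical-Bayes location/scale batch correction, missingness filtering
   (> 20% removed), k-NN imputation, per-metabolite log₂ / Z-score
   standardization `z = (log₂x − μ) / σ`, level-1 library matching (m/z
   within 10 ppm, retention time within 30 s), and pooling of the
   HILIC-positive and C18-negative chromatography runs.
2. **Subtype discovery** by agglomerative clustering with Euclidean distance
   and Ward.D linkage (the Lance–Williams recurrence on unsquared
   distances), scored over k = 2…6 with six validity metrics — BIC, AIC,
   silhouette, Dunn, Calinski–Harabasz, allocation entropy — and the cluster
   count chosen by metric majority vote. K-means and unsupervised
   random-forest-proximity clusterings are available as sensitivity checks.
3. **Differential ranking** of metabolites between the subtypes by two-sided
   Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment, selecting the
   set with adjusted p < 10⁻⁵.
4. **Pathway enrichment** of the selected set against the assayed background
   via the uncorrected Pearson χ² on the 2×2 table
   `[[k, m−k], [T−k, N−m−T+k]]` (background N, selected T, pathway size m,
   hits k), df = 1.
5. **Survival analysis**: Kaplan–Meier curves and log-rank tests by subtype,
   Cox proportional-hazards ladders (unadjusted → age/sex/HPV[/smoking] →
   fully adjusted), a proportional-hazards check via a subtype-with-time
   interaction on episode-split data, stratification by smoking history and
   HPV status, and a three-year alive/dead logistic regression with ROC/AUC
   comparison of HPV-only, subtype-only and HPV+subtype classifiers.

Because patient-level metabolomics cohorts are rarely public, the package
includes a first-class **synthetic cohort generator** that emulates the
study design this pipeline targets: 209 patients, 186 level-1-identified
metabolites in two modes, triplicate injections with batch structure and
intensity-dependent (MNAR) missingness, a latent 41%/59% two-subtype split
with pathway-concentrated effect sizes, and exponential survival in which
the high-risk subtype carries a ~3-fold hazard among ever-smokers but none
among never-smokers.

## Worked example

```python
from metabotype import (SimulationConfig, generate_cohort,
                        PrognosticSubtypeModel, PipelineConfig)

cohort = generate_cohort(SimulationConfig(seed=0))
model = PrognosticSubtypeModel(cohort.raw, cohort.clinical, cohort.library,
                               cohort.pathway_map, PipelineConfig(seed=0))
results = model.fit()
print(results.summary())
```

```
Prognostic metabolic subtype analysis
==========================================
samples: 209   metabolites: 186
chosen k: 2 (votes: {'bic': 2, 'aic': 3, 'entropy': 2, 'silhouette': 2, 'dunn': 5, 'calinski_harabasz': 2})
subtype sizes: {'A': 89, 'B': 120}
selected metabolites: 38 of 186
top enriched pathways:
  Fatty acid biosynthesis: k=4/m=6 chi2=8.15 p=0.0043 (enriched)
  Transfer of acetyl groups into mitochondria: k=3/m=5 chi2=4.95 p=0.0261 (enriched)
  Glycine and serine metabolism: k=0/m=14 chi2=3.89 p=0.0487 (depleted)
  Arginine and proline metabolism: k=5/m=12 chi2=3.56 p=0.0592 (enriched)
OS HR A vs B, full (adjusted): 2.19 (1.27, 3.79), p=0.00501
OS HR A vs B, ever_smokers (adjusted): 2.38 (1.31, 4.33), p=0.00459
OS HR A vs B, never_smokers (adjusted): 1.18 (0.27, 5.14), p=0.828
```

Reading the output: four of six clustering metrics vote for two clusters;
the 89-patient subtype A sits high on the co-regulated fatty-acid /
acetyl-transfer / amino-acid / sugar pathway metabolites (positive mean Z)
and carries the excess mortality; 38 of 186 metabolites separate the
subtypes at adjusted p < 10⁻⁵; four of the six fatty-acid-biosynthesis
metabolites land in that selected set, a draw with probability ~0.004 under
random selection (χ² = 8.15, df = 1); and the subtype → survival association
is concentrated in ever-smokers (adjusted hazard ratio 2.38 vs a
never-smoker CI straddling 1), recovering the planted ×3 / ×1 hazard
structure.

`results` also carries the full metric table (`results.metric_table()`),
per-metabolite differential statistics (`results.differential`), the
enrichment table (`results.enrichment`) and the per-stratum survival report
(`results.survival_report`); plotting helpers live in `metabotype.plots`.

## Command line

Every stage is exposed as a subcommand of the `metabotype` console script:

```bash
metabotype simulate --out cohort/ --seed 0
metabotype preprocess --features cohort/features.tsv --library cohort/library.tsv --out matrix.tsv
metabotype cluster --matrix matrix.tsv --kmin 2 --kmax 6 --out labels.csv
metabotype rank --matrix matrix.tsv --labels labels.csv --out ranked.csv
metabotype enrich --ranked ranked.csv --gmt cohort/pathways.gmt --out enrichment.csv
metabotype survive --clinical cohort/clinical.csv --labels labels.csv --out survival.json
metabotype run-all --out run/ --seed 0     # all of the above + report.json
```

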