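# netprog

Network-based discovery and evaluation of multi-omic prognostic
subnetworks for cancer survival analysis.

Tumor cohorts profiled on several molecular levels (mRNA expression,
copy-number variation, promoter DNA methylation) rarely yield single-gene
survival markers that replicate: the signal is spread across interacting
genes perturbed through different mechanisms. `netprog` implements a
pipeline that pools weak per-gene survival associations over a
protein-protein interaction (PPI) network to find *subnetworks* — modules
of interacting genes whose combined molecular profile predicts overall
survival — and turns them into patient-level risk scores and survival
strata. It is aimed at computational biologists studying prognosis in
heterogeneous cancers (the motivating setting is triple-negative breast
cancer) and ships with a synthetic-cohort generator so the whole pipeline
is testable without access to restricted patient data.

## Method

1. **Screening.** Every (gene, modality) feature is fitted in a Cox
   proportional-hazards model adjusted for age; significance is the 1-df
   likelihood-ratio test of (feature + age) against age alone, with Efron
   tie handling. Features with `p < 0.05` are survival-related. For
   methylation, one probe per gene is retained (smallest LRT p).
2. **Heat scoring.** Per gene, the selected p-values are combined by
   Fisher's method, `score = -2 * Σ_m ln(p_m)` over
   `m ∈ {mRNA, CNV, methylation}`; genes with positive score form the
   survival-related gene set.
3. **Subnetwork discovery.** Scores diffuse over the PPI network by
   insulated heat diffusion (random walk with restart `β`):
   `F = β (I − (1−β) W)⁻¹` with `W_ij = A_ij / deg(j)`. The exchanged
   heat `E_ij = F_ij h_j` is thresholded at `δ` (chosen so permuted heat
   yields no reportable component); strongly connected components with
   ≥ 4 genes are candidate subnetworks, with empirical size-class
   p-values from heat permutation.
4. **Prognostic evaluation.** Each subnetwork's multi-omic profile is
   scored by Monte-Carlo cross-validation: 100 random 80/20 splits, an
   elastic-net penalized Cox model per split, Harrell's concordance index
   (C-index) on the held-out split. The median C over splits is the
   subnetwork's predictive value; a survival-permutation test gives its
   significance. Models pass with median C > 0.5 and permutation p < 0.05.
5. **Risk scoring (snRS).** Features selected in more than 5 of the
   splits are refitted in an unpenalized multivariable Cox model; the
   subnetwork risk score is the linear combination `snRS_i = Σ_f β_f x_fi`.
   Patients split at the median snRS are compared by Kaplan-Meier curves,
   the log-rank test, and clinically adjusted Cox regression.
6. **Stratification.** Stable features pooled across all models with
   median C > 0.5 are clustered by consensus non-negative matrix
   factorization (k = 2 by default) into survival-compared strata.

## Worked example

Simulate a cohort with one planted 8-gene prognostic module and run the
full pipeline:

```sh
netprog simulate --sim-config sim.yaml --out data/
netprog run-all --data data/ --config cfg.yaml --out run/
```

with `sim.yaml` asking for 150 genes, an 8-gene module (per-feature
log-HR 0.8), 200 patients and 30% censoring, and `cfg.yaml` reducing the
split/permutation budgets for a quick run (`n_cv_splits: 25`,
`n_permutations: 20`). The run summary printed at the end:

```
best_median_c: 0.8464849354375896
n_events: 137
n_models: 1
n_passed: 1
n_patients: 200
n_selected_features: 48
n_subnetworks: 1
n_survival_genes: 37
risk_hr: 9.930825039467422
risk_logrank_p: 1.2701619335690383e-34
strata_logrank_p: 0.0017914401531728954
```

Reading: screening kept 48 of ~900 features, mapping to 37
survival-related genes; diffusion found one subnetwork (it contains the
planted module); its profile predicts held-out survival with median
C-index 0.846 (0.5 would be chance) and passes the permutation filter;
the median-split snRS separates the cohort into risk groups with hazard
ratio ≈ 9.9 (log-rank p ≈ 1e-34); the consensus-NMF strata also differ in
survival (log-rank p ≈ 0.002). Per-stage tables (screening statistics,
gene heats, subnetwork memberships as TSV/GMT, per-split C-indexes, snRS
and KM tables, cluster labels) are written into `run/`.

Every stage is also available as a library function
(`netprog.screening`, `netprog.heat`, `netprog.discovery`,
`netprog.evaluation`, `netprog.risk`, `netprog.stratify`) and as a CLI
subcommand (`screen`, `score`, `discover`, `evaluate`, `risk`,
`stratify`).

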