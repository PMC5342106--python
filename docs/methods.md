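# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, the design decisions taken where the procedure
was genuinely open, and what the synthetic cohorts do and do not emulate.

## Survival screening

Each (gene, modality) feature `x` is fitted in the proportional-hazards
model `h(t | x, age) = h0(t) exp(β1 x + β2 age)` by maximum partial
likelihood with the Efron approximation for tied event times. The
reported p-value is the 1-df likelihood-ratio test against the age-only
model, so the age-only log-likelihood is computed once per cohort.
Features are z-standardized before fitting; coefficients are therefore
log hazard ratios per standard deviation and comparable across
modalities, and the LRT p is invariant to affine rescaling of a feature.
Direction is reported as "P" (HR > 1, worse prognosis) or "G" (better).

Fitting is a Newton solver vectorized across features (all features
share the outcome and the age covariate, so the risk-set suffix sums are
formed for the whole feature block at once), with step-halving and a
divergence guard (|β| > 50 flags non-convergence; such features are
excluded from selection). The solver is checked against lifelines'
`CoxPHFitter` in the test suite (coefficients, standard errors and LRT
p-values agree to ≤ 1e-5).

Decisions:

- screening adjusts for age only; the richer clinical covariates enter
  later, in the risk-model adjustment table;
- no multiple-testing correction at screening — the selection rule is the
  raw `p < alpha_screen` (default 0.05) and the heat score is built from
  exactly the selected features;
- "the methylation probe most correlated with survival" is
  operationalized as the probe with the smallest screening LRT p
  (ties broken by lexicographic probe id), which keeps a single statistic
  for censored outcomes rather than defining a separate correlation;
- constant features are flagged degenerate and never selected; missing
  values are resolved upstream (features > 20% missing in the core set
  are dropped, the remainder median-imputed, both logged).

## Heat scores

`score(g) = -2 Σ_m ln p_m` over the gene's *selected* modality p-values
(at most one per modality after probe collapse) — Fisher's combination.
An empty sum is 0, and genes with positive score form the
survival-related set. Numerically zero p-values are floored at the
smallest positive double and logged. The factor 2 follows the combining
rule for independent tests; monotonicity (smaller p, larger score) and
additivity over disjoint feature sets are asserted as properties.

## Insulated diffusion and subnetwork extraction

With adjacency A, walk matrix `W_ij = A_ij / deg(j)` and restart
probability `beta_restart` (default 0.4, the usual choice for PPI
networks), the diffusion operator is `F = β (I − (1−β) W)⁻¹`, computed by
a linear solve per connected component (never an explicit inverse);
isolated nodes keep their own heat. F is column-stochastic, so the
exchanged heat `E_ij = F_ij h_j` conserves column mass: `Σ_i E_ij = h_j`.
Genes absent from the heat table are cold (h = 0); heat on genes absent
from the network is dropped with a logged count.

Subnetworks are the strongly connected components of the directed graph
with an arc j → i wherever `E_ij > δ` (diagonal ignored), keeping
components with at least `min_subnetwork_size` (default 4) genes.

δ selection ("auto"): for each of `auto_delta_perms` (default 10)
uniform permutations of the heat vector over network genes, take the
smallest δ at which the largest SCC falls below a size cap, and return
the median. The cap defaults to `min_subnetwork_size + 1`: δ is pushed
just high enough that permuted heat yields no component of reportable
size. This is the package's own resolution of a parameter the published
procedure leaves unstated; on planted-module simulations it separates
the module from the background, whereas visibly larger caps (e.g. 10)
leave δ low enough that chains of background genes with
chance-significant features merge into the hot module's component.

Significance: heats are permuted `discovery_n_perm` times; for each
observed size s, p(s) is the add-one fraction `(k+1)/(n+1)` of
permutations with at least as many SCCs of size ≥ s as observed. Every
subnetwork is annotated with its size-class p. Subnetworks discovered in
different PPI networks are matched by Jaccard gene overlap ≥ 0.5.

## Monte-Carlo cross-validated evaluation

A subnetwork's profile is the patients × features matrix of the selected
features of its member genes (z-standardized). Predictive value is the
median Harrell C-index over `n_cv_splits` (default 100) random splits
with `train_frac` 0.8: per split, features are re-standardized on the
training part, an elastic-net penalized Cox model
(`l1_ratio = enet_mix`, default 0.5; regularization path of `n_alphas`
points with the strength chosen by `inner_cv_folds`-fold held-out
concordance, or fixed via `fixed_alpha`) is fitted on train, and the
linear predictor is scored on test. Splits without events on either side
are redrawn; an all-zero model scores C = 0.5 (no information).
Selected-feature counts accumulate across splits.

Harrell's C counts pairs where one patient is known to fail first
(earlier observed event, or tied time with exactly one event): a pair is
concordant when the earlier-failing patient has the higher predicted
risk, tied risks count 0.5. Both the implementation and an independent
brute-force pair enumeration, and agreement with lifelines on tie-free
data, are asserted in tests.

The permutation test jointly permutes (time, event) across patients
`n_permutations` times (default 100) and re-runs the cross-validation
with `perm_cv_splits` (default 20) splits per permutation — a
fidelity/runtime trade-off; set `perm_cv_splits = n_cv_splits` for full
fidelity. p is the add-one fraction of permuted median C ≥ observed. For
null calibration studies the observed median must be computed under the
same reduced settings as the permuted replicates, otherwise the add-one
p is no longer exchangeable. Models pass with median C > 0.5 and
permutation p < 0.05; ranking is by median C descending, ties by
permutation p then id.

The genome-wide baseline (`baseline_molecular_model`) mirrors the same
loop over all features of one or more modalities, with a univariate
pre-selection (`p < alpha_screen`) performed *inside* each training
split to avoid selection leakage.

## Risk scores and stratification

Features selected in strictly more than `stability_min_count` (default
5) splits are refitted in an unpenalized multivariable Cox model on the
full cohort (ridge fallback 0.01 → 0.1 on non-convergence or
collinearity, logged); the snRS is the linear predictor under those
frozen coefficients. In external-cohort mode only the mRNA features and
their original coefficients are used — no refit and no renormalization,
which is a documented limitation when the dropped modalities carried
signal. Patients are split at the median snRS (ties go to the low-risk
group, a deterministic and conservative rule); groups are compared by
the product-limit estimator with Greenwood confidence bands, the
log-rank test, and a Cox fit of the group indicator; snRS enters the
clinical adjustment table as a continuous covariate next to age, stage
dichotomized III/IV vs I/II, lymph-node count and tumor weight.

Stratification pools the stability-selected features of all models with
median C > 0.5, min-max scales each feature to [0, 1] (the simplest
rank-preserving map into the NMF domain), runs `nmf_runs` (default 50)
NMF factorizations of rank `nmf_k` (default 2) from random starts,
labels each patient by the dominant factor, and cuts the co-clustering
consensus matrix by average-linkage hierarchical clustering into k
strata, compared by log-rank and pairwise hazard ratios.

## Synthetic cohorts

The generator plants `n_modules` disjoint modules of `module_size` genes
in a planted-partition graph (within-module edge probability `p_in`,
background `p_out`), emulating a sparse interactome with dense
functional modules. Features: mRNA standard normal; CNV a continuous
GISTIC-like score N(0, 0.5²); methylation beta values
`logistic(probe intercept + gene latent + probe noise)` with 1–3 probes
per gene, so planted effects act on the latent (logit) scale and beta
values stay in [0, 1]. A fraction `frac_active_features` of the planted
(gene, modality) pairs carries log hazard ratio `effect_log_hr` per SD;
survival times follow a Weibull proportional-hazards model (shape 1.2,
scale 60 time units — a gently increasing hazard over a breast-cancer
follow-up scale) with that linear predictor; censoring is independent
exponential with the rate solved numerically (Brent) so the expected
censored fraction matches `censoring_rate` (default 0.3). Clinical
covariates (age, stage, lymph-node count, tumor weight) are generated
independently of the molecular features. All stages draw from named
substreams of a single master seed, so identical configs reproduce
bit-identical cohorts.

Defaults were fixed once as a plausible desk-scale cohort (300 genes,
one 8-gene module, 400 patients, log-HR 0.7, 60% active features).
What the simulations do *not* emulate: platform/batch artifacts,
correlated co-expression structure outside the planted modules,
copy-number segmentation, probe cross-hybridization, informative
censoring, or clinical covariates confounded with molecular features.
Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated model, not that the pipeline's
power estimates transfer to real tumor cohorts.

Note that with many simultaneously active features the marginal
(single-feature) hazard ratios are attenuated relative to the planted
conditional effects — an expected property of omitted-covariate Cox
models that the screening power tests account for.

## Numerical choices and degenerate inputs

- Newton convergence at max |gradient| < 1e-8·n, 60 iterations,
  25 step-halvings; observed information gets a 1e-10 ridge floor.
- Wald CIs use z = 1.96 (95%).
- Empirical p-values always use the add-one estimator, so p = 0 is
  impossible and p has granularity 1/(n_perm + 1).
- β = 1 makes F the identity (no heat exchange): subnetworks are then
  impossible by construction, and auto-δ refuses the all-zero ensemble.
- Constant risk scores, single-cluster labelings, event-free splits,
  empty pre-selections and empty stability sets are all explicit,
  logged degenerate paths rather than crashes.
- Problem sizes in the shipped tests (cohorts of 150–500 genes,
  150–500 patients, reduced split/permutation budgets for calibration
  loops) were chosen as desk-scale study conditions; all replicate
  counts of the calibration suites (50-seed recovery, 200-seed type-I,
  100-replicate coverage, 1000-replicate concordance) are run in full.
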