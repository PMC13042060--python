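# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Synthetic cohort generator

The generator emulates a multi-region, multi-donor snRNA-seq study of the
adult human striatum and cortex. Its defaults are the study conditions the
analyses assume, not tuning knobs:

- **Donors.** 150 by default; ages uniform on 27–90 years, with any age
  above the cap (90) collapsed to 90, mirroring brain-bank privacy
  handling of ages above 89; sex Bernoulli with male fraction 111/178
  (the composition of the emulated cohort); villages of 20 donors.
- **Regions.** Caudate head (CaH), putamen (Pu), nucleus accumbens (NAC),
  internal capsule (ic), dorsolateral prefrontal cortex (DFC).
- **Counts.** For donor *i*, region *r*, cell type *g* the latent logit
  fraction is `l = baseline_g(r) + slope_g*(age-60)/10 + u_ig + e_igr`,
  with `u ~ N(0, tau2)` shared across regions and `e ~ N(0, sigma2)` per
  sample. Counts are one multinomial per sample over
  (cell types..., remainder) with `p_g = expit(l_g)`; totals are Poisson
  with mean 5,000 nuclei. This keeps compositional closure (counts sum to
  the total) while making each focal type's marginal logit *exactly* the
  linear predictor — the model the abundance analyses fit. A softmax over
  all-type logits would also close the composition but distorts each
  type's marginal slope by the softmax Jacobian (≈3% for a 3% type),
  which would contaminate parameter-recovery testing; the
  direct-marginal construction was chosen for that reason. If latent
  fractions ever sum above 0.995 the row is rescaled defensively; default
  variances keep this rare (<1%).
- **Abundance defaults.** OPCs: 3% of nuclei at age 60, slope −0.096
  log-odds/decade, tau²=0.04, sigma²=0.02. TAC3-PLPP4 interneurons: 1.5%
  of neurons, slope −0.047/decade. MSN-subtype compositions: caudate
  D1/D2 odds 1.23 (putamen 1.00, accumbens 1.02), striosomes 17% of MSNs,
  eccentric MSNs 19% of MSNs in NAC and 7% elsewhere. Glial shared
  variance comes from observed median pairwise fold differences
  (`exp(0.9539*sigma_shared)` = 1.2 for astrocytes/OPCs, 1.4 for
  microglia, giving sigma²_shared ≈ 0.0365 and 0.1244).
- **Cross-region sharing.** The correlation of a donor's two regional
  logits is `tau2/(tau2+sigma2)` by construction. The *r²* of measured
  fractions is smaller: squaring the correlation, expit nonlinearity, and
  binomial sampling all attenuate it. When a target fraction-scale r² is
  requested (`glial_sharing_config`), the latent correlation is found by a
  deterministic Monte-Carlo root-find (400k common-random-number donors,
  Brent's method) so that the population r² of measured fractions at
  5,000 nuclei equals the target; total latent variance is anchored as
  sigma²_shared/√r². The uncalibrated mode (`calibrate=False`) sets the
  ratio directly.
- **Expression.** Per gene and cell type, log2-CPM mean = baseline +
  log2FC/decade × (effective age − 60)/10 + sex effect + eQTL effect ×
  dosage; effective age adds optional donor-shared and per-cell-type
  "biological age" offsets (used to study clock residual correlations).
  Counts are gamma-Poisson around `library × 2^log2cpm / 1e6` with
  dispersion 0.05 (per-donor pseudobulk CV ≈ 22%; at dispersion 0.2 the
  CV ≈ 45% swamps realistic age effects and none of the expression
  analyses have power at n≈150, which contradicts the emulated study's
  structure of thousands of detectable age effects and ~5-year clocks).
  Libraries are log-normal (ln-mean 15, ln-sd 0.3). chrY genes are zeroed
  in XX donors; a few chrX genes are elevated in XX donors. Default
  age-effect scale is 0.1 log2FC/decade; eQTL effects 0.6 log2/allele
  split ≈16% pan-cell-type, ≈16% neuron-shared, ≈68% cell-type-specific.
- **Genotypes.** Independent SNPs in Hardy–Weinberg proportions with MAF
  in (0, 0.5]; no linkage disequilibrium is simulated.
- **Determinism.** All draws descend from `CohortConfig.seed` through
  `numpy.random.SeedSequence` spawn keys; identical config+seed gives
  byte-identical outputs, and the `TruthRecord` retains every latent.

What the generator does **not** emulate: droplet-level effects (ambient
RNA, UMI saturation), real LD, batch/village technical effects beyond what
QC fixtures inject, non-uniform age distributions, or gene–gene
correlation beyond shared factors. Passing tests therefore demonstrate
correctness of the estimators under the assumed generative structure, not
robustness to artefacts real pipelines remove upstream.

## Abundance model

Beta-binomial likelihood with logit link; overdispersion parameterized as
rho ∈ [0,1) via (a,b) = (mu, 1−mu)·(1−rho)/rho. Optimization: analytic
score vector, L-BFGS-B from a least-squares empirical-logit warm start,
rho initialized at 0.05, the logit of rho bounded in [−20, 5]. The
observed information is a central finite difference of the analytic
gradient. Non-convergence raises unless the final gradient is already
negligible. The MLE is verified against a grid-search oracle on small
instances (≤1e−4 log-likelihood units).

Because age and sex are donor-level covariates and donors contribute one
sample per region with a shared latent propensity, model-based standard
errors on pooled multi-region fits undercover badly (≈70% for a nominal
95% CI in simulation). Clustered fits therefore default to a
donor-clustered sandwich covariance with CR1 small-sample scaling
(G/(G−1)) and t(G−1) critical values; coverage in 400-seed simulations is
≈0.93. Headline p-values for age and sex are the clustered Wald t tests;
the likelihood-ratio test (which assumes independent observations and is
anti-conservative under clustering) is used only for unclustered fits.

Two intrinsic biases are worth knowing. (1) The fitted slope is a
*marginal* (population-averaged) effect: fitting a marginal beta-binomial
to logit-normal mixing attenuates the conditional generating slope by
≈3% at these variances (a binomial GLM shows ≈2% of it); recovery tests
bound the absolute bias at 0.01 log-odds/decade and observe ≈0.003.
(2) A per-donor count ratio such as D1/D2 carries a Jensen bias of order
1/(N·p₂) (≈+0.2% at 1,500 MSNs); the composition recovery tests use a
tolerance of three per-seed Monte-Carlo standard errors of the
cohort-mean estimator, an order of magnitude above this bias.

The median pairwise fold difference uses the exact Gaussian constant
`median|X−Y| = sqrt(2)·Phi^{-1}(3/4)·sigma = 0.95387·sigma` with the
shared variance estimated as the (non-negative) covariance of paired
log fractions, and a donor bootstrap CI.

## Differential expression

Weighted least squares per gene with one shared design (intercept, age in
decades centred at 60, sex, declared covariates), weights log(cell
count); this is exactly OLS when weights are equal, which the tests
exploit as an oracle. Genes expressed in <25% of donors are skipped. BH is
applied within (cell type, region) separately for the age and sex
families. The linear model on log2 CPM (rather than a count GLM) keeps
the estimators closed-form and oracle-checkable; pseudobulk aggregation
over hundreds of nuclei makes the Gaussian approximation serviceable.

The transcriptome-wide impact is the first moment of squares:
`mean_g(beta_hat_g^2 − SE_g^2)`. It is unbiased for the mean squared true
effect, pure-noise genes contribute zero in expectation (adding them
dilutes by the known gene-count ratio), and its SE comes from a
1,000-resample gene bootstrap. The full distributional deconvolution of
true-effect distributions is intentionally out of scope; outputs are
labelled "TWI (simplified)".

Gene age-profile clustering defaults to k=8 with 50 k-means restarts; a
gap-statistic report (uniform-box reference) is provided because the
appropriate k is not identifiable a priori. Cross-cell-type effect
correlations are Spearman rho² on union-significant genes (q<0.05 in
either member), with an all-genes variant for sensitivity.

## Aging clocks

Elastic net with mixing 0.5 and a 50-point penalty grid 10⁻³…10², inner
5-fold CV on each training fold, outer 10-fold CV for out-of-sample
predictions, prediction SD from repeated outer CV (20 shuffles by
default). Standardization lives inside each training fold, so a corrupted
held-out donor cannot leak into other folds' predictions (asserted by a
spiked-donor test). Feature genes are the cell type's age-associated DE
genes; selecting them on the full cohort mirrors the emulated study's
procedure and is a known, deliberate simplification.

The bias curve is a P-spline: cubic B-spline basis on 12 equally spaced
knots, second-difference penalty, smoothing weight chosen by GCV over a
41-point log grid. The penalty null space is linear, so the fit always
absorbs straight-line shrinkage of predictions toward the cohort mean;
corrected residuals are uncorrelated with age (observed |Spearman|<0.05
per run). The curve was implemented directly because the installed
GAM facility cannot select its penalty in the presence of a parametric
linear term, and without that term its penalized fit leaves an
age-correlated residual trend.

## cis-eQTL mapping

Per cell type: log2 CPM, per-gene Blom inverse-normal transform
((rank−3/8)/(n+1/4) through the normal quantile), covariates (intercept,
age in decades, sex) projected out of both expression and dosage
(Frisch–Waugh, so the marginal slope equals the full-model OLS dosage
coefficient to machine precision — asserted against a statsmodels
oracle), and t statistics with n − covariates − 2 degrees of freedom.
cis windows are ±1 Mb around the TSS; SNPs below 5% MAF are excluded;
gene-level p is min-p × number of cis SNPs capped at 1; eGenes by BH at
FDR 0.01 within cell type; genes with no cis SNP are reported as NA rows.
Fold-change-scale effects (log2 CPM without the rank transform) are
computed for the constraint analysis, since rank-transformed effects are
not comparable across genes on a fold-change scale. Sign orientation
flips a row when negatives outnumber positives (ties broken by the row
sum) and is idempotent. The lead SNP is chosen in the best cell type and
propagated to all others, which reconciles per-cell-type discovery with
one row per eGene in the effect matrix.

## Village QC

Genotypic doublet expectation `1 − Σp_i²`; total-rate inversion; per
cluster a one-sided exact binomial tail against the dataset-wide rate with
BH across clusters, flagged only when also ≥2× enriched (so very large
clusters with trivial excess are not flagged). Sample exclusion:
total nuclei < 500, then per region robust z (median/MAD with the 1.4826
consistency factor) on centred-log-ratio coordinates (pseudocount 0.5 for
zeros; interneuron counts of zero do occur) with threshold 4; a
coordinate with zero MAD treats any deviation as infinitely outlying.
Thresholds are configuration, not claims: the emulated study reports only
the resulting exclusion fractions (~15% of samples, ~5% in expression
analyses), not its rule.

## Simulation sizes used by the automated checks

Slope recoveries: 200 seeds × 150 donors (5 regions for the OPC design, 3
for the interneuron design; 131 donors, 1 region for the caudate
gray-matter OPC subtype design). Composition recoveries: 200 seeds ×
(131/100/97) donors. Cross-region sharing: 200 seeds × 114 paired donors.
Null calibrations: 200 seeds each with 100-donor, 2-region cohorts (four
cell types) for abundance, one cell type × 300 genes for expression, and
200 genes with ~10 cis SNPs each for eGene calls. Clock behaviour: 20
seeds × 120 donors × 3 cell types × 150 genes with a 4-year donor-shared
biological-age offset, one outer-CV repeat. These sizes are the package's
chosen desk-scale experiment designs; the generator accepts larger ones.

## Known limitations

- Beta-binomial effects are population-averaged; conditional
  (donor-specific) slopes are attenuated ≈3% at default variances. No
  random-effects formulation is provided.
- The expression model is Gaussian-on-log2CPM; a count GLM is not
  implemented.
- eQTL mapping tests single SNPs only — no haplotypes, no conditional
  or secondary signals, no permutation-based gene-level p (Bonferroni
  min-p is conservative when cis SNPs are correlated; with independent
  simulated SNPs it is nearly exact).
- Clock models are dataset-internal; coefficients are not transferable
  across datasets with different normalization.
- Village QC flags clusters; it does not reimplement donor-assignment
  likelihoods or expression-based same-donor doublet classifiers.
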