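# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic benchmark does and does not
establish about real data.

## O-PLS

Given a samples × features matrix X and a continuous response y, X is
centered and (by default) unit-variance scaled, y centered.  Orthogonal
components are extracted iteratively: from a provisional predictive weight
w ∝ Xᵀy the loading p = Xᵀt/(tᵀt) of the provisional score t = Xw is
computed, the orthogonal weight is w_o ∝ p − (wᵀp)w, and X is deflated by
the score/loading pair of w_o.  After `n_orth` rounds a single predictive
PLS component is fitted on the filtered matrix.  With `n_orth = 0` the
model is exactly one-component PLS1 (verified against scikit-learn in the
test suite).

Defaults and rationale:

* `n_orth = 1`, overridable, plus `choose_n_orth` which adds components
  while cross-validated Q²Y improves by more than 0.01 — a common
  chemometrics stopping heuristic.  One orthogonal component is the usual
  starting point for single-response omics models.
* Scaling: unit variance.  Pareto and no scaling are available; the
  upstream log10 transform is applied by the pipeline, not by the model.
* Q²Y = 1 − PRESS/SS_tot with leave-one-out folds by default; centering
  and scaling are re-estimated inside every training fold, so no
  information leaks from held-out samples.  An integer `cv` gives
  deterministic interleaved k-fold assignment (used where thousands of
  refits are needed).
* Permutation validation permutes y uniformly; both R²Y and Q²Y are
  recomputed per permutation and p-values use the +1-smoothed estimator,
  which can never return 0 and is exactly valid under exchangeability.
* VIP: predictive-component variant; for a single predictive component it
  reduces to √p·|w_j| and satisfies mean(VIP²) = 1 identically.  A
  total-variant weighting orthogonal components by explained X-variance is
  available behind a flag.
* Loading significance: the per-feature statistic is the Pearson
  correlation between the (scaled) feature and the predictive score t,
  tested two-sided on a t distribution with n − 2 df and BH-adjusted.
  Correlation-scaled loadings are the standard convention when a
  closed-form null for raw loadings is not available.
* Selection rule: pFDR < 0.05, or pFDR < 0.10 together with VIP > 1.

## O2-PLS

Joint weight pairs (W, C) are the leading singular vectors of YᵀX.
Block-specific orthogonal components are estimated one at a time as the
dominant left singular vector of EᵀT, where E = X − TWᵀ is the residual of
the joint reconstruction; the block is deflated by the corresponding
score/loading pair and the joint part re-estimated on the filtered
matrices.  Inner relations U ≈ TB and T ≈ UB′ are least-squares fits.
Component counts are chosen by symmetric k-fold cross-validation (7 folds
by default): the objective sums the standardized held-out squared error of
predicting Y from X and X from Y, because the model describes joint
variation rather than a directed regression.  Ties go to the smallest
total component count.  Correlation loadings are pcorr[j,k] =
corr(x_j, t_k), qcorr[j,k] = corr(y_j, u_k); zero-variance features are
reported as 0 with a warning.  Default orthogonal-component search grids
are 0–2 per block.

## Mnet (MCP + ridge)

Objective: (1/2n)‖y − Zb − Xβ‖² + Σⱼ MCP(βⱼ; λ₁, γ) + (λ₂/2)‖β‖² with
λ₁ = αλ and λ₂ = (1−α)λ, so α → 1 is concave-dominant and α → 0
ridge-dominant.  MCP(b; λ, γ) = λ|b| − b²/(2γ) for |b| ≤ γλ, else γλ²/2.
The univariate standardized coordinate update has the closed form
S(z, λ₁)/(1 + λ₂ − 1/γ) inside the MCP region and z/(1 + λ₂) outside;
γ(1 + λ₂) > 1 is enforced so each subproblem is strictly convex.  Features
are standardized internally with the 1/n variance convention and
coefficients back-transformed; the intercept and the covariate columns Z
are never penalized (covariates are updated as plain least-squares
coordinates).  Convergence is declared when the largest coefficient change
in a sweep falls below 1e-7.  Cross-validation uses a seeded shuffled
fold assignment, a warm-started descending λ path (default 100 points from
λ_max down to 0.001·λ_max), α ∈ {0.1, …, 0.9} and γ ∈ {2.5, 3, 8}; ties
are broken toward the sparser model (larger λ).  On small instances the
coordinate-descent solution is verified against a derivative-free
minimizer of the objective, and against LASSO (γ → ∞, α = 1) and OLS
(λ = 0) limits.

## Partial Spearman correlation

x, y and continuous covariates are rank-transformed (average ranks on
ties); categorical covariates (sex, country) enter as dummy columns —
ranking a binary indicator is affine and multi-level categories have no
order.  rho is the Pearson correlation of the residuals of ranked x and
ranked y after regression on [1, Z]; the p-value uses
t = rho·√((n − 2 − k)/(1 − rho²)) with k adjustment columns, two-sided.
The t approximation is the conventional choice for rank partial
correlations and calibrates well in simulation (the suite checks null
uniformity by Kolmogorov–Smirnov).

## Other statistics

* **BH adjustment** is delegated to statsmodels and checked against the
  step-up definition to 1e-12.
* **Mann–Kendall across quartiles** is Kendall's tau-b between group index
  and value: S = Σ_{i<j} sign(g_j − g_i)·sign(v_j − v_i), variance with
  the full tie correction (including the cross-tie terms), ±1 continuity
  correction, two-sided normal p.  This is the natural reading of a trend
  test applied to grouped cross-sectional data.
* **Wilcoxon–Mann–Whitney**: exact enumeration when the combined sample is
  ≤ 20 without ties, otherwise tie-corrected normal approximation with
  continuity correction.
* **ORA**: upper-tail hypergeometric P(X ≥ k) per gene set after
  intersecting sets with the universe; Bonferroni correction by default,
  BH optional.
* **PERMANOVA**: Anderson's one-way pseudo-F from total and within-group
  sums of squared distances; p = (1 + #{F_perm ≥ F_obs})/(1 + B) with
  seeded label permutation, or exhaustive enumeration of distinct
  relabelings on small designs.
* **PCoA**: classical scaling of −½D² after double centering.  Negative
  eigenvalues (possible for non-Euclidean dissimilarities such as
  Canberra) are reported but their axes are dropped and they are excluded
  from the proportion-explained denominator; no Lingoes/Cailliez
  correction is applied.
* **Quartiles**: type-7 (linear interpolation) percentiles; boundary
  values go to the lower quartile.
* **Chao1**: bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) by default
  (defined when F₂ = 0); the classic F₁²/(2F₂) form is available to match
  textbook examples and falls back to the bias-corrected estimate when
  F₂ = 0.
* **Feature filtering** implements the printed abundance/prevalence rule
  verbatim (relative abundance > A in at least P of samples, defaults
  A = P = 0.20) with both thresholds configurable, because a 20% relative
  abundance cutoff is far more stringent than the detection-level rules
  common in practice; the pipeline benchmark uses A = 0.001, P = 0.20.
* **Bray-Curtis with an all-zero sample** returns distance 1 with a
  warning (the diagonal stays 0).
* **Ward clustering** uses the Ward.D2 criterion on Euclidean distances
  via SciPy; the leaf order is SciPy's deterministic recursive child
  ordering.

## Pipeline gating

Feature selection for a block proceeds only if the permutation p of Q²Y is
below `gate_alpha` (default 0.05); otherwise the block is reported as
"model not valid" with its statistics, not an exception.  pSC confirmation
uses raw p < 0.05, matching the display convention of correlation
heatmaps; the BH-highlighted subset is also reported.  All stage outputs
are pure functions of (inputs, config, seed); the report manifest records
the config and SHA-256 hashes of every table so a run can be verified
bit-for-bit.

## Synthetic data generator

The generator emulates post-processing feature tables of an obesity/NAFLD
cohort study:

* **Response**: log-normal, default exp(N(4.0, 0.8)) — median ≈ 55 with a
  long right tail, a realistic serum-ferritin shape in µg/L.  The source
  cohorts' actual distribution parameters are unpublished; these defaults
  are free parameters of the generator, not estimates of any study.
* **Covariates**: age N(45, 9) (middle-aged cohort), BMI N(35, 5)
  (obesity), sex Bernoulli(0.5), country two-level categorical, hs-CRP
  log-normal.  Dependence with the response is induced by a Gaussian
  copula: each covariate's latent is ρ·z_response + √(1−ρ²)·noise pushed
  through its marginal inverse CDF, which controls rank correlation for
  arbitrary marginals.
* **Counts blocks**: per-sample Dirichlet-multinomial.  The systematic
  log-composition is baseline + β·z(log response) for planted features
  plus latent-factor terms for cross-block links; the Dirichlet
  concentration (default 50; the benchmark uses 200, appropriate for
  family-level tables which are far less dispersed than species-level
  ones) controls overdispersion, and each sample's total equals its drawn
  log-normal sequencing depth.  β acts on the standardized log-response,
  so it is a unit-free log-abundance shift per SD of log-response.
* **Intensity blocks**: exp of a Gaussian with the same systematic
  structure; dispersion is the residual log-SD.
* **Seeding**: one integer master seed; every sub-draw uses a
  SeedSequence spawn key derived from CRC32 of string labels
  ("cohort", ("block", name), ("link", …)), so adding a block or link
  never perturbs earlier draws, and cross-block link factors regenerate
  identically from either end of the link.

What the generator does **not** emulate: taxonomic correlation structure
(features are exchangeable given their baselines), zero-inflation beyond
what the Dirichlet-multinomial produces, batch effects, measurement drift,
or phylogenetic relationships.  Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that the pipeline is robust to every artefact of real sequencing data.

## The benchmark (ferroflux.benchmark)

The canonical end-to-end conditions are 25 replicates of a 200-subject
cohort (confounding: age 0.3, BMI 0.3, hs-CRP 0.2) with one 200-taxon
counts block, Dirichlet concentration 200, sequencing depth ≈ 20 000.  In
the planted variant ten taxa carry effects of magnitude 1.2 — roughly a
3.3-fold abundance change per SD of log-response, a strong but plausible
family-level effect — balanced five up / five down and placed at
below-median baseline abundance.  The sign balance and modest abundance
placement keep the planted structure from dominating the composition:
closure gives every unplanted taxon a common per-sample factor equal to
one minus the planted share, and if that share trends with the response
the entire null block inherits a spurious monotone association.  A
benchmark meant to measure false discoveries among *null* taxa must keep
those taxa null after closure, which a sign-balanced, low-abundance
planting achieves to first order.  Replicate seeds derive from one master
seed by SeedSequence spawning.

Problem sizes in the calibration tests (400 null permutation replicates at
n = 40, p = 20 with 200 permutations and 7-fold Q²; 200 PERMANOVA null
replicates at n = 20 with 99 permutations; 25 benchmark replicates with
99 permutations) were chosen so the whole suite completes in a few minutes
while keeping the Monte-Carlo error of each checked proportion well inside
its acceptance band.

## Known limitations

* O-PLS supports a single continuous response; binary group comparisons
  are handled by 0/1 coding, full multi-response O-PLS2 is out of scope.
* UniFrac distances require a phylogeny and are not implemented.
* The Mnet track fits Gaussian responses only (no GLM variants).
* The coordinate-descent Mnet solution is a stationary point of a
  non-convex objective; the suite verifies global optimality only on
  small instances.
* PERMANOVA is one-way (a single grouping factor).
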