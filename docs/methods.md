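# Methods

## Model and tests

Each SNP's genotype is the B-allele count g ∈ {0, 1, 2}. A candidate
genetic model assigns scores (c₀, c₁, c₂) — recessive (0,0,1), dominant
(0,1,1), multiplicative (0,1,2) — and the association with a
right-censored trait (X_i = min(T_i, C_i), δ_i = I(T_i ≤ C_i)) is tested
through the proportional-hazards model λ_g(t) = λ₀(t) exp(β c_g) with the
Cox partial score test of β = 0. The statistic W is n^{-1/2} times the
gradient of the Breslow partial log-likelihood at zero; its variance
estimator accumulates the at-risk variance of the scores at each event
time. Both are invariant (in T = W/σ̂) to affine transformations of the
scores, so the particular score values only encode the ordering pattern.

Because the true model is unknown, the three standardized statistics are
combined into Q = max(|T₁|, |T₂|, |T₃|). Under the null the vector
(T₁, T₂, T₃) is asymptotically normal with a correlation matrix estimated
from the risk sets; the p-value of Q is approximated by B Monte-Carlo
draws from that (degenerate) trivariate normal. Two structural facts
matter here:

* the multiplicative score triple is the sum of the recessive and
  dominant triples, and W is linear in the scores, so W₃ = W₁ + W₂
  exactly and the correlation matrix always has rank 2. Sampling uses a
  jittered Cholesky factor; the quadratic-form diagnostic W² = Sᵀ Σ̂⁻ S
  uses the generalized inverse with chi-square df = rank = 2. No
  reference use of W² beyond a diagnostic is made.
* a scoring that is constant on the sample (e.g. recessive with no BB
  carriers) has an undefined statistic; it is dropped from the max and
  the correlation matrix shrinks to the remaining models. Monomorphic
  SNPs yield a degenerate result with p = 1.

The Monte-Carlo p-value uses the add-one estimator (1 + #{q⁽ᵇ⁾ ≥ q})/(B+1),
which cannot return 0 and differs from the plain proportion by at most
1/B. Per-SNP draws are seeded as `seed + snp_index`, so results do not
depend on evaluation order. Tied event times follow the Breslow
convention (simultaneous events share a risk set); the simulated data are
continuous, so ties only arise in user data.

Model identification takes the scoring with the largest |T_l|
(equivalently the smallest marginal p-value); exact ties break by the
fixed order recessive < dominant < multiplicative for cross-platform
determinism. Two-sided statistics make the tests direction-free, so no
risk-allele flipping is attempted when the B allele is protective.

### Finite-sample calibration

The marginal score tests refer an estimated-variance statistic to the
normal distribution; with d events the statistic behaves like a
t-variable with roughly d degrees of freedom, so at α = 0.01 the
realized level with ~140 events is ≈ 0.0107 per scoring and ≈ 0.0115 for
the max test (measured over 100,000 null SNP-tests; ≈ 0.0113 at 280
events). This mild anti-conservatism is a property of the published
reference distribution (continuous normal draws), not of the
implementation, which matches an independent Cox implementation's score
and information to machine precision.

## Gradient lasso

The fitter maximizes the Breslow partial log-likelihood subject to
‖β‖₁ ≤ s. Each iteration performs

1. **Addition** — pick the coordinate with the largest |∂l/∂β_j|, move
   along the segment from β to the L1-ball vertex s·sign(∂l/∂β_j)·e_j
   with an exact line search over α ∈ [0, 1];
2. **Deletion** — within the active set σ, step along the gradient
   projected to preserve Σ sign(β_k) β_k (taking θ_σ = sign(β_σ)),
   truncated at the first coefficient sign change (U = min{−β_k/h_k :
   β_k h_k < 0}), so coefficients can leave the model exactly.

Both steps keep ‖β‖₁ ≤ s and never decrease the likelihood (a candidate
step is rejected if roundoff would lower it); convergence is declared
when the relative improvement drops below 1e−6 (at most 1000 iterations).
Line searches solve the 1-D concave problem by safeguarded Newton on the
directional derivative to tolerance 1e−8. When the projected gradient on
the active set is at roundoff level (≤ 1e−10 relative to the gradient)
the deletion step is skipped: stepping along numerical noise with
U ~ 1/|h| would amplify it. With the constraint inactive the algorithm
converges to the unpenalized partial MLE (verified against lifelines).

Covariates are standardized with divisor-n mean and SD, and the
constants are stored in the fitted model and reused verbatim on new
samples — predictions never re-estimate anything on test data.

### Choosing the L1 budget

`select_budget` implements k-fold cross-validation on the
Verweij–van Houwelingen criterion l_full(β̂₋fold) − l₋fold(β̂₋fold), with
either the maximizer ("max") or the smallest budget within one standard
error of it ("1se"); fold fits are warm-started along the ascending grid.

The pipeline, however, defaults to a **fixed unit budget** (s = 1 on
standardized covariates). The reason is structural: screening admits only
SNPs that are already marginally significant on the same samples, so
every screened SNP improves any same-sample likelihood criterion — CV,
AIC and BIC curves are all near-monotone in s on the screened design and
retain essentially the whole screened set. A unit budget — one unit of
standardized log hazard ratio shared by all coefficients — makes the
coordinates compete, keeps the fitted models parsimonious, and
concentrates the budget on the truly prognostic SNPs as the sample size
or effect size grows. Cross-validated selection remains available via
`PipelineConfig(budget=None)`.

## Evaluation protocols

* **Train/test split** — fit on the training samples, compute risk
  scores on the test samples, cut at the *test-set* median (the
  simulation-study protocol), and compare groups with the two-sided
  two-sample log-rank test (hypergeometric variance, chi-square(1)
  reference; computed by lifelines). Scores exactly at the cutoff go to
  the low-risk group. Constant scores yield a single group, flagged with
  p = 1.
* **Leave-one-out** — each fold repeats screening, model identification,
  and the lasso fit on the n−1 remaining samples and assigns the held-out
  sample by the fold's *training-median* cutoff. The cutoff provenance
  deliberately differs between the two protocols. Folds with an empty
  screening selection assign risk 0 (low risk) and are counted. Per-SNP
  inclusion counts across folds are reported. The budget is re-selected
  (or re-applied) within each fold; nothing leaks across the fold
  boundary.

## Synthetic data

The generator emulates a survival GWAS with local linkage disequilibrium:
per sample, latent standard normals follow an AR(1) process across SNPs
(x₁ = ε₁, x_j = ρ x_{j−1} + √(1−ρ²) ε_j), thresholded at the normal
quantiles of the cumulative genotype frequencies. The D prognostic SNPs
occupy the first D positions (adjacent, so ρ > 0 puts them in LD) with
frequencies (.25, .5, .25); the rest use (1/3, 1/3, 1/3). True models
cycle dominant, recessive, multiplicative.

Survival times follow Λ(t) = t · exp(Σ β z'_ij) — a unit-exponential
baseline, without loss of generality for rank-based quantities since the
selection and log-rank metrics are invariant to monotone time
transforms. The hazard covariate z'_ij is the SNP's true-model score
standardized by its population moments, so β is a per-SD log hazard
ratio, comparable across genetic models; with the raw 0/1/2-scale scores
instead, β = 0.8 gives per-SNP screening power far too low to recover
most prognostic SNPs at α = 0.01, inconsistent with the operating
characteristics the generator is meant to emulate. Censoring is
Uniform(0, τ) with τ solved once per configuration by bisection on
E[min(T, τ)]/τ = target over 100,000 Monte-Carlo event times, then held
fixed across replicates.

The replicated study protocol (`simulation_study`) treats n as the
training-set size: each replicate draws 2n samples, trains on the first
n, evaluates on the last n (generation order is exchangeable). Default
conditions: m = 1000, n = 200, D = 6, β = 0.8, ρ ∈ {0, 0.3}, censoring
15% or 30%. The scaled-down reruns in `scripts/acceptance.py` use 25
replicates with B = 10,000 Monte-Carlo draws per SNP; replicate means of
model-size counts then carry a standard error of roughly 0.2–0.5 SNPs.

What the generator does **not** emulate: realistic LD block structure,
minor-allele-frequency spectra, Hardy–Weinberg deviation, population
stratification, covariate effects, or tied/discrete event times. Passing
tests therefore demonstrate correctness of the statistics and the
algorithmic machinery under the stated model, not robustness to those
features of real cohorts.

## Known limitations

* The max-test p-value inherits the mild finite-sample anti-conservatism
  quantified above (≈ 0.0115 realized at nominal 0.01 with 140 events).
* The fixed unit budget is a deliberate design choice, not a data-driven
  one; on designs where screened covariates are not pre-selected for
  significance (e.g. user-supplied candidate lists), cross-validated
  selection may be preferable.
* Missing genotypes cause the whole SNP to be excluded (matching the
  screening filter for complete data); no per-SNP complete-case analysis
  is offered because the downstream joint model requires a rectangular
  matrix.
* LOOCV refits the entire pipeline n times and is intended for cohorts of
  at most a few hundred samples at screening-scale SNP counts.
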