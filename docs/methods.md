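# Methods

## Estimands and estimators

The unit of analysis is a two-arm individually randomised trial with
baseline covariates `X`, arm `Z ∈ {0,1}` (1 = intervention) and a binary or
continuous outcome `Y`. An estimand is a (summary measure, target
population) pair. Summary measures: mean difference, risk difference, risk
ratio, marginal odds ratio, conditional odds ratio. The first three are
collapsible (marginal and conditional versions coincide in the absence of
confounding); the odds ratios are not, so the marginal odds ratio depends
on the in-trial covariate distribution while the conditional one depends on
which covariates are conditioned on. Target populations: all randomised
participants, or the complete cases. Ratio measures are estimated and
reported internally on the log scale; differences on the identity scale.

Method–estimand compatibility is enforced before fitting: direct
adjustment yields conditional summaries only; standardisation and IPTW
yield marginal summaries only. For collapsible measures the distinction is
immaterial and all three approaches target the same value.

### Direct adjustment

Maximum-likelihood GLM of `Y` on `Z` and covariate main effects (no
`Z × X` interaction), with the link matched to the measure. Model-based
covariance by default; HC0 sandwich optionally (HC1 available) — the
variant matters only in small samples and HC0 is the conventional default.
With `robust=True` the risk-ratio route switches from the log-binomial to a
Poisson model with HC standard errors, which converges more reliably
because the log link is canonical for Poisson.

Convergence policy (applies to every GLM in the package): IRLS with
relative deviance tolerance 1e-10 and at most 100 iterations. Rank-deficient
designs are rejected up front with the implicated terms named. A fit whose
coefficient exceeds 15 in absolute value on a log or logit scale is
declared separated (a probability beyond expit(±15) is numerically 0/1 and
indicates perfect prediction), naming the offending term. Identity- and
log-link binomial fits must keep fitted probabilities strictly inside
(0, 1); if the constraint binds, the fit is reported as
`invalid_fitted_values`, never silently clamped. There is deliberately no
automatic fallback between models: a pre-specified analysis plan must name
its backup, so the caller chooses.

### Standardisation

Working model: logistic (binary) or linear (continuous) with covariate
main effects; `Z × X` interactions are opt-in
(`arm_interactions=True`). The model is fitted on rows with observed
outcome and covariates; predictions are averaged over the all-randomised
set (default) or the complete cases. Counterfactual design matrices reuse
the declared categorical coding (reference level = first declared level),
so coefficients and predictions are pinned independent of row order.

Categorical levels present in the prediction set but absent from the fit
set have no estimable coefficient: the default is a typed failure naming
the level and the affected count; `drop_unpredictable=True` reproduces the
pragmatic alternative of omitting those participants, with the count
logged. Dummy columns that are identically zero in the fit set are pruned
from both fit and prediction designs.

Variance: delta method through the contrast. With
`f(μ₁, μ₀)` the measure on the estimation scale,
`∇_β μ_z = n⁻¹ Σᵢ g⁻¹'(η_i(z)) x_i(z)` and
`SE² = (∂f/∂μ)ᵀ J V_β Jᵀ (∂f/∂μ)`. The analytic contrast gradients can be
cross-checked against central finite differences (1e-6 relative) via
`check_gradient=True`. Standardised means of exactly 0 or 1 make ratio and
odds contrasts infinite; this is raised as a typed error rather than
returned as ±inf. A test-based interval (half-width `(q/|z|)·|θ̂|` using
the working-model z statistic) is available for difference-scale measures,
guaranteeing agreement between the p-value and the interval across scales.

### IPTW

The weight model is a logistic regression of `Z` on covariate main
effects; weights are `1/P̂(Z = zᵢ | xᵢ)`. Stabilised weights (numerator =
marginal arm proportion) are available but off by default — they change
weight magnitudes, not point estimates, in this setting. No truncation by
default: trial propensities sit near the allocation ratio. The outcome
step contrasts weighted arm means, equivalent to an arm-only weighted GLM
with the measure's link, and cannot fail to converge.

The default SE solves the stacked M-estimation system over
`(α, μ₁, μ₀)`: logistic score equations for the weight model(s) joined
with the weighted-mean estimating equations, using
`∂ log wᵢ/∂α = (pᵢ − rᵢ) xᵢ`. The bread/meat matrices are assembled over
all participants and the `(μ₁, μ₀)` block of `A⁻¹ B A⁻ᵀ/n` is pushed
through the contrast gradient. `se_method="naive"` exposes the
"weights known" shortcut for teaching. Results at n below a configurable
threshold (default 100) carry a small-sample caveat: the sandwich is
anti-conservative there (verified by the coverage simulations in the test
suite).

When outcome missingness weights are combined with treatment weights, the
stacked system includes both weight models' scores, so the variance
acknowledges the estimation of both.

### Inference extras

- Normal quantiles throughout (the methods are asymptotic); a t option
  exists only where it is conventional (Rubin's rules use the standard
  small-sample df).
- Design-respecting bootstrap: under a stratified-block design, resampling
  is within stratum-by-arm cells, because the stratifier's balance across
  arms is a fixed feature of the design and must hold in every replicate;
  simple resampling instead treats it as chance and inflates the SE (this
  misuse is demonstrated in a test, and warned about at run time).
  Percentile intervals by default. Replicates whose estimator fails to
  converge are counted; beyond a 1% failure fraction (configurable)
  inference is refused — a plan that cannot survive resampling is not a
  safe plan. Minimisation designs are refused by default: no i.i.d.
  resampling scheme mimics sequential dynamic allocation. The override
  accepts simple resampling as an approximation (re-running the
  minimisation per replicate would detach observed outcomes from the arms
  they were observed under, so it is not offered).

## Missing data

Complete-case analysis is valid for the complete-case population; with
effect modification on the summary scale and covariate-dependent
missingness that population's estimand genuinely differs from the
all-randomised one. Three routes to the all-randomised estimand:

1. **Three-step standardisation** — fit on complete cases, average the
   predictions over every randomised participant. With a saturated working
   model this recovers the all-randomised value exactly on the bundled
   deterministic example; with main effects only it is close but not
   identical (the complete-case score equations weight the strata
   differently from the all-randomised average), which is why the
   package's exactness checks use the interaction-including model.
2. **Multiple imputation by arm** — logistic imputation models fitted
   separately per arm (a pooled model with an arm main effect would *not*
   target the all-randomised population under treatment–covariate
   interaction). Proper imputation: approximate-posterior parameter draw,
   then Bernoulli outcome draw. Each arm model is augmented against
   perfect prediction with two pseudo-observations (outcome 0 and 1) at
   the covariate means carrying total weight `augment_scale × p` (p = the
   number of parameters; `augment_scale` default 1, logged). m = 10
   imputations by default; the seed is mandatory in spirit — all
   randomness flows through one generator. Rubin's rules combine on the
   estimation scale by default (normality is more plausible for log-odds
   than for risk differences); summary-scale combination is allowed but
   flagged. Combining MI with IPTW is possible but its Rubin variance can
   be inconsistent (uncongeniality); the CLI surfaces this as a warning.
3. **IPMW + IPTW** — missingness modelled by logistic regression on the
   analysis covariates with arm interactions (equivalently by arm);
   observed rows weighted by `1/P̂(observed | X, Z)` and multiplied with
   the treatment weights. A covariate pattern that is *fully observed*
   drives its missingness-model coefficient to +∞; that is benign (the
   weight tends to 1), so the separation check for this model is on the
   quantity that matters — no observed row may have fitted P(observed)
   near 0, which would mean an unbounded weight.

An MNAR sensitivity analysis adds a per-arm log-odds shift `δ` to the
linear predictor of imputed draws only; `δ = 0` reproduces MAR. This is
one conventional parameterisation of departure from MAR, not the only one.

Missing covariates: across-arm mean imputation (continuous) or an explicit
extra level (categorical — equivalent to the missing-indicator method for
factors), and the missing-indicator method. Both are appropriate for
marginal/collapsible estimands and flagged as unsuitable for the
conditional odds ratio.

## Synthetic trials

The generator draws independent covariates (categorical with given level
probabilities, or normal), assigns arms by simple randomisation,
stratified permuted blocks, or minimisation, generates outcomes from a
logit- or identity-link linear predictor (terms may be squared or level
indicators; arm × term effect modification supported), and applies an
arm-, covariate- or outcome-dependent missingness mechanism. True marginal
means under each arm are computed analytically — exact enumeration over
finite covariate supports, 64-node Gauss–Hermite quadrature for a normal
covariate — and all derived estimands (risk difference, log risk ratio,
marginal log odds ratio, mean difference) come from those. The generator is
bitwise reproducible given the specification and seed.

Minimisation uses the range method with equal covariate weights: the
marginal imbalance after a hypothetical assignment is
`Σ_covariates |n₁ − n₀|` within the participant's level, the minimising
arm is taken with probability 0.8 by default, ties by fair coin.

What the generator does *not* emulate: correlated covariates, more than
two arms, clustering, time-to-event outcomes, non-monotone missingness.
Passing simulation tests therefore demonstrate the estimators' properties
under clean conditions — independence, correct or deliberately misspecified
mean functions — not robustness to everything real data can do.

### Misspecification experiment

True model `Y = α + θZ + γX²` with no residual error; analysis model is
linear in `X`. Covariate values are a deterministic uniform grid (each grid
point appears in both arms, so `x ⟂ z` exactly); a stochastic variant
exists. On a zero-centred interval the sample correlation of `x` with `x²`
vanishes and the fitted linear coefficient is 0; on shifted intervals it is
positive — a misspecified adjustment still partially adjusts. Standard
errors here use the asymptotic residual variance RSS/n rather than
RSS/(n−p): with the df correction, adding a covariate whose coefficient is
exactly zero would inflate the SE infinitesimally, obscuring the point that
linear adjustment is never less efficient than no adjustment; on the
asymptotic scale equality holds exactly in the orthogonal case.

### Bundled worked examples

The two-stratum table (40 participants, within-stratum odds ratios both 9,
marginal odds ratio 49/9 ≈ 5.44) is stored as counts and expanded to
records on demand.

The notional 2000-participant trial (two arms × binary X, 500 per cell,
effect modification on every summary scale, covariate-dependent outcome
missingness removing half of the X=0 stratum) is stored as its four event
counts per 500. Those counts are cross-validated at load time against a
reconstruction oracle: the four published all-randomised and complete-case
risk-difference and risk-ratio values determine the four cell risks through
a linear system, and the bundled counts must agree within tolerance
(default 0.01, reflecting the 3-decimal rounding of the published
summaries). The complete-case view is expressed at doubled scale (X=0
cells of 500 with the original odd event counts, X=1 cells of 1000) so
that "exactly half of X=0 observed" stays integral; every summary measure
is scale-invariant. The record-level missingness dataset is built at
n = 4000 for the same reason.

## Simulation study sizes

The package's own simulation checks use: 2000 trials of n = 200 for the
designed-balance coverage study (stratified blocks on one strongly
prognostic binary covariate, null effect, continuous outcome — chosen as
the cleanest setting in which the unadjusted model-based SE is biased
upward while all three adjusted analyses are calibrated); 1500 trials at
n = 50 and 800 at n = 1000 for the IPTW sandwich coverage contrast; and
1000 replicates of n = 2000 for the missing-data estimand-recovery study,
which simulates from the notional trial's exact cell risks. Monte-Carlo
standard errors at these sizes are 0.5–0.8 percentage points on a coverage
proportion and ~4×10⁻⁴ on a risk-difference bias, comfortably inside the
margins being asserted.

## Known limitations

- Two arms only; no clustering, repeated measures, or time-to-event
  estimators.
- No influence-function/augmented hybrid estimators, overlap weighting, or
  propensity matching.
- No small-sample-corrected sandwich variance; the bootstrap is the
  recommended fallback at small n.
- MI is outcome-only and by-arm logistic; no chained equations for general
  non-monotone patterns.
- Standardisation to external target populations is out of scope.
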