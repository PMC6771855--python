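# Methods

This note documents the statistical models, the synthetic-data
generator, numerical choices, and the places where the design was
genuinely open. Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic stepped-wedge trial

**Design.** `n_clusters` maternity units (default 11, enrolment weights
proportional to annual delivery volumes of 3000–9000) over `n_steps`
6-week periods (default 12). A seeded uniform permutation fixes the
crossover order; the unit in position *j* adopts revealed PlGF testing
at step *j + 1*, so step 0 is all usual care, the final step all
intervention, and the intervention indicator is monotone per cluster.
`n_steps ≥ n_clusters + 1` is enforced. Women are assigned to
(cluster, period) cells compatible with their arm, with cell
probability proportional to the cluster's enrolment weight; per-arm
totals default to the trial's 434 usual / 571 revealed.

**Subgroups.** Each woman gets one of nine PlGF-band × final-diagnosis
cells. The PlGF marginals (23.5% <12, 38.3% 12–100, 38.2% >100) are the
trial's; the diagnosis mix *within* band is not published, so the
default conditional probabilities are a synthetic choice (very-low PlGF
dominated by pre-eclampsia, normal PlGF by uncomplicated outcomes) and
are flagged as such in the configuration file.

**Resource use.** Every category follows a hurdle model. On the link
scales, both parts share the woman's centre intercept
`u_c ~ N(0, σ_c²)` and a linear secular trend `β_t · step`:

- use probability: `logit⁻¹(logit(p) + u_c + β_t·step)`;
- positive part: zero-truncated negative binomial whose *untruncated*
  location is `exp(log m + u_c + β_t·step)`, where `m` solves
  `m / (1 − (k/(k+m))^k) = μ⁺` so that the configured `μ⁺` is the mean
  of the truncated distribution (hence the hurdle identity
  `E[Y] = p·μ⁺` at `u_c = β_t = 0`, which the tests verify against a
  large-sample simulation and a direct pmf summation). `μ⁺ > 1` is
  required — the truncated support starts at 1. Draws use the inverse
  CDF restricted to `{1, 2, …}`, so they are exact, vectorised and
  reproducible. Poisson behaviour is the large-`k` limit.

Defaults: `σ_c = 0.3`, `β_t = 0.02` per step — moderate centre
heterogeneity and a mild secular trend, chosen once as plausible for
NHS maternity units; neither is published. The per-category levels
(`p`, `μ⁺`, `k`) and the arm modifiers (odds ratios on `p`, ratios on
`μ⁺`) are synthetic calibrations: revealed testing mainly reduces
outpatient attendance for normal-PlGF women and mildly increases
antenatal admission for low/very-low PlGF, mirroring the qualitative
pattern the trial reported.

Severe maternal adverse events are Bernoulli per woman at the arm's
configured rate (defaults 24/447 and 22/573). Delivery mode is drawn
from a four-mode multinomial shared across arms.

**What the generator does not emulate.** Gestational-age dynamics,
repeat presentations, care-pathway decisions, correlation between
resource categories within a woman beyond the shared centre effect, and
any real unit-cost schedule. Passing tests therefore demonstrate that
the *estimation and costing machinery* is correct under the assumed
data-generating process, not that the synthetic magnitudes equal the
published ones.

**Realisation variability.** Because neonatal stays are heavy-tailed
(`k ≈ 1.2`, means of 8–9 days) and the centre intercept is shared by
both hurdle parts, single-trial realisations of n ≈ 1005 show weighted
per-woman cost differences that swing by hundreds to thousands of GBP
across seeds. This is a property of the assumed study conditions; the
Monte Carlo probabilities quantify parameter uncertainty conditional on
one realised trial.

## Resource-use models

**Covariates.** All candidate families share one fixed-effect set:
intercept, 8 subgroup dummies (reference: PlGF>100 × normal), arm, the
arm × subgroup interaction (so every cell × arm has its own mean, as
required to reproduce per-cell arm differences), and the step index
centred at its sample mean. A centre random intercept completes the
stepped-wedge adjustment. Columns that are identically zero in the
estimation subset (empty cells) are pinned to zero with zero variance.

**Families and selection.** Candidates per category: two-part truncated
negative binomial, two-part truncated Poisson, one-part negative
binomial, one-part Poisson. The two-part log-likelihood is the sum of
its logistic and truncated-count parts, so AICs are comparable across
one- and two-part families on the same data. The converged candidate
with minimal AIC wins; exact ties go to fewer parameters. If no
candidate converges the category falls back to a plain logistic
admission model plus a linear length-of-stay model on the admitted
subset (combined mean `p̂ · days`), with subgroup × arm cells containing
no admissions emitted as fixed zeros.

**Estimation.** The marginal likelihood integrates the centre intercept
by adaptive Gauss–Hermite quadrature (7 nodes by default): per cluster,
the posterior mode and curvature are found by a damped Newton step on
the random effect, nodes are placed at
`û_c + sqrt(2/h_c)·z_j`, and the fixed parameters are maximised by
L-BFGS with an analytic gradient for that node set; the nodes are then
re-adapted and the cycle repeats until the marginal log-likelihood is
stable (relative change < 1e-8, at most 25 outer cycles). Dispersion
and the random-effect SD are estimated on the log scale, which keeps
the problem unconstrained. With a single cluster the random effect is
dropped (σ fixed ≈ 0), and the fit provably reduces to the unmixed
maximum-likelihood fit (tested against statsmodels and an independently
written likelihood). Quasi-separation (a cell with all-zero or all-use
outcomes) drives the corresponding logit coefficient to a large finite
value where the gradient vanishes; the cell's predicted probability
degenerates to ~0/1 with negligible delta-method SE, which is the
intended structural-zero behaviour. Standard errors come from the
inverse observed information (central differences of the analytic
gradient).

**Adjusted means.** Predictions are *conditional*: centred time at 0
and random effect at 0 (the marginal/standardised alternative is a
recognised option; conditional is the default because the prediction
time point is a free choice). Two-part mean:
`expit(x'β₁) · tm(exp(x'β₂), k)` with `tm` the truncated mean. SEs by
the delta method with numerically differentiated gradients against each
part's parameter covariance (parts treated as independent); the test
suite cross-checks the fallback path's delta SE against a 500-replicate
parametric bootstrap (within 15%). Every category always emits all
9 × 2 cells; absent cells are fixed zeros with a logged warning.

**Delivery cost.** Per-woman cost is the unit cost of the delivery
mode; a gamma GLMM with log link (arm + time + centre intercept) gives
per-arm means with Wald 95% CIs. It is reported alongside the cost
tables but never added to the Monte Carlo totals, because bed-day
reference costs already include delivery (double-counting rule). A
degenerate all-one-mode input returns the exact cost with a zero-width
CI rather than a boundary gamma fit.

## Probabilistic model

Each iteration draws every (category, cell, arm) quantity from a normal
distribution truncated at zero with the adjusted mean and SE (`fixed`
cells pass through; the tag mechanism admits other distributions per
cell). Costs are quantity × weighted unit cost; differences are
PlGF − usual, so *negative means saving* and "percentage cost-saving"
counts iterations strictly below zero (ties are not savings).

**Weighting.** Default subgroup weights are the pooled both-arm cell
proportions. The trial's description of weighting ("in each subgroup in
each arm") is ambiguous between pooled and arm-specific weights, so a
`per-arm` mode (each arm's costs weighted by its own proportions before
differencing) is provided behind a flag; neither is asserted to be the
original choice. In the published-table shape, the per-cell "Weighted"
row is weight × actual cell difference and the row total is the mean
per-woman weighted difference.

**Adverse events.** Rates per arm are Beta(r, n−r) — chosen because its
mean r/n preserves the observed proportions, which reproduces the
printed ~15 events avoided per 1000 (the (r+1, n−r+1) rule would round
to 16). If an arm has zero events that rule is undefined and the draw
switches to Beta(r+½, n−r+½) with a logged note. Events avoided per
1000 = 1000·(p_usual − p_PlGF).

**CEAC and sweep.** Net monetary benefit per 1000 women at
willingness-to-pay λ is `λ·ΔE − 1000·ΔC`, with ΔC the weighted combined
difference *including* the test cost; the CEAC is the fraction of
iterations with positive NMB over a £0–£50,000 grid (step £1,000). The
test-price sweep recomputes the three cost-saving probabilities with
each candidate price added; the probabilities are non-increasing in
price by construction. The run is deterministic given the seed, and
per-iteration accounting identities (combined = maternal + infant;
weighted = weight-sum of cells) hold to 1e-9 GBP.

**Scale.** 5000 iterations by default (Monte-Carlo SE on a probability
near 0.5 is ≈ 0.007); the test suite uses 400–5000 iterations and
trial sizes of ~320–5000 women so the default run completes in under a
minute on one CPU.

## National extrapolation

`eligible = round(births × p_suspected × p_preterm)`;
`saving = eligible × per-woman saving (test included)`. With the
published inputs (646,794 births, 10%, 30%, £149) this gives 19,404
women and £2,891,196 — note the eligible count is rounded *before*
multiplying. The source discussion also quotes "approximately 38,800
women per year", which is arithmetically inconsistent with its own
product; the implementation follows the chain that reproduces the
printed annual saving and records the discrepancy here without
asserting which figure was intended.

## Numerical choices

- Link-scale linear predictors are clipped at ±30 before
  exponentiation; truncated-NB terms use `expm1`/`log1p` forms that are
  stable as the location → 0 (where 1 − P(Y=0) underflows naively).
- Non-finite objective evaluations inside optimisation return a large
  penalty with a zero gradient, which backtracks the line search.
- An inner optimiser restart exactly at the optimum may abort its line
  search; a vanishing final gradient (∞-norm < 1e-2) still counts as
  convergence.
- The observed-information matrix is pseudo-inverted, so pinned or
  weakly identified directions yield large-but-finite variances instead
  of failures.
- Truncated-normal PSA draws use the exact `truncnorm` inverse-CDF
  sampler, not clipping, so degenerate `se = 0` cells are reproduced
  bit-exactly.

## Known limitations

- No QALYs (none were collectable in the source trial), no
  post-discharge costs, no discounting (within-pregnancy horizon), and
  an NHS-perspective costing only.
- The fallback admission/length-of-stay models omit the centre random
  effect, as in the original analysis.
- Delta-method SEs ignore the (small) covariance between the two hurdle
  parts induced by shared clusters.
- Wald intervals for cluster-level contrasts can undercover slightly
  with only 11 clusters; the parameter-recovery test quantifies this
  (≥ 90% empirical coverage required at nominal 95%).
- The synthetic unit-cost table and resource-use calibrations are
  placeholders with realistic magnitudes; absolute cost outputs under
  the default configuration are illustrative.
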