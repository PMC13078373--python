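# Methods

## Scaling of strain-guide records

A strain guide supplies, per week *w* of rearing, the end-of-week body weight
BW_w (g) and the ME intake for the week ME_w (kcal/bird).  Both are scaled to
per-gram-of-body-weight, per-day units before modelling:

    y_w = (BW_w − BW_{w−1}) / (BW̄_w · d_w)
    x_w =  ME_w              / (BW̄_w · d_w)

with d_w the number of rearing days in the interval (7 by default,
configurable per record for non-weekly guides).  When a guide omits the hatch
weight, 38 g is assumed — a standard day-old layer-chick weight.

Two conventions for the average body weight BW̄_w are implemented because the
verbal rule "mean of the weight at hatch and the end of each week" conflicts
with the per-interval gain numerator:

* `interval_mean` (default): BW̄_w = (BW_{w−1} + BW_w)/2, the biologically
  standard per-interval scaling (week 1 starts at hatch);
* `hatch_anchored`: BW̄_w = (hatch + BW_w)/2 for every week, the rule as
  verbally stated.

The two coincide at week 1 and diverge increasingly with age; neither is
asserted to be the computation behind any published table.  x is carried
internally in kcal/g BW/day; report layers multiply by 1000 for kcal/kg.

Note one homogeneity property used in the tests: rescaling every body weight
(and hatch weight) by a common factor k rescales x by 1/k but leaves y
unchanged, because the gain numerator carries the same body-weight unit as
the denominator.

## Monomolecular model and fitting

The response curve y = a − (a+b)e^(−cx) is strictly increasing and concave
for positive parameters, with y(0) = −b (fasting loss), y(∞) = a, and a
unique zero crossing.  Estimation is nonlinear least squares:

* **Positivity** is enforced by optimizing over (log a, log b, log c) with
  Levenberg–Marquardt (scipy `least_squares`, analytic Jacobian via the chain
  rule).  Convergence: relative RSS change < 1e-12 or step norm < 1e-10,
  at most 500 iterations; non-convergence raises an error carrying the last
  iterate.
* **Initialization** (when not supplied): a₀ = 1.05·max(y),
  b₀ = max(1e-4, −min(y)), and c₀ from the log-linear regression
  ln(a₀ − y) = ln(a₀ + b) − c·x — the standard self-starting heuristic for
  monomolecular curves.
* **Uncertainty**: covariance s²(JᵀJ)⁻¹ with s² = RSS/(n−3), J the Jacobian
  in the natural parameters at the optimum (equivalently, the delta-method
  transport of the log-scale covariance).  SEs are its diagonal square roots.
* **Degenerate inputs**: fewer than 4 observations or fewer than 3 distinct
  intakes raise an under-determined error; constant gain (or any input whose
  Jacobian is numerically singular, condition number > 1e12) raises a
  singular-Jacobian error.

## Bioenergetic traits

All traits are closed forms in (a, b, c); the tests verify them against
independent numeric oracles (bisection root-finding, central finite
differences, direct curve evaluation).

* Maintenance intake x₀ = ln((a+b)/a)/c; MEm = 1000·x₀ kcal/kg BW/day.
  x₀ depends only on b/a and c, so it is invariant to a common rescale of
  (a, b).  b = 0 gives MEm = 0.
* Instantaneous efficiency (slope) dY/dx = c(a+b)e^(−cx); at x₀ this reduces
  to c·a.
* Average (chord) efficiency between multiples m_lo < m_hi of maintenance:
  (Y(m_hi x₀) − Y(m_lo x₀)) / ((m_hi − m_lo)·x₀).
* k_g(m): the default `chord` mode reports the average efficiency on
  [m, m+1]× maintenance ("between m and m+1 times maintenance"); a `point`
  mode reports the instantaneous slope at m× maintenance.  Both are exported
  because both conventions appear in the energy-partitioning literature.
  Concavity guarantees k_g(1) > k_g(2) > k_g(3) > k_g(4).
* NEg = f / k_g(1–4) with the ME→NE conversion factor f = 0.62 by default
  (balanced layer diets); NEg is linear in f.
* Optional delta-method SEs for MEm and NEg propagate the fit covariance
  through a central-difference gradient.

## Goodness-of-fit criteria

For actual A and forecast F with n points and p free parameters:
R² = 1 − RSS/TSS; R²adj = 1 − [(n−1)/(n−p)](1 − R²); RMSE = √(RSS/(n−p));
MAD = Σ|A−F|/n; MAPE = (1/n)Σ|(A−F)/A|·100.

Two deliberate conventions:

* AIC = n·ln(RSS) + 2p and BIC = n·ln(RSS/n) + p·ln(n).  The pair is
  asymmetric (the AIC omits /n inside the log); both are kept in these forms
  because at fixed n the ranking they induce is unaffected by the n·ln(n)
  offset.  The conventional n·ln(RSS/n) + 2p is exported as `aic_standard`.
* MAD uses absolute deviations, as its name requires; the signed mean error
  is exported separately as `mean_bias`.

A zero actual value makes MAPE undefined; it is returned as NaN with an
explicit `mape_defined=False` flag rather than dropping points silently.
Perfect fits give RSS = 0, for which ln(RSS) is taken as −∞ so that the
information criteria still order a perfect fit ahead of any imperfect one.

## The 1-3-2-1 network benchmark

A fully connected feed-forward net — 1 input (x), hidden layers of 3 and 2
units, 1 output (y) — with tanh activation in every layer including the
output; 17 free parameters with biases.

* **Scaling.** Inputs are z-scored.  Because the output unit is a tanh, the
  output is mapped affinely onto [−0.8, 0.8] (midrange-centred) rather than
  z-scored: z-scored targets routinely exceed |1| and are then unreachable by
  the output unit, capping the attainable fit (observed plateau R² ≈ 0.93 on
  noiseless data regardless of optimizer).  With the range map the same data
  reach R² ≈ 0.9999.  Predictions invert the output map; with all weights
  zero the prediction is therefore the target midrange.
* **Split.** round(n·0.33) observations form the validation set after a
  seeded shuffle (n = 18 → 6 validation, 12 training).
* **Training.** Full-batch gradient descent with momentum 0.9, initial
  learning rate 0.05 on the scaled data, Xavier-uniform initialization, at
  most 20 000 epochs.  A step that would increase the training loss is
  rejected: weights roll back, the learning rate halves and the momentum
  resets, so the loss over accepted steps is non-increasing; accepted steps
  regrow the rate by 2 % (capped at 10× the initial value) so the safeguard
  cannot permanently strangle the step size.  Early stopping watches the
  validation loss with patience 200 and the best-validation weights are
  restored.  Everything is a pure function of `random_state`.
* **Gradients.** Backpropagation; verified against central finite
  differences to 1e-6 in the tests.
* **Criteria.** Per-split criteria count p = min(17, n_split − 1) so the
  suite (which requires n > p) stays defined on the small splits the 67/33
  design produces; the raw parameter count is exposed as `n_parameters_`.
* **Degenerate targets** (constant y) skip training and return the mean
  predictor, flagged via `degenerate_`.

## Random-effects meta-analysis

Each strain's fitted parameter is one study (θ_i, se_i).  Fixed weights
w_i = 1/se_i² give the fixed-effect mean and Cochran's
Q = Σw_i(θ_i − θ̄)² (chi-square, K−1 df, under homogeneity).
I² = max(0, (Q − (K−1))/Q)·100; the DerSimonian–Laird moment estimator is
τ² = max(0, (Q − (K−1)) / (Σw − Σw²/Σw)).  Random weights
w*_i = 1/(se_i² + τ²) give the pooled mean, SE = (Σw*)^(−1/2), 95 % CI
pooled ∓ 1.96·SE and a two-sided z-test against zero.  No Knapp–Hartung
adjustment is applied — the plain normal interval is what published pooled
layer-strain parameters use.  I² anchor points 25/50/75 % are attached as
labels by nearest band (< 37.5 low, < 62.5 moderate, else high).  K = 1 is
handled by an explicit passthrough (the study is the result, τ² = 0).

The packaged six-strain parameter table reproduces the published pooled
rate-constant row essentially exactly (pooled 3.276, SE 0.380, CI
2.531–4.021, I² 76.3 %); Q computed from the table's rounded SEs is 21.129
against a printed 21.137 — printed-precision rounding of the inputs, not a
method difference.  The asymptote and intercept rows reproduce to within
~1 % and ~3 % for the same reason, which is why the tests pin the
rate-constant row tightly and the others at wider tolerance.

## Synthetic data

`SyntheticSpec` defaults define the test conditions: true parameters
(a, b, c) = (0.10, 0.15, 3.5), 18 weeks, intake grid on 0.05–0.45 kcal/g
BW/day, additive Gaussian gain noise σ = 0.002, hatch weight 38 g.  The
intake range brackets the implied maintenance intake (0.262) from well below
to well above; the noise scale matches the absolute residual magnitudes seen
in real guide fits.  `generate_profile` inverts the scaling step — weekly
body weights follow BW_w = BW_{w−1}(1 + 3.5y_w)/(1 − 3.5y_w) and weekly ME
intakes are back-solved as x_w·BW̄_w·7 — so scaling the profile reproduces
the generated (x, y) pairs to 1e-10.

What the generator does *not* emulate: intakes below maintenance early in
the grid make the synthetic trajectory lose weight in early weeks, unlike a
real pullet whose intake always exceeds maintenance; there is no mortality,
feed-composition or temperature structure; noise is homoscedastic.  Passing
tests therefore demonstrate correctness of the estimators under the stated
noise model, not field-data robustness.

Meta-analysis study sets draw θ_i ~ N(μ, τ² + se_i²), i.e. true effects
N(μ, τ²) observed with known sampling error.  Simulation tests use K = 6,
μ = 3, τ² = 0.6 and the six published rate-constant SEs — the configuration
the package's own pooled analysis faces.

## Problem sizes in the test suite

Noisy parameter-recovery uses 200 replicates of n = 18 (median absolute
relative bias < 5 % per parameter); pooling recovery uses 1 000 replicates of
K = 6 (mean pooled estimate within 2 % of μ); the oracle cross-checks use 100
random inputs with K ≤ 8.  The full suite runs in well under a minute.

## Known limitations

* Published per-strain trait tables derived from these curves could not be
  reconciled with their own printed parameters under any definition
  implemented here (closed-form MEm 102.4 vs a printed 135.6 for the same
  parameter triple); the package exposes the closed forms and treats such
  table values as non-reproducible.
* The network optimizer is a robustified first-order method chosen for
  determinism and monotonicity, not speed; second-order methods would
  converge in far fewer epochs on 17 parameters.
* MAPE is unstable when gains pass through zero near maintenance intake —
  exactly where pullet data live — so RMSE/MAD are the more trustworthy
  criteria in that region.
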