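# Methods

## Model setting

A focal ("invading") species of abundance n lives in a community of fixed
size N. While rare (n ≪ N) its individuals do not interact with each
other, so the per-dwell-time displacement moments are linear/quadratic in
n: E[Δn] = ℰn and Var[Δn] = V_d n + V_e n². The environment is piecewise
constant: it holds one value for a dwell time τ and is then redrawn
independently, making τ twice the environmental autocorrelation time.
Invasibility is the probability Π(n → n_f) of reaching a target abundance
n_f before absorption at 0, i.e. the absorption probability of the
backward Kolmogorov problem for the one-dwell-time transition kernel.

Two closed forms approximate that problem (see README for the formulae):

* the **diffusion approximation**, a second-order continuum expansion in
  n, valid when jumps are small relative to n and the mean displacement
  is small relative to its standard deviation (n ℰ² ≪ V_d + n V_e);
* the **WKB (large-deviations) form**, which assumes only that ln Π is
  smooth. The jump process in z = ln n is replaced by a two-destination
  process (±β with forward probability α) that preserves the first two
  jump moments; the outer-regime exponent q̄ solves
  1 = 2α·sinh(qβ) + e^{−qβ}, giving q̄ = ln((1−α)/α)/β, while the inner
  (demographically dominated) regime is the z-space diffusion limit with
  exponent q_in(n) = −2E0·n/V_d. The two are bridged by the interpolation
  q_inter(n) = −2E0·n/(V_d − 2E0·n/q̄), whose integral gives
  Π_II ∝ 1 − (1+nR)^q̄ with R = −2E0/(q̄ V_d). The scale 1/R separates
  the demographic from the environmental regime; invasion is effectively
  binary (well summarised by the sign of the mean growth) only when
  1/R ≪ n ≪ n_f.

Derived quantities: the extinction threshold n_th = V_d/V_e (the
abundance at which demographic and environmental variance are equal; the
correct absorbing boundary when using infinite-population models), the
natural establishment target n_f ~ e^{1/|q̄|}/R (defined for positive
mean growth), and the quenched limit — when the environment outlives the
invasion attempt, Π is the state-weighted average of fixed-environment
(Haldane/Kimura) probabilities.

## Numerical evaluation of the formulae

Both formulae are ratios 1 − (1+x)^k over 1 − (1+y)^k and are evaluated
as expm1(k·log1p(x))/expm1(k·log1p(y)), which is uniformly stable as
k → 0 (no catastrophic cancellation near the neutral point) and is
guarded in log space against overflow for strongly deleterious invaders.
Explicit analytic branches handle ℰ = 0 (exactly n/n_f), E0 = 0 (the
logarithmic q̄ → 0 limit), Q = 0, and V_d = 0 (continuum limit without
absorption, defined for n ≥ 1 only; n < 1 is rejected since without
demographic noise there is no extinction state to escape).

The fixed-environment branch engages when V_e/E0² < 10⁻⁵. This threshold
is deliberately far above floating-point scale: the WKB expression
approaches the Kimura form only logarithmically (its exponent scale is
q̄ ~ ln(E0²/V_e)/β), so switching much later would leave a relative gap
of order 10⁻⁴ against the fixed-environment result that both limits are
meant to share. α and q̄ are computed through the identity
(1−α)/α = V_e/(β+E0)² (or its mirror for E0 < 0) to avoid cancellation
when V_e ≪ E0², and a q̄ underflow at subnormal E0 falls back to the
analytic q̄ → 0 limit. Results are clipped to [0,1] only within 10⁻¹²
(rounding dust); larger violations raise, since they indicate misuse
rather than rounding.

**Do not mix parameter spaces.** For the same process the n-space and
z-space means differ by an Itô-type correction, ℰ ≈ E0 + (V_e + E0²)/2.
Substituting E0 for ℰ (or vice versa) changes the asymptotic exponent of
the formulae at order one whenever V_e ≳ |E0|; the two formulae agree in
the weak-noise regime only under the consistent mapping. This is why the
two parameter sets carry distinct field names and no automatic conversion
is offered.

## Parameter inference

Input is an abundance series sampled exactly at τ (a resampling helper
thins finer series). Each adjacent pair gives one transition (n, Δn);
origins at n = 0 are dropped. Transitions are binned logarithmically in
the origin abundance (default 12 bins/decade, ≥ 50 transitions per bin —
abundance visits spread geometrically over n, so log bins equalise
occupancy). All fits are weighted least squares with bin occupancies as
weights (statsmodels WLS); reported diagnostics include per-fit weighted
RMS residuals and parameter standard errors.

* n-space: ℰ from the zero-intercept regression of the per-bin E[Δn] on
  n; (V_d, V_e) from intercept and slope of Var[Δn]/n on n.
* z-space: transitions into n = 0 are removed (ln 0 diverges) and
  counted. (V_e, V_d) from intercept and slope of Var[Δz] on 1/n; E0
  from the intercept of E[Δz] on 1/n (whose slope −V_d/2 reflects the
  demographic depression of the log-mean).

Two cutoffs protect the z-space fits. The **mean fit** excludes bins
below n_min because the zero-destination filter biases E[Δz] upward at
very small n; by default n_min is five times the crossover abundance
V_d/(2|E0|) (estimated once from a fit over all bins, then applied once),
capped so at least three bins remain. The **variance fit** excludes bins
below n = 10 (configurable): there the one-step relative change is O(1),
Δz is strongly discrete and the zero filter suppresses its variance, so
the linear law Var[Δz] = V_e + V_d/n simply does not hold; fitting
through those bins was measured to bias V_d low by more than a factor of
two. The variance-fit V_d is reported as primary; the mean-fit value is
kept as a diagnostic and the two typically agree within ~20% on 10⁶
transitions. Negative fitted variance components are truncated to zero
with a flag.

The dwell time is estimated as twice the integrated autocorrelation time
of an environmental signal (or, when the environment is unobserved, of
large-n log-abundance increments): τ = 2·(½ + Σ_k ρ_k)·dt, summing the
autocorrelation function from lag 1 until its first non-positive value.
An uncorrelated signal therefore reports τ = dt, signalling that the
sampling cannot resolve a shorter dwell time. E[r] = E0/τ converts the
per-dwell mean to the conventional invasion growth rate.

## Simulators

All simulators are driven by a `numpy.random.Generator` and are
bit-for-bit reproducible given a seed; community/adult-site totals are
conserved by construction.

* **Discrete-time lottery.** Per step of duration τ each individual dies
  with probability min(τ,1) (independent thinning per species — the same
  law as a Binomial(N, τ) total split hypergeometrically); every vacancy
  is refilled by an invader with probability p = n·e^s/(n·e^s + N−n),
  where s = s0 + σ·η and η is the (by default dichotomous ±1)
  environment state, redrawn each step. τ > 1 is rejected (a death
  fraction cannot exceed 1); use the Moran variant instead. Exact
  conditional moments of one step are exposed
  (`lottery_step_moments`): E[Δn|s] = τ′(Np − n) and
  Var[Δn|s] = Nτ′p(1−τ′p) + nτ′(1−τ′) − 2pnτ′(1−τ′), the covariance term
  arising because recruits and invader deaths share the vacancy count;
  the environment average adds the variance of the conditional mean.
  These closed forms anchor both the simulator tests and the
  parameter-recovery truth values.
* **Moran lottery.** One uniformly chosen individual is replaced per
  elementary event (time 1/N generations); the environment is redrawn
  every ⌈τN⌉ events. The implementation draws geometric waiting times to
  the next abundance-*changing* event (probabilities p(1−n/N) up,
  (n/N)(1−p) down per event), which is exact in distribution and removes
  the O(N) cost of resident-replaces-resident events; it is vectorised
  across replicates/chains.
* **Leslie–Gower trees and saplings.** Per year: saplings survive with
  probability f and each species recruits Poisson(adults × rate_year)
  new ones (start-of-year adults); adults survive with probability d;
  vacant sites are filled by drawing saplings without replacement
  (hypergeometric two-species lottery). In the rare case the pools
  cannot fill all vacancies, the leftover sites are filled in proportion
  to surviving adults so the site total stays conserved. Yearly
  recruitment-rate series are user-supplied or produced by a synthetic
  lognormal generator (specified arithmetic means, log-variance and
  cross-correlation) standing in for empirical tropical-forest
  estimates.

The update rules are canonical reconstructions of the named models and
are isolated behind one interface, so alternative variants can be swapped
in without touching inference or the formulae.

**Monte-Carlo invasion estimates** run independent replicates from n0 to
absorption at 0 or first passage at n_f, with a Wilson 95% interval
(well-behaved near probabilities of 0 or 1). Replicates exceeding the
elementary-event cap (default 10³·N·n_f) are reported as censored and
counted as failures, never dropped.

**Calibration transition sampling.** Inference needs transitions across
the whole abundance range, but a free invader is quickly absorbed. The
samplers therefore run many chains homed at log-spaced abundances inside
a band [1, n_band]; a chain leaving the band is re-seeded at its home.
Each recorded (n, Δn) pair is a genuine one-step kernel draw at its
origin — re-seeding teleports are never recorded — so banding shapes only
the visit distribution, not the conditional moments. The default band top
is N/50 clipped to [2n_f, 10n_f]: high enough to identify V_e beyond the
demographic/environmental crossover, low enough that density dependence
(O(n/N) corrections to ℰ and V_e) stays negligible. When precise
inference matters, prefer enlarging N over enlarging the band top; at
n_band/N ≈ 0.02 the induced bias on ℰ was measured at ~2%.

## Validation experiments and problem sizes

`run_comparison` executes, per grid point: calibration sampling →
n-space and z-space inference → Π_DA and Π_WKB evaluation → Monte-Carlo
measurement, with one child seed per grid point (fully deterministic,
failures recorded per row without stopping the grid). Named presets:
"desk" (N = 10⁴, 2×10⁴ replicates, 10⁶ calibration transitions) for
interactive runs and the test suite, and "paper" (N = 10⁵, 10⁵
replicates, 10⁷ transitions) approaching the original studies' scales.

The test suite asserts, among others:

* exact-oracle agreement: first-passage Monte Carlo vs the linear-system
  solution of the backward Kolmogorov equation on a two-environment
  lottery kernel (N = 200, n_f = 50), built by exact convolution of the
  death and recruitment distributions;
* neutral collapse: the Moran lottery's measured Π(10→100) equals the
  gambler's-ruin 0.1;
* parameter recovery: estimates from 10⁶ lottery transitions
  (τ = 0.2, s0 = 0, σ = 0.25) match the same fits applied to the exact
  one-step moments within 10% (n-space) and 15% (z-space variances);
* data collapse: over a 3×3 (τ, σ) grid at s0 = 0 (N = 10⁴, n_f = 50),
  Π_WKB tracks the measured Π within 0.05 absolutely on ≥ 90% of points,
  while the measured Π is demonstrably non-monotone in E[r];
* regime behaviour (N = 10⁶, n_f = 200): at weak noise both formulae
  agree with the measurement within 3 standard errors of the difference
  — the Monte-Carlo SE combined with a delta-method SE propagated from
  the inference WLS (both compared quantities are estimators), with a
  Sidak family-wise correction across the 8-point grid; at strong noise
  the WKB error is no larger than the diffusion error on ≥ 80% of
  points.

## What the synthetic data does and does not show

The simulators generate exactly the kind of stationary,
density-independent-at-low-n, piecewise-constant-environment data the
formulae assume, with unlimited length and no observation error. Passing
tests therefore demonstrate the correctness of the formulae, the
estimators and their coupling — not robustness to the failure modes of
field data: observation/sampling error (which inflates V_e and is *not*
corrected here), short series, temporally correlated or non-stationary
environments, density dependence at moderate n, or multi-species
feedbacks beyond the effective single-invader reduction.

## Known limitations

* The formulae require the invasion time to exceed τ; for very slow
  environments use the quenched average instead (provided).
* n_f/N must be small, or density dependence invalidates the constant
  parameters.
* The z-space (WKB) parameterisation degrades when data exist only at
  very small abundances (demographic jumps depress and the zero filter
  inflates E[Δz] there); the n-space diffusion formula is then the more
  reliable choice, mirroring the estimators' bias structure.
* The two-destination reduction uses symmetric jump distances;
  alternative unequal-distance reductions are not implemented.
* Mean times to extinction/invasion, multi-species formulae and the
  partitioning of Π into coexistence mechanisms are out of scope.
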