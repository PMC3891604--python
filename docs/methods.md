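# Methods

This note records the models implemented in `lagfit`, the numerical choices
behind them, and what the synthetic benchmarks do and do not demonstrate.

## Growth-curve metrics

A well's OD600 series (15-min sampling by default) is smoothed with a cubic
smoothing spline fitted to OD versus time; the specific growth rate is the
analytic derivative of the interpolant divided by the smoothed OD,
μ = od′(t)/od(t) = d ln od/dt. Smoothing is applied **before** the log
transform; at the noise levels of plate-reader data the two orders are
near-equivalent, and the chosen order keeps the spline's error model
(additive OD noise) aligned with the instrument's.

The smoothing parameter follows the classic `spar` convention: with
abscissae scaled to [0, 1], the roughness weight is
λ = r·256^(3·spar−1), where r balances the traces of the B-spline
data-fit and roughness Gram matrices. `spar = 0.35` is the default. This
mapping is a convention, not a canonical constant: other smoothing-spline
implementations parameterise λ differently, so numeric equality of
smoothed values across packages at the same nominal parameter is not
expected and not asserted anywhere. What is asserted: at the default, a
noiseless exponential's rate is recovered to 1e-2 across the analysis band
(boundary bias of the natural-spline end conditions is excluded; it is the
standard O(λ) edge effect of penalised splines and stays outside the
0.15–0.75 OD band in all shipped configurations).

- **MaxR** is an OLS slope of ln OD on time over raw samples with
  OD ∈ [0.15, 0.30]; at least 3 points are required.
- **GMR** uses interpolated crossing times of OD 0.15 and 0.75. Crossings
  are located with monotone piecewise-cubic (PCHIP) interpolation on a
  bracketing window of ±3 samples, root-solved by Brent's method. When a
  bound is crossed upward more than once (plateau/settling noise), the
  first upward crossing is used with a warning. The identity
  GMR = ln(hi/lo)/Δt makes GMR equal the true rate exactly on exponential
  curves, for any bounds.
- **Lag trough**: the minimum of μ over the OD band. "No lag" is flagged
  when the minimum sits at the band's upper edge *or* is within 5% of the
  rate at the upper edge (a flat profile, e.g. pure exponential growth,
  has no meaningful trough even though numerical wiggle puts its argmin
  somewhere). In both cases the reported OD-at-minimum is the upper bound,
  matching the convention that a minimum "at 0.75" means no lag phase.
- **Windowed mean rates** around the trough are time-averages of μ between
  the interpolated endpoint times of the OD window
  [od_min·2^(−before), od_min·2^(after)] clipped to the band — i.e. the GMR
  restricted to the window, ln(od_r/od_l)/(t_r − t_l). The degenerate
  zero-width window returns the minimal rate. This definition makes the
  constant-rate case exact and gives the window mean a closed quadrature
  form against the synthetic generator.
- **Fitness variability** is rel-GMR(HG) / geomean(rel-GMR of LG, LG+Mal,
  LG+Gal) with rel-GMR = GMR/MaxR; the resampling SD draws one biological
  replicate per condition uniformly at random, 1,000 times by default.

OD values are used as-is; an optional affine OD→density calibration hook
exists on `GrowthCurve` but no linear-range correction is applied.

## Censored lag survival analysis

Cells that never bud within the recording horizon (20 h default) are
censored at the horizon, never excluded. Kaplan–Meier estimation and the
two-group log-rank test are delegated to `lifelines`; the escape fraction
is 1 − survival. Summary moments (mean, SD, quartiles, noise = SD/mean)
are computed over event rows only, since censored lags are unknown; the
fraction-resumed statistic carries the censoring information.

The Cox proportional-hazards fit is implemented in-package: Newton
iteration on the partial likelihood with step-halving, centred covariates,
convergence at gradient norm < 1e-6 (or a stalled step at machine
precision), at most two covariates, standard errors from the observed
information, two-sided Wald p-values. **Breslow** tie handling is the
default — ties are common at 15–60-min scoring resolution and Breslow is
the simplest well-defined choice — with Efron available via `ties="efron"`.
On tie-free data the fit matches `lifelines`' CoxPHFitter to ~1e-5 and an
exhaustive partial-likelihood grid search to 1e-3 (both asserted in
tests). |β| drifting beyond 20 is flagged as likely complete separation.

## Lag competition simulator

The model: J strains with environment-specific rates μ_{j,k}. Glucose
segments are lag-free exponential growth. On every maltose entry each cell
draws a lag τ and a 0/1 viability status; a viable cell contributes
1 until t = τ and e^{μ(t−τ)} afterwards, a non-viable cell stays at 1 for
that maltose segment. Population sizes are real-valued — the only
stochasticity is the per-cell draw — and each maltose entry uses a fresh
cohort of `n_cells` agents (50,000 default) whose per-capita trajectory
rescales the strain's current population size. Time advances in 0.1-h
increments; segment durations not divisible by dt are rounded with a
warning.

Choices where the model is underdetermined:

- **Re-entries redraw lags independently each cycle**; no memory mechanism
  across cycles is modelled.
- **Cells still lagging when glucose returns grow immediately** at the
  glucose rate (glucose entries are lag-free by assumption). The ~10%
  glucose slowdown observed for maltose-committed cells is *not* in the
  model; the implementation carries no penalty term by default.
- **Non-viable cells** sit at size 1 for the maltose segment and are
  treated as viable again on the next glucose entry, since viability is
  defined only within the maltose observation horizon.
- **Cohort sampling is stratified by default**: lag times come from one
  uniform per equal-probability stratum pushed through the distribution's
  quantile function, and the viable count is the exact expectation with
  the fractional cell resolved by a single Bernoulli draw. Every cell's
  marginal law is unchanged; the cohort's Monte-Carlo error drops well
  below the iid rate, so a 50,000-cell cohort tracks the deterministic
  CDF-integral limit to a few 10⁻³ relative. `stratified=False` gives
  plain iid draws.

The deterministic oracle `lag_phase_expectation` evaluates
(1−v) + v·[S(t) + ∫₀ᵗ e^{μ(t−τ)} dF(τ)] by trapezoidal Stieltjes
quadrature on a 20,001-point CDF grid (exact summation for empirical
specs), including the atom at τ = 0 that zero-clipped normal laws carry.
It is used only as an independent cross-check, never as the simulator.

`proportion_heatmap` runs one maltose→glucose episode per grid cell and
uses **common random numbers**: every cell of the grid shares one cohort
draw, so duration effects are not confounded with Monte-Carlo noise
between cells, and monotonicity of the landscape in either duration axis
is a property of the dynamics rather than of sampling luck.

The shipped generalist/specialist pair (`synth.archetype_pair`) is an
**illustrative archetype**, not a fit: the specialist grows ~28% faster in
glucose (0.45 vs 0.35 /h) with a long uniform lag law (2–24 h, 92%
viable); the generalist has a short normal lag (2.5 ± 1.0 h, 97% viable);
both share the maltose rate (0.30/h). The exact parameter set behind the
published fitness landscape lives in unpublished supplementary material,
so the landscape is reproduced qualitatively (generalist dominance under
long maltose, specialist dominance under long glucose, a coexistence
band), not numerically.

## Malthusian fitness

w = ln(final subpopulation size / initial subpopulation size), with
subpopulation size = plating density × corrected label fraction (raw event
counts serve as sizes when no density is given). Duration normalisation is
deliberately omitted: it cancels in the ratio w_query/w_reference that is
used downstream, and the episode length is common to both strains.
Misclassification correction inverts M = [[1−e_rq, e_qr],[e_rq, 1−e_qr]];
the matrix is singular iff e_qr + e_rq ≥ 1, rates are restricted to
[0, 0.5), and negative corrected counts (possible at observed zeros) are
clipped to 0 with a warning. Replicate aggregation reports mean ± SD.

## Switching dynamics

The two-state chain is identified from paired hysteresis endpoints: the
gap between ON-started and OFF-started trajectories decays by λᵍ, so
λ = (gap_g/gap_0)^{1/g}, then f_∞ from either trajectory and
a = (1−λ)(1−f_∞), b = (1−λ)f_∞, clipped to [0,1]. Only λ ∈ (0, 1] is
recoverable from endpoints at non-integer powers; a non-positive gap ratio
or a growing gap raises an error naming the inconsistency. Flat series
yield a = b = 0. A least-squares variant fits the closed form to all
points when series are longer than two points. Delta-method standard
errors propagate binomial sampling noise through the endpoint estimator;
under the generator's per-generation resampling the final-fraction
variance accumulates as V' = λ²V + f(1−f)/n, which the SE uses by default.

Generations are expected as log₂ population fold-change; the conversion
from times is left to the caller/config. ON/OFF classification thresholds
are input parameters; no mixture-model deconvolution is attempted.

The estimation scheme is the minimal model consistent with per-generation
two-state switching; it is a reconstruction for rate *estimation*, not a
reproduction of any published rate values.

## Synthetic generators

Diauxic curves are generated from a rate-versus-OD law — constant μ₁ below
the shift OD, a cosine dip to the trough rate and recovery to μ₂ over a
set number of doublings, and a sharp logistic roll-off at the stationary
plateau — because the growth metrics are defined in rate-vs-OD space, so
ground truth is exact there: crossing times have the closed quadrature
form t(OD) = ln2·∫ dx/μ(2ˣ). Integration uses `solve_ivp` at rtol 1e-10
with dense output, sampled on the 15-min grid, with mean-one lognormal
multiplicative noise. Lag tables attach proportional-hazards covariates
exactly via S₁ = S₀^HR inverse sampling. Competition counts sample labels
binomially (or return the infinite-event limit) and apply forward
misclassification event-wise.

What the generators deliberately do **not** emulate: evaporation and
edge-well artifacts, carrying-capacity coupling between wells, scoring
discretisation of bud times, cytometry gating noise beyond the 2×2
confusion model, and any resource (Monod) dynamics. Passing recovery tests
therefore demonstrates estimator correctness under the stated models, not
robustness to instrument pathologies.

## Problem sizes and defaults

Simulations in the test suite and the acceptance script use the model's
own defaults where they are part of the model (0.1-h steps, 50,000-cell
cohorts, 24-h viability horizon, 20-h censoring horizon, 1,000 resamples)
and modest panel sizes elsewhere (10–18 synthetic strains, 200–2,000 cells
per lag table, 200-seed recovery batteries, 1,000 null simulations for
test calibration) — sizes at which every Monte-Carlo tolerance asserted is
a ≥3σ bound under the stated sampling model.

## Known limitations

- The Cox fit supports at most two covariates and no stratification,
  frailty, or time-varying effects.
- The endpoint switching estimator cannot recover negative memory
  (a + b > 1) from non-integer generation counts; oscillatory chains need
  the least-squares variant on integer-generation series.
- The simulator has no resource dynamics, death, dilution events, or
  demographic noise in division timing; within-segment growth is exactly
  exponential.
- GMR assumes the curve actually spans the OD band; wells that never reach
  0.75 are summarised only up to the metrics that are defined.
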