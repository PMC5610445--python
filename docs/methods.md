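# Methods

This note documents the models and procedures the package implements, the
defaults and where they come from, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Respirometry processing

A trial is a 1 Hz time series of raw oxygen-analyzer readings from a
closed 896 ml chamber flushed at a constant 350 ml min⁻¹, with CO₂ and
water scrubbed upstream of the sensor.

* **Calibration.** Two-point linear calibration against pure N₂ (0% O₂)
  and outdoor air (20.95% O₂), with one pair at trial start and one at
  trial end. Zero and span are linearly interpolated in time between the
  pairs, which removes linear sensor drift exactly; with only a start pair
  the package falls back to a constant calibration and warns. Calibrated
  fractions outside [−0.01, 0.25] are flagged `out-of-calibration`.
* **Mass balance.** VO₂ = F_ri (FᵢO₂ − FₑO₂)/(1 − FₑO₂). Flow and
  instantaneous VO₂ are kept in ml min⁻¹ throughout; RMR is reported in
  ml h⁻¹ (× 60). Negative drawdowns are returned but flagged, never
  silently clipped.
* **STP correction.** Per-sample ideal-gas factor
  273.15/(T+273.15) × P/101.325 using the trace's chamber-temperature and
  pressure columns (defaults 22 °C / 101.325 kPa when absent).
* **RMR extraction.** Among all contiguous 10-min windows starting at or
  after the 30-min acclimation (configurable; 0 disables it for the
  short-protocol trials used at extreme temperatures), windows containing
  flagged samples are inadmissible, and the remaining windows must satisfy
  a stability criterion. "Stable" is not defined operationally in the
  protocol this package models, so the package defines it as a
  within-window coefficient of variation ≤ 0.10 (configurable). The
  admissible window with the smallest mean is the RMR window. The scan is
  a cumulative-sum sweep over every 1 s start offset, and is tested
  against a brute-force window scan for exact global minimality.
* **Washout.** The chamber's first-order time constant is
  τ = volume/flow = 2.56 min. No response correction (Z-transform) is
  applied; the acclimation discard covers equilibration, and the 10-min
  window is long relative to τ.

## Jonckheere-Terpstra trend test

For groups ordered by ambient temperature, J counts cross-group pairs in
which the later group's value is larger, ties counting ½ (deterministic
even though ties have measure zero for continuous msRMR). The decreasing
alternative evaluates J on the reversed group order.

* **Exact p.** Exhaustive enumeration over all distinct assignments of
  pooled-value *positions* to the group sizes (index-combination
  recursion). Each multinomial split is equally likely under
  exchangeability, so tied values are weighted with correct multiplicity.
  Capped at 2 × 10⁶ splits; beyond that the permutation form is the tool.
* **Permutation p.** n_perm seeded reshuffles of the pooled values across
  groups holding sizes fixed, vectorized over permutations;
  p = (1 + #{J* ≥ J})/(n_perm + 1) (add-one form, so p > 0 always).
  Defaults: n_perm = 10 000, seed = 20170922. Group values are stored
  sorted, making every p-value invariant to input record order.

## Step-down TNZ search

1. Drop temperatures with fewer than `min_group_n = 5` values.
2. T\* = qualifying temperature with the lowest mean msRMR (ties break to
   the lower temperature).
3. Upper side: test temperatures ≥ T\* for an increasing trend at
   α = 0.05; while significant, drop the hottest group and retest. The UCT
   is the hottest temperature of the first non-significant range.
4. Lower side: test temperatures from the design minimum up to the UCT for
   a *decreasing* trend (msRMR falls as Tₐ rises toward the TNZ — the only
   direction consistent with thermoregulatory physiology); while
   significant, drop the coldest group and retest. The LCT is the coldest
   temperature of the first non-significant range.

A boundary equal to the extreme qualifying temperature is flagged
`boundary-of-design` (the design did not bracket it). Two edge policies
were genuinely open and are resolved as follows: a side that *starts* with
fewer than two groups (T\* already at the design edge) has no testable
trend, and the boundary is reported as that temperature with the flag; a
side whose loop stays significant down to fewer than two groups raises a
no-TNZ-detected error carrying the full step trail, because a boundary
inside the design genuinely was not found. α was not dictated by the
procedure's source and defaults to 0.05, consistent with the decisions the
procedure is known to have produced (p = 0.0486 treated as a trend, 0.16
not). The full trail of every test is always returned, mirroring a
critical-temperature summary table.

**Known limitation — post-selection behaviour.** Because T\* is the
*sample* minimum, the first upper-side tests condition on that choice and
over-reject on a flat plateau; when T\* falls on the hottest plateau
temperature the upper loop can exhaust into the error path. Simulations at
the emulated design (flat 26–30 °C plateau, n = 14, Gamma CV 0.2) end in
the error in roughly half the seeds and otherwise recover UCT = 30 °C
modally. Symmetrically, the final one-degree step of the lower search must
detect a 0.05 ml g⁻¹ h⁻¹ elevation at one temperature against ≈ 0.19
noise SD (one-sided power ≈ 0.16 at these sample sizes), so the modal LCT
estimate lands one design step low (25 °C for a true 26 °C boundary).
These are properties of the published procedure at these effect sizes, not
of the implementation; the test suite records them honestly.

## Gamma GLMM (identity link)

y_ij ~ Gamma(shape k, mean μ_ij), μ_ij = x_ij'β + u_i, u_i ~ N(0, σ_u²),
variance μ²/k (CV = k^{-1/2}), mean/shape parameterization. The marginal
likelihood integrates each animal's u_i by adaptive Gauss-Hermite
quadrature centred at the per-animal posterior mode (damped, vectorized
Newton) and scaled by its curvature; `n_quad = 1` is exactly the Laplace
approximation, the default is 11 nodes. β, log k and σ_u are maximized
jointly by L-BFGS-B with a second start at the σ_u = 0 boundary (guards
against flat ridges when the random effect is weakly identified).

* **Positivity.** Identity link does not guarantee μ > 0; any parameter
  vector with min μ ≤ 10⁻⁶ receives a smooth, steep penalty, and the
  quadrature nodes mask excursions below the floor. log k is bounded in
  [−5, 20]; the cap binds only for degenerate zero-variance responses.
* **Inference.** Standard errors from the observed information (numerical
  Hessian, pseudo-inverted if σ_u sits on its boundary). AIC = 2k_p − 2logL
  with k_p = #β + 1 (shape) + 1 (σ_u unless fixed). Nested models are
  compared by the likelihood-ratio χ². The status contrast (breeder minus
  non-breeder, response scale) uses a Wald statistic referred to the
  standard normal by default — denominator degrees of freedom for a GLMM
  are contested — with a t-reference available via `df=`.
* **Forward selection** starts from the intercept + random-intercept null
  model and, each round, accepts the candidate with the lowest AIC
  provided it both lowers AIC and has LRT p < α. AIC-vs-LRT precedence was
  ambiguous in the procedure modelled; requiring both is the stricter and
  is applied uniformly (so even α = 1 cannot drag in AIC-worsening terms).
  Continuous covariates (√mass, age) are centred — √mass is nearly
  constant relative to its mean and leaving it raw ill-conditions the
  likelihood surface. When two or more terms are accepted, the
  all-interactions model is reported as a supplementary fit. Age is an
  optional candidate meant for the known-age subset.
* **Oracle.** With σ_u fixed at 0 the model is an independent Gamma GLM;
  the fit is verified against statsmodels' IRLS Gamma GLM to 10⁻⁴
  relative — the GLM is never the implementation, only the cross-check.

## Synthetic-data generator

The generator defines the conditions under which everything is tested.

* **Thermal curve.** Piecewise-linear Scholander-Irving form: flat plateau
  between LCT and UCT, linear rise outside. Status-specific defaults:
  plateau 0.89 (non-reproductive, TNZ 26–30 °C) and 1.17 (reproductive,
  TNZ 28–33 °C) ml O₂ g⁻¹ h⁻¹ — the fitted status levels and reported
  TNZs of the emulated study. Slopes outside the TNZ are not printed in
  that study; defaults are slope_low = 0.05 and slope_high = 0.08
  ml g⁻¹ h⁻¹ per °C.
* **Noise.** Per-animal additive intercept u_i ~ N(0, σ_u = 0.05) shared
  across repeated measurements, then Gamma noise with shape 25 (CV 0.2),
  anchored to the printed SD/mean ratios (≈ 0.23/0.81 at single
  temperatures, 0.19/0.89 pooled within the TNZ). Draws with a
  non-positive mean trigger an intercept redraw (practically unreachable
  at the defaults).
* **Design.** Non-reproductive: 14 animals at 10, 15, 20, 25, 26, 28, 30,
  32, 33, 34, 35, 37 °C and 11 at 40 °C. Reproductive: 12 animals at 28,
  30, 32, 33 °C and 4 at 20, 25, 26, 34, 35, 37 °C. Rosters draw body
  mass and age per sex × status from the study's summary moments.
* **Traces.** True VO₂ = resting level, elevated ×2.5 during
  Poisson-arriving 120 s activity bouts (rate 2 h⁻¹ — enough to exercise
  the minimal-window logic); excurrent fraction from the exact inverse of
  the mass balance, fe = (F_ri FᵢO₂ − VO₂)/(F_ri − VO₂), relaxed with the
  τ = 2.56 min washout; raw sensor values add Gaussian noise
  (2 × 10⁻⁴ raw units) and linear baseline drift (−5 × 10⁻⁴ per hour)
  that the returned start/end calibration pairs correct by construction.
  The requested resting VO₂ is an STP value; the chamber-condition VO₂ is
  back-computed so the analysis chain's STP correction recovers the input.
* **Not emulated:** CO₂/RER and humidity dynamics, torpor or hyperthermia,
  behavioural autocorrelation beyond square bouts, analyzer nonlinearity.
  Passing tests therefore show the estimators recover the generative truth
  under the stated noise model — not that real traces are this benign.

All generators are bit-reproducible under a fixed seed; the pipeline
splits one root seed deterministically per stage (and writes no
timestamps into artifacts, so reruns are byte-identical).

## Problem sizes used by the checks

The recovery experiments use 50 replicates for the mixed model (26
animals, 90 within-TNZ records each) and 20 seeds per design for the
step-down search with n_perm = 10 000; the null-calibration check uses
1000 exchangeable datasets at n_perm = 999 (the add-one estimator makes
the effective level ≈ 0.049). These sizes give Monte-Carlo standard errors
comfortably below the tolerances being checked.
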