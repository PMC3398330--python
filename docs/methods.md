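# Methods

## Model

A tail skin temperature series from one animal in one experimental phase is
modelled as `y_n = x(nΔt) + c(nΔt) + e_n` with Δt = 3 min.  The circadian
component `x(t)` is the second-order perturbation solution of the van der
Pol oscillator `ẍ + εω(4x²/γ² − 1)ẋ + ω²x = 0` (ω = 2π/τ):

    x(t) = a(t)·cos(ωt + ψ) − ε·a(t)³/(8γ²)·sin(3ωt + 3ψ),
    a(t) = [ (1/a0² − 1/γ²)·e^(−εωt) + 1/γ² ]^(−1/2).

The O(ε²) remainder of the expansion is dropped.  The leading amplitude is
the dynamic `a(t)` in both terms; a frozen-amplitude variant
(`dynamic_amplitude=False`) exists for comparison but is not the default,
since the whole point of the model is that the envelope moves.  The
envelope obeys `ȧ = εωa/2·(1 − a²/γ²)` exactly (it is the closed form's
exact derivative), so `a(t)` runs monotonically from `a0` to the limit-cycle
amplitude `γ`.  When `a0 = γ` the integration constant `k` defined by
`1/(4k) = 1/a0² − 1/γ²` is at infinity; the code returns an `inf` sentinel
and the amplitude is constant, avoiding any division by zero.

The baseline `c(t) = c0 + c1·t` absorbs the one-sided nighttime elevation
produced by estrogen deprivation (the oscillator itself is symmetric about
its baseline).  Time is measured in **hours since the first sample of the
phase**; `c1` is °C/hour.  Each phase of each animal is fitted
independently.

Noise is independent Gaussian with three variances tied to the husbandry
day: day1 = [06:00, 12:00) (husbandry and dosing disturbances),
day2 = [12:00, 18:00) (quiet), night = [18:00, 06:00) (activity).
Intervals are half-open and left-closed, so the three regimes partition the
clock exactly; a sample's regime comes from its timestamp's clock time, so
series need not start at midnight (simulated series start at 06:00, the
start of the husbandry day).

## Fitting

Pseudo-maximum likelihood with the diagonal-covariance Gaussian negative
log-likelihood as objective:

1. `(c0, c1)` by OLS on the whole phase; held fixed thereafter.
2. `τ = 24 h` fixed (entrainment to the 12:12 light cycle).
3. `(a0, γ, ε, ψ)` by L-BFGS-B within box constraints; at **every**
   objective evaluation the three regime variances are re-profiled as the
   per-regime mean squared residuals (divisor n, floored at 1e-6 °C²), i.e.
   the optimiser sees the profile likelihood.  An alternative outer-loop
   mode (optimise with variances fixed, re-profile, repeat to a 1e-6
   relative tolerance) is available via `FitConfig(profile_mode="outer")`
   and agrees with the default on smooth data.

Boxes: `ε ∈ [0.2, 1]` — the floor prevents the degenerate trade-off where a
huge `γ` hides behind a vanishing `ε`, the ceiling keeps the perturbation
solution near the true oscillator; `ψ ∈ [−π, π]`; `a0` and `γ` bounded
above by half the raw span of the first and last day respectively, and
below by 0.05 °C (a floor below any physiologically meaningful amplitude,
needed only to keep the closed form defined).

Start values: one-day cosinor regressions `A1·cos(ωt) + A2·sin(ωt)` on
**detrended** data — amplitude `√(A1²+A2²)`, phase `−atan2(A2, A1)` — using
the first day for `a0` and `ψ` and the last day for `γ`; `a0` is overridden
to 0.5 °C in phase P1, where post-surgical hypothermia makes the first day
unreliable; `ε` starts at 0.5 (box midpoint; no principled preference).
Optimiser tolerance 1e-8 on relative objective decrease, at most 500
iterations; non-convergence is flagged on the returned fit rather than
raised, and the final value never exceeds the start value.

Reported per fit: all ten parameters, NLL, AIC = 2p + 2·NLL with p = 9 free
parameters (τ is fixed; a p = 10 count is available), the end-of-phase
amplitude `a(T)` with `T = n·Δt`, residuals by regime, bounds and start
values.  Identifiability caveat: when the true amplitude is constant, `a0`
carries almost no information (there is no transient) and its estimate
scatters with an SD of ~0.3 °C at study noise levels; this is a property of
the model, not an optimiser artefact (the fitted `a0` sits at its exact
conditional optimum), and is why `γ`, not `a0`, is the treatment endpoint.

## Inference

The endpoint is the fitted `γ` per animal and phase, collected into a
per-animal table.  Two contrasts:

* **Restoration within group**: within-animal differences `γ_P2 − γ_P3`,
  summarised by a percentile bootstrap of the mean (B = 1000) with a
  one-sided 95% interval `(−∞, q_0.95]`; an interval entirely below zero
  demonstrates significant amplitude recovery under treatment.
* **Similarity between compounds**: reconstruction ratios `Q = γ_P3/γ_P1`
  per animal; one-sided bootstrap test of the difference of group medians
  `θ_ref − θ_test` against a margin of 0.2 on the ratio scale
  (H0: difference ≥ 0.2), resampling groups independently, with
  p = P*(difference ≥ margin) and rejection when the 95% upper percentile
  bound falls below the margin.  The difference-of-medians estimator (not a
  median of cross-pair differences) matches the reported estimator
  convention; percentile intervals (not BCa) are used throughout; even-n
  medians use the standard midpoint definition.

Percentile-bootstrap caveats, measured by the calibration tests: with
n = 10 per group the one-sided mean interval is anti-conservative (miss
rate ≈ 8% instead of 5% under normal data — the usual small-sample
behaviour of the percentile method), while the non-inferiority test holds
its size at the H0 boundary (≤ α + 3%).  The p-value and the CI decision
agree up to quantile interpolation, which percentile bootstrapping does not
guarantee exactly.

## Synthetic data

`default_scenario` emulates the two-group OVX study: 10 animals per group
(estradiol reference "E2", test compound "Tibolone"), phases P1 = 6 d
(estrogen reference), P2 = 6 d (vehicle washout), P3 = 10 d (treatment),
480 samples/day.  Per-animal parameters are drawn independently per phase
from normal distributions centred at published group means with the
published between-animal spreads used as SDs (the conservative reading of
"±"), truncated to valid ranges (`ε` to [0.2, 1], `ψ` to [−π, π],
amplitudes ≥ 0.1–0.3 °C, variances ≥ 0.5 °C²).  Central values: `γ` falls
from ~4.0/3.6 (P1) to ~1.6 (P2) and recovers to 2.7/3.3 (P3); baselines
~30 °C; variances 3.5–15 °C², night and morning noisier than the quiet
afternoon.  Noise is sampled from the fitted-model form (perturbation
solution + trend + regime Gaussians), not by integrating the raw ODE — the
likelihood is defined on the perturbation solution, so the simulator and
the estimator share one data-generating form.

What the simulator does **not** emulate: residual autocorrelation from
short-term thermoregulation (real residuals show short-range dependence;
the injection/husbandry disturbances appear only as the inflated morning
variance, not as structured transients), non-Gaussian tails, and
between-animal correlation of parameters across phases (draws are
independent).  Passing recovery tests therefore demonstrate correctness of
the estimator under its own assumptions, not robustness to these real-data
features.

The fixed-step RK4 integrator of the van der Pol ODE (default step 0.02 h)
exists purely as a validation oracle.  Two numerical findings are baked
into the tests: (1) starting **on the limit cycle**, the sup-norm gap
between the RK4 trajectory and the perturbation solution over 10 periods
scales cleanly as O(ε²) (measured ratio 4.0 when ε is halved from 0.1 to
0.05); a mid-transient start mixes in the incomplete amplitude relaxation
and yields much larger apparent ratios, so convergence-order experiments
use `a0 = γ`.  (2) The envelope reaches `γ` to 0.1% by 144 h across a full
factor-10 range of `a0/γ` only for ε ≥ 0.3; at the ε = 0.2 box floor a
growing amplitude started at `γ/10` is still ~2.6% short (the relative gap
is `(γ²/a0² − 1)/2 · e^(−εωt)`), while decaying starts converge already at
ε = 0.2.

## Problem sizes and tolerances

Simulation-based tests use the study's native sizes (2880-sample 6-day
phases, 4800-sample 10-day phases, 20-animal studies) — single fits take
~0.1 s, the full 60-fit study a few seconds.  Calibration experiments use
500 Monte-Carlo replicates at B = 1000 bootstrap samples.  Variance floor
1e-6 °C²; amplitude floor 0.05 °C; RK4 step 0.02 h; likelihood oracle
agreement asserted to 1e-10.

## File formats

Series: long CSV (`animal_id, group, phase, timestamp, temperature_c`),
ISO 8601 timestamps (numeric minutes-since-phase-start accepted given a
start clock hour), temperatures written at 6 decimals so round trips
preserve values to 1e-6 °C.  Ground truth and fits: JSON.  The
human-readable comparison report rounds to 4 decimals; machine formats
keep full precision.
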