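# circavdp

Dynamic van der Pol modelling of circadian rhythms in rodent tail skin
temperature telemetry.

## The problem

In the ovariectomized (OVX) rat model of menopausal thermoregulatory
dysfunction, estrogen deprivation flattens the circadian oscillation of tail
skin temperature; an effective treatment restores its amplitude.  Telemetry
yields long, noisy series (one sample every 3 minutes for days), and the
scientific quantity of interest is not the temperature itself but the
*amplitude dynamics*: how large the daily oscillation is at the end of a
treatment phase, and how fast it got there.  `circavdp` is for
pharmacologists and biostatisticians who want to turn such series into
interpretable oscillator parameters and group-level treatment comparisons.

## The model

An observed series is decomposed as

    y_n = x(nΔt) + c(nΔt) + e_n

where `c(t) = c0 + c1·t` is an affine baseline, `e_n` is independent
Gaussian noise with one variance per daily regime — morning 06:00–12:00
(husbandry and dosing disturbances), afternoon 12:00–18:00 (quiet), night
18:00–06:00 (active) — and `x(t)` is the circadian component of a van der
Pol oscillator

    ẍ + εω(4x²/γ² − 1)ẋ + ω²x = 0,   ω = 2π/τ,

represented by its second-order perturbation solution

    x(t) = a(t)·cos(ωt + ψ) − ε·a(t)³/(8γ²)·sin(3ωt + 3ψ)

with the closed-form dynamic amplitude

    a(t) = [ (1/a0² − 1/γ²)·e^(−εωt) + 1/γ² ]^(−1/2),

which starts at `a0 = a(0)` and approaches the limit-cycle amplitude `γ`
monotonically at a pace set by the flexibility `ε`.  Fitting is
pseudo-maximum likelihood: the trend is fixed by OLS, `τ` is pinned to 24 h
by the imposed light cycle, the three regime variances are profiled from
residuals, and `(a0, γ, ε, ψ)` are optimised by bounded L-BFGS-B
(`ε ∈ [0.2, 1]`, `ψ ∈ [−π, π]`, amplitude bounds from the first/last day's
raw span).  Group inference runs on the fitted `γ` per animal and phase:
bootstrap mean confidence intervals for the within-animal washout-to-treatment
differences `γ_P2 − γ_P3`, and a one-sided bootstrap median test of the
reconstruction ratios `Q = γ_P3/γ_P1` against a non-inferiority margin.

## Worked example

Simulate one washout-like phase (6 days, true `γ = 2.7`, realistic noise)
and fit it:

```python
from circavdp import *

design = StudyDesign()
truth = FullModelParams(
    vdp=VanDerPolParams(a0=1.4, gamma=2.7, epsilon=0.3, psi=0.15),
    trend=TrendParams(c0=30.7, c1=1e-4),
    noise=NoiseParams(var_day1=10.0, var_day2=3.5, var_night=9.8),
)
series = simulate_phase(truth, design, phase="P2", seed=42,
                        animal_id="r01", group="E2")
fit = fit_phase(series)
v = fit.params.vdp
print(f"n = {series.n} samples over {series.duration_hours:.0f} h")
print(f"a0 = {v.a0:.4f}  gamma = {v.gamma:.4f}  eps = {v.epsilon:.4f}  psi = {v.psi:.4f}")
print(f"a(T) = {fit.a_at_T:.4f}  AIC = {fit.aic:.1f}  converged = {fit.converged}")
```

prints

```
n = 2880 samples over 144 h
a0 = 1.2221  gamma = 2.6248  eps = 0.3865  psi = 0.1513
a(T) = 2.6248  AIC = 14061.8  converged = True
```

The limit-cycle amplitude is recovered to within 0.08 °C of the truth at a
noise level several times the signal amplitude, and `a(T) ≈ γ̂` shows the
oscillation has settled on its limit cycle by the end of the phase.

The same pipeline from the shell, for a full two-group study (20 animals,
phases of 6/6/10 days):

```sh
circavdp simulate --seed 1 --out study.csv --truth truth.json
circavdp fit --input study.csv --out-summary fits.csv
circavdp compare --summary fits.csv --out report.json --seed 1
```

```
Mean differences gamma_P2 - gamma_P3 (one-sided bootstrap CI)

group         estimate  CI
E2             -1.2733  (-inf, -0.8547]
Tibolone       -1.3855  (-inf, -0.8993]

Reconstruction-ratio non-inferiority test (margin 0.2, alpha 0.05)

estimator                 estimate  CI                  p
median(ref)-median(test)   -0.2095  (-inf, 0.0359]      0.0230
H0 (difference >= 0.2) rejected
```

Both confidence intervals lie entirely below zero — treatment significantly
restored the circadian amplitude in both groups — and the reconstruction-ratio
test rejects a reference-over-test recovery deficit of 0.2, i.e. the test
compound restores a similar fraction of the pre-surgery amplitude.

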