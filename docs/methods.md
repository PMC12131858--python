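# Methods

## Target profiles

Both operating modes of the rig are defined by a one-compartment target
model with first-order elimination `ke` (h⁻¹), dosing interval `τ` (h) and a
first-dose peak `Cmax,1` (mg/L):

* **IV mode** — zero-order input of duration `t_infusion`; the single-dose
  solution rises as `1 − e^(−ke·t)` during the infusion and decays
  mono-exponentially after it; the peak sits at the end of the infusion.
* **Absorption mode** — first-order input at rate `ka` (h⁻¹); the
  single-dose solution is the Bateman function
  `C(t) ∝ e^(−ke·t) − e^(−ka·t)` with peak time
  `t_max,1 = ln(ka/ke)/(ka−ke)`. When `|ka−ke|/ke < 1e-8` the flip-flop
  limit `C(t) ∝ t·ke·e^(−ke·t)`, `t_max = 1/ke` is used instead, which
  avoids catastrophic cancellation near the removable singularity.

Multi-dose profiles are plain superpositions of the single-dose solution,
scaled so the first-dose peak equals `Cmax,1` exactly. Secondary parameters
follow the standard closed forms: `t_1/2 = ln 2 / ke`; doses to ~90% of
steady state `N = ⌈3.3·t_1/2 / τ⌉`; IV accumulation ratio
`Rac = 1/(1 − e^(−ke·τ))`; in absorption mode the steady-state peak, trough
and within-interval peak time are evaluated on the closed-form
steady-state profile
`Css(t) ∝ e^(−ke·t)/(1−e^(−ke·τ)) − e^(−ka·t)/(1−e^(−ka·τ))`.

All internal computation uses hours, mg, L and mg/L; minutes and mL/h
appear only at the I/O boundary (pump programs), because pump hardware is
programmed in those units while all rate constants are per hour.

## Pump-program design (absorption mode)

Given `Cmax,1`, `ka`, `ke`, the end time of the last sub-interval `t_n` and
the design volume `V_total`, the nominal dose is the inverse of the
Bateman peak:

```
Dose = Cmax,1 · V_total · (ka−ke) / (F · ka · (e^(−ke·t_max) − e^(−ka·t_max)))
```

Only `f_dose = 1 − e^(−ka·t_n)` of it can be delivered by `t_n`; the
schedule divides that deliverable amount into `n` equal parts with end
times `t_i = −ln(1 − f_dose·i/n)/ka`, so the cumulative delivery at every
`t_i` coincides exactly with the continuous first-order input. Durations
therefore increase strictly with `i` (convexity of the exponential), and
the per-interval infusion rate is `S_i = (A_{i−1} − A_i)/(t_i − t_{i−1})`
with `A_i = Dose·e^(−ka·t_i)`.

The infusion-solution concentration is chosen so each sub-interval infuses
a fixed volume (default 2.0 mL, the smallest volume the ambulatory pump
injects with good precision); flows are then `S_i / C_infusion`.

**Quantization.** Flows are rounded to the pump's programmable grid
(default 0.1 mL/h). Durations are rounded in two stages: first to 0.1 min —
the precision at which the design app displays them — then half-up to whole
minutes. The two-stage rule reflects how programs are actually transcribed
into the pump and differs from single-stage rounding in the two cases where
the raw duration falls in [x.45, x.50) minutes (e.g. 18.468 → 18.5 → 19,
41.495 → 41.5 → 42). Delivered amounts are recomputed as
flow × duration × concentration and kept alongside the nominal equal
amount; for the reference 12-step design the total delivered deviates from
nominal by < 0.1%.

The same quantized program is repeated every `τ` with no carry-over
correction for the undelivered `1 − f_dose` fraction — mirroring actual
practice, where this causes a small systematic under-exposure. Rounding can
make a program's total length overrun `τ` by a minute; overruns up to 2% of
`τ` are truncated at the interval boundary when the program is tiled
(the clipped amount is ≤ 0.01 mg for the reference design).

**Design volume.** `V_total = V_central + V_ECS` (0.300 + 0.060 = 0.360 L
for the reference rig). The fiber-lumen (ICS) volume is excluded: it is in
fast equilibrium with the reservoir through the circulation loop and is
accounted for only by the tri-compartment simulator. This choice is what
reproduces the reference program's 0.297 mg per sub-interval.

**IV mode.** The dose carries an elimination-during-infusion correction,
`Dose = Cmax,1·V_total·(ke·t_inf)/(1 − e^(−ke·t_inf))`; without it a 30-min
infusion undershoots the target peak by roughly `ke·t_inf/2` (≈ 6% at
`ke` = 0.23 h⁻¹).

**Elimination pump.** `CL_elim = ke·V_total`; diluent volume
`V_diluent = CL_elim·Exp_duration` (7.95 L at the defaults).

## Rig simulator

The physical rig is a tri-compartment linear system (amounts `A`,
concentrations `C = A/V`):

```
dA_c/dt = in(t) + Q_cart·(C_i − C_c) − CL_elim·C_c
dA_i/dt = Q_cart·(C_c − C_i) + Q_diff·(C_e − C_i)
dA_e/dt = Q_diff·(C_i − C_e)
```

Reference configuration: `V_central` = 0.300 L, `V_cartridge` = 0.078 L of
which `V_ICS` = 0.018 L (fiber lumen of a pediatric dialyzer) and
`V_ECS` = 0.060 L, loop flow `Q_cartridge` = 3.6 L/h (60 mL/min),
`CL_elim` = 0.0828 L/h, `Q_diffusion` = 0.387 L/h, 96 h experiments.

Because the input is piecewise constant, the system is linear
time-invariant within every segment, and the simulator propagates the
*exact* solution with a matrix exponential per step (a 5×5 augmented matrix
carrying the two amounts integrals: cumulative elimination and the
constant input). Exponentials are cached per distinct (rate, step) pair, so
a uniform output grid costs one `expm` per sub-interval plus matrix–vector
products. This sidesteps the stiffness of the system (the ICS equilibrates
with time constant `V_ICS/Q_cart` ≈ 18 s, elimination with ≈ 4.3 h) and
makes the mass-balance identity — infused = content + eliminated — hold to
~1e-14 relative, which the tests assert at 1e-6.

The `V_ICS` default is nominal (the exact fiber fraction is
manufacturer-specific); a test documents that the short-infusion delay
metric varies by less than the 0.25 h reporting resolution over
`V_ICS ∈ [0.01, 0.03]` L.

### Central-vs-ECS metrics

Per dosing interval, the simulator reports the ECS-minus-central peak-time
difference, the ECS/central peak ratio, and the ECS/central AUCτ ratio
(trapezoid on the simulation grid). Peak times are read off the grid
(default 0.01 h) and can be snapped to a coarser reporting grid (0.25 h)
to mirror sparse experimental sampling.

Two regimes behave qualitatively differently:

* **Short infusion** — the central concentration changes fast, so the ECS
  (fill time constant `V_ECS/Q_diff` ≈ 9 min) lags: peak delay ≈ 0.3 h and
  ≈ 12% peak attenuation at the reference configuration, while AUCτ is
  preserved (at steady state exactly, by flow balance).
* **Absorption program** — the driving is slow and the two compartments
  peak together *in amplitude*: their concentrations agree to < 0.3% around
  the peak. A caveat for fine-grid argmax metrics: because the first-dose
  peak is extremely flat, the grid argmax of two nearly identical flat
  curves can sit ~0.7 h apart at dose 1 even though the curves are
  indistinguishable; from the second dose on (and on the 0.25 h reporting
  grid) the delay is zero. Validation therefore evaluates the delay on
  steady-state intervals at the reporting resolution.

## Diffusion-flow estimation

`Q_diffusion` is the only structural unknown; everything else is fixed to
experimental values. The estimator maximizes a Gaussian likelihood with
combined residual error `sd² = sd_add² + (sd_prop·pred)²` over
(`log Q_diffusion`, `log sd_add`, `log sd_prop`) using L-BFGS-B from five
log-spaced starts in [0.001, 100] L/h; the log parameterization guarantees
positivity, and the additive floor (1e-6 mg/L) keeps the likelihood finite
on noise-free data. The standard error comes from the numerical curvature
of the profile likelihood in `log Q` (delta method). Replicates are pooled:
with every structural parameter but one fixed, between-replicate random
effects are not identifiable and are out of scope.

The synthetic-observation generator perturbs exact simulations with the
same combined error model (values truncated at zero), seeded explicitly.
The default synthetic experiment samples both central and ECS in 2
replicates at 10% proportional noise, **densely over the first 1.5 h
(every 0.05 h) and hourly afterwards**: the information about a diffusion
lag with a ~9 min time constant lives in the early rise, and sampling that
resolves it makes the estimator unbiased (sparse 15-min sampling leaves a
~5% finite-sample bias). With this design the 20-seed recovery test sees a
median error < 5% and every run within 15%.

### Validation rules

* **Prediction-interval rule** — 1,000 simulations with residual noise from
  the fitted model form a pointwise 5th–95th percentile band; the setup
  passes when ≥ 90% of observations fall inside. On well-calibrated data
  the observed coverage fluctuates around 0.90 (Monte-Carlo and estimation
  error), so this hard threshold fails near-calibrated data about half the
  time; it is a gross-misfit detector, not a calibrated test.
* **20% rule** — per-parameter percent bias `100·(obs−target)/target` for
  concentrations, AUCs and half-life, absolute bias in hours for peak
  times (a percent scale is meaningless for a clock time); pass at
  |bias| ≤ 20% (peak times: ≤ 0.5 h by default). Aggregates: mean
  percentage error (bias) and RMSE (imprecision) over the relative rows.

## What the synthetic data does and does not emulate

The generator reproduces the deterministic rig physics plus assay-like
noise. It does not emulate drug adsorption to fibers, bacterial
degradation, temperature drift, pump mis-programming or sample-handling
losses — so passing recovery/coverage tests demonstrates the estimator and
the validation machinery, not the behavior of any particular wet rig.
Observed data from a real experiment enter through the same
`ConcentrationSeries` CSV format.

## Problem sizes and tolerances

Simulation grids default to 0.01 h; peak times are grid-quantized by
design (observed peak-time reporting is grid-quantized too). Validation
simulations use 3–4 dosing intervals, the estimator tests 20 seeds × ~100
observations, and the prediction-interval check 1,000 replicates — sizes
chosen so the whole suite runs in well under a minute of compute per
module while keeping Monte-Carlo error comfortably inside the asserted
tolerances. Equal-rate absorption uses the 1e-8 relative switching
threshold; schedule conservation identities are asserted at 1e-12–1e-14;
the rig mass balance at 1e-6 (actual ~1e-14).

## Known limitations

* The one-compartment approximation is the design contract: targets whose
  true profiles are multi-compartmental must first be approximated by
  (`Cmax,1`, `ka`, `ke`) — the package never re-derives such parameters
  from a clinical model, it takes them as inputs.
* The undelivered `1 − f_dose` fraction is not carried over between doses;
  multi-dose absorption profiles therefore sit systematically slightly
  below the ideal curve, as they do on real rigs.
* The pump flow grid (0.1 mL/h) and the 2 mL minimum precise volume are
  defaults inferred from one pump model; both are configurable.
* `compare_to_target` assumes matched parameter names and a nonzero
  target; zero targets are flagged rather than scored.
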