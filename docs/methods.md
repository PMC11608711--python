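# Methods

## Model structure

A partitioned survival model with three health states — progression-free
(PFS), progressed disease (PD), dead — on 21-day cycles over a 20-year
horizon (348 cycles; the final cycle is truncated so the horizon is
covered exactly). State occupancy is read directly off the modelled
curves: `pfs_k = min(PFS_k, OS_k)`, `pd_k = OS_k − pfs_k`,
`dead_k = 1 − OS_k`, which partitions to 1 by construction. Costs and
QALYs accrue at cycle starts and are discounted at 3%/year in continuous
cycle time, `(1 + r)^(−t_k)`. A half-cycle correction switch exists but
is off in the base configuration.

Three arms: **BC** (bevacizumab 15 mg/kg + paclitaxel 175 mg/m² +
cisplatin 75 mg/m², chemo capped at 6 cycles), **ABC** (adds
atezolizumab 1200 mg flat, capped at 2 years ≈ 34 cycles in the base
case), **PBC** (adds pembrolizumab 200 mg flat, capped at 35 cycles).
Drugs are priced linearly per mg at pack prices (no vial rounding) using
average US female weight (77.5 kg) and body surface (1.86 m²). Cost
components: drug acquisition (× PFS occupancy, respecting caps),
administration (cycles with any active drug), follow-up (all alive),
severe adverse events (one-off at cycle 0: Σ incidence × unit cost, with
a one-cycle disutility), post-progression care (a mix of subsequent
active treatment and best supportive care), and one-off end-of-life cost
on each cycle's new deaths. Recurring costs in the truncated final cycle
are prorated.

## Evidence chain

1. **Digitized curves → pseudo-IPD.** The reconstruction assigns, within
   each number-at-risk interval, event and censoring counts consistent
   with the digitized survival drops and the next at-risk count, then
   places them at the digitized time grid (with a half-grid-step shift).
   An integer-search over per-interval censoring allocations minimizes
   the discrepancy; a validation report records the maximum absolute gap
   between the digitized coordinates and a KM refit of the pseudo-records
   (tolerance 0.02).
2. **Fitting.** All likelihoods, survival functions, and the
   restricted-cubic-spline basis (natural cubic splines in `ln t`, knots
   at quantiles of log uncensored event times) are hand-written;
   optimization is BFGS with a Nelder–Mead fallback and overflow-guarded
   objectives. Zero interior knots reproduce Weibull (hazard scale) and
   log-logistic (odds scale) exactly — verified to 1e-4 in log-likelihood
   by the acceptance suite. Spline fits whose survival is non-monotone on
   the horizon are rejected. Wald confidence intervals use the inverse
   Hessian on the unconstrained scale.
3. **Selection.** Default `model_selection="common"`: among model labels
   available for all four arm/endpoint fits, pick the label with the
   lowest summed AIC. Rationale: independently selected families can give
   the two directly-fitted arms qualitatively different tail behaviour,
   and since the PBC arm is anchored to the BC curve, a common family
   keeps all three extrapolations structurally comparable.
   `model_selection="independent"` and an explicit `model_override`
   remain available.
4. **Anchoring.** PBC curves are `S_BC^HR` with HR(OS) = 0.63 and
   HR(PFS) = 0.61; in probabilistic analysis the HRs are drawn lognormal
   with σ from their tabulated 95% ranges.

## Parameters

The bundled table (2024 USD) carries, per parameter: base-case mean, SD,
low/high range for one-way sensitivity analysis (±20% of the mean when no
range is tabulated), and the sampling family — gamma for costs, beta for
probabilities/proportions/utilities, lognormal for hazard ratios, fixed
otherwise. Method-of-moments matching: gamma `shape = (m/sd)²`,
`scale = sd²/m`; beta `ν = m(1−m)/sd² − 1`; lognormal `μ = ln(m)` with
`σ = (ln hi − ln lo)/3.92`. Note the lognormal therefore parameterizes
the tabulated value as the **median** (geometric mean) of the draws; the
calibration checks in the test suite compare the geometric mean of
hazard-ratio draws and arithmetic means elsewhere.

## Synthetic generator

Each simulated arm draws latent Weibull death and progression times
(optionally coupled by a shared gamma frailty; the bundled fixture uses
independence), takes PFS as their minimum, censors by
`min(accrual-driven administrative follow-up, exponential drop-out)`, and
renders the KM estimate as digitized monthly coordinates with a quarterly
at-risk table — the same evidence shape the pipeline consumes. The
bundled fixture truth (BC death Weibull(2.0, 2.8), progression
Weibull(2.0, 1.15); ABC death Weibull(2.0, 3.2), progression
Weibull(2.0, 1.35); n = 230/arm, 1.5-year accrual, 4-year minimum
follow-up, 5%/year drop-out) was calibrated *to the generator's design
goals*: roughly 20% censoring on overall survival, control-arm
extrapolated life-years near 2.5, and incremental cost-effectiveness for
the checkpoint-inhibitor arms well above common US thresholds — i.e. the
same qualitative regime as the published analysis this model family
addresses. No claim of clinical fidelity is made; the PBC arm is never
simulated but derived through the anchoring hazard ratios, mirroring the
indirect comparison.

## Numerical choices

- Extrapolated per-cycle curves are clipped to [0, 1], forced to start at
  1, and made non-increasing by a running minimum.
- State occupancy tolerates digitization noise: PFS above OS is clamped
  to OS with a warning (this occurs when sensitivity bounds push the
  anchored PFS above OS).
- Optimizer objectives return a large finite penalty on
  overflow/invalid-parameter evaluations rather than propagating
  non-finite values into the line search.
- All stochastic steps take explicit seeds; the pipeline, PSA and
  generator are bit-reproducible at a fixed seed.

## Limitations

- Fixed-curves PSA: survival-curve parameter uncertainty is not resampled
  (only the PBC hazard ratios vary); the published input inventory this
  mirrors does likewise, but it understates decision uncertainty.
- Linear per-mg pricing ignores vial wastage.
- The SAE burden is a one-off at model entry rather than a time-resolved
  process.
- The anchored comparison inherits proportional-hazards and
  trial-comparability assumptions; no population adjustment is applied.
- Independent parameter draws in PSA (no correlation structure).
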