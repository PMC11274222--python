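# Methods

## The measurement being modelled

A stable chromogenic radical in solution (DPPH·, monitored at 517 nm, or
galvinoxyl, 428 nm) is mixed with an aliquot of a plant-extract dilution and
its absorbance is recorded for 1000 s at 1 s intervals. Antioxidants donate
hydrogen atoms to the radical (AH + r → P), so the absorbance decays from
the initial value of the pure radical solution (1.1219 AU for DPPH, 1.1720
AU for galvinoxyl in this assay's configuration) towards a plateau set by
whichever reactant runs out first. Radical survival is reported as
R% = 100·A(t)/A₀; values slightly above 100% are legal early-point noise
and are deliberately not clamped.

## Kinetic laws

**Parallel first-order, orders 1–3.** `y(t) = y0 + Σ Ar(i)·exp(−t/tᵢ)`.
Each term is an independent pseudo-first-order quenching channel (the
antioxidant is assumed in effective excess for that channel); `1/tᵢ` are the
per-channel rate constants [s⁻¹] and `y0` the absorbance remaining at
infinite time. The two- and three-component forms are the conventional way
multi-component extracts are handled when each constituent reacts on its own
time scale.

**Second-order.** A single bimolecular step consumes radical and
antioxidant together: `dAr/dt = dA_AH/dt = −k·Ar·A_AH`. Integrating with
unequal initial conditions `Ar(0) ≠ A_AH(0)` gives

    Ar(t) = Ar(0)·d·E / (A_AH(0) − Ar(0)·E),   d = A_AH(0) − Ar(0),
    E = exp(−k·t·d),

with the limits `Ar(0)` at t = 0 and `max(0, Ar(0) − A_AH(0))` at t → ∞.
The implementation switches to the equal-concentration form
`Ar(0)/(1 + k·t·Ar(0))` when `|d| ≤ 1e−9·max(Ar(0), A_AH(0))`; the
threshold sits far below any fit-parameter uncertainty while preventing
catastrophic cancellation, and continuity across the switch is tested
(≤ 1e−4·Ar(0) at a relative offset of 1e−6). For radical excess the
expression is algebraically rearranged so the exponent is always
non-positive (no overflow). The antioxidant trajectory follows from
conservation, `A_AH(t) = A_AH(0) − (Ar(0) − Ar(t))/n`, with stoichiometric
factor n defaulting to 1 (n > 1 is observed for polyphenols reacting with
galvinoxyl and is exposed as an argument).

Units: the model is fitted on absorbance, so `k` is 1/(AU·s) and `A_AH(0)`
is an absorbance-equivalent. Mapping onto a concentration scale goes
through the empirical calibration line (`y = 8.6885x + 0.0315` for DPPH,
`y = 18.465x + 0.0471` for galvinoxyl, x in the opaque unit of the standard
series); the package stores and inverts these lines but never invents
units for x.

**ODE oracle.** `integrate_so` integrates the rate equations with DOP853 at
rtol = 1e−12 and atol = 1e−300. The essentially-zero absolute tolerance
gives pure relative error control, which is what lets the closed form be
verified to ≤ 1e−6 relative even where the trace decays through dozens of
orders of magnitude (k = 0.1, twofold antioxidant excess, t = 1000 s). The
oracle is used only in tests and in the acceptance script — never as the
fitting model.

## Fitting and model comparison

Parameters are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, `x_scale="jac"`,
`max_nfev = 5000`). Bounds: amplitudes and `y0` non-negative, time
constants ≥ 1e−6 s, all second-order parameters > 0 — absorbances are
physically non-negative and the bounds stabilise multi-exponential fits.
Fitted multi-exponential components are canonicalised fastest-first so that
label permutations of the starting values cannot change the reported
parameters.

Starting values are data-driven: offset at the trace minimum, total
amplitude at (first point − offset) split equally, time constants
log-spaced over [span/100, span]; for the second-order law `Ar(0)` starts
at the first point, `A_AH(0)` at 1.5·`Ar(0)`, and `k` at the initial-slope
estimate floored at 1e−6. Two safeguards matter in practice:

* **Warm-started nesting.** A higher-order multi-exponential fit is also
  started from the fitted next-lower order plus a zero-amplitude component.
  Trust-region steps never increase the cost from the starting point, so
  adding a component can never worsen the residual sum of squares — the
  nested-dominance property holds by construction instead of by luck with
  local minima.
* **Seeded restarts.** If the first attempt fails to converge, up to five
  log-normally perturbed restarts are tried (deterministic given the seed);
  the lowest residual sum of squares wins. A still-stalled optimiser is
  reported as `converged=False`, never as an exception.

Goodness of fit: R² = 1 − RSS/TSS (TSS about the trace mean), clipped to
[0, 1]; a zero-variance trace reports R² = 0 and p = 1 by convention. The
significance of a fit is the overall-regression F statistic
`[(TSS−RSS)/(p−1)] / [RSS/(n−p)]` with p the parameter count, reported as
its upper-tail probability — the probability that the true R² is zero.
At the assay's n = 1001 any fit with R² ≥ 0.9 has p < 1e−5, which the test
suite asserts as a property.

Selection in `fit_all`: within the nested multi-exponential family a higher
order must improve R² by more than δ = 0.001 (this encodes "a third
component does not improve the fit" as a testable rule); the surviving
multi-exponential representative then competes with the second-order fit on
plain R², ties going to the model with fewer parameters. Non-converged fits
never win.

`estimate_antioxidant_level` returns the fitted `A_AH(0)` and the
antioxidant trajectory on the trace grid. In multicomponent extracts this
is a pooled estimate of the collective antioxidant amount, not a
per-compound value.

## Synthetic data: what it emulates, what it does not

The generator evaluates a known ground-truth law on the assay grid
(1000 s, 1 s steps) and adds homoscedastic Gaussian noise, σ defaulting to
0.005 AU — a typical UV–Vis repeatability figure, configurable because the
real instrument noise for this assay is unknown. The default study layout
is the assay's full factorial: flower/fruit × four dilution levels
(1.0–2.5 × 10⁻³ g/mL) × DPPH/galvinoxyl, sample acronyms `KDPPH1.0` …
`OGL2.5`. Ground-truth rules encode the assay's qualitative structure as
simulator defaults:

* `Ar(0)` is the radical's assay constant (1.1219 / 1.1720 AU);
* `A_AH(0) = c·level` with c = 0.35 AU per 10⁻³ g/mL for flower and 0.30
  for fruit — proportionality is the simplest rule consistent with the
  observed dose ordering, and the coefficients put terminal radical
  survival in the observed 20–50% band;
* rate constants k = 0.01/0.001 (flower/fruit, DPPH) and 0.03/3e−5
  (flower/fruit, galvinoxyl) AU⁻¹s⁻¹, i.e. flower faster than fruit by one
  (DPPH) and three (galvinoxyl) orders of magnitude, galvinoxyl faster than
  DPPH within flowers and slower within fruits.

Not emulated: baseline drift, photobleaching, heteroscedastic or correlated
noise, mixed multi-antioxidant second-order kinetics, and any
concentration-dependence of k. Passing recovery tests therefore shows the
estimator works under additive Gaussian noise on a correctly specified
model — not that real infusion traces are free of model error. The fruit ×
galvinoxyl cells decay only ~0.03 AU in 1000 s at the default parameters;
at σ = 0.005 they are genuinely weakly identified, which is why recovery
scoring reports NaN rows (excluded from medians) for non-converged fits
rather than failing.

## Problem sizes and determinism

Test and acceptance runs use: a 28-combination oracle sweep × 1001 points;
100 seeded replicates for second-order recovery; 20 for two-exponential
selection; one 16-cell study for nested dominance and determinism. These
sizes give stable medians (repeat runs at different base seeds move the
medians by well under the margin to their thresholds) while keeping a full
run in tens of seconds. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; per-cell seeds are derived
arithmetically from the base seed, so identical configs produce
byte-identical traces, fits and reports. Report JSON carries a provenance
block (config hash, seed, package version) and no timestamps.

## Known limitations

* The empirical calibration x-unit is opaque; converting k or `A_AH(0)` to
  molar units is left to the caller and no Beer–Lambert physics is applied.
* Uncertainty is linearised (Jacobian-based standard errors only); no
  bootstrap or Bayesian intervals, and model comparison uses R² only (no
  AIC/BIC), matching the assay's own workflow.
* Above three exponential components, and for kinetics beyond the single
  bimolecular step (e.g. concentration-dependent k at extreme dilutions),
  the package deliberately offers no model.
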