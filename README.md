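# radkin

Kinetic analysis of radical-quenching absorbance traces from antioxidant
assays.

Spectrophotometric antioxidant assays follow the decay of a stable coloured
radical — DPPH· (517 nm) or galvinoxyl (428 nm) — as antioxidants in a plant
extract quench it. The absorbance–time trace A(t), typically recorded for
1000 s at 1 s intervals, encodes both *how fast* the quenching proceeds and
*how much* antioxidant the sample contains. `radkin` fits such traces with
two families of kinetic laws, compares them, and turns the winning fit into
rate constants and an estimated antioxidant level.

**Who it is for:** phytochemists and physical chemists running DPPH·/Glv·
decay-kinetics assays who want reproducible, scriptable curve fitting with a
parameter-recovery benchmark instead of spreadsheet fits.

## Models

**Parallel first-order (FO1/FO2/FO3)** — one to three independent
pseudo-first-order quenching channels:

```
y(t) = y0 + Σᵢ Ar(i) · exp(−t/tᵢ),     i = 1..order,  rate constants 1/tᵢ [s⁻¹]
```

**Second-order (SO)** — a single bimolecular step AH + r → P in which both
the radical absorbance Ar and the antioxidant pool A_AH are consumed,
dAr/dt = −k·Ar·A_AH. For unequal initial levels the integrated law is

```
Ar(t) = Ar(0)·(A_AH(0) − Ar(0))·e^(−kt(A_AH(0)−Ar(0))) / (A_AH(0) − Ar(0)·e^(−kt(A_AH(0)−Ar(0))))
```

collapsing to `Ar(0)/(1 + k·t·Ar(0))` when the initial levels coincide. The
fitted `A_AH(0)` is the initial antioxidant level in absorbance-equivalent
units — in multicomponent extracts a pooled, collective estimate. `k` is in
1/(AU·s); an empirical calibration line (`y = slope·x + intercept`) can map
absorbance onto a concentration scale.

Model comparison fits all four laws by bounded nonlinear least squares and
selects the highest R², with a parsimony guard: a higher-order
multi-exponential model wins over a lower one only if it improves R² by
more than 0.001. Fit significance is reported as the overall-regression
F-test p-value (the probability that the true R² is zero).

Because real assay traces for this design were never deposited, the package
ships a first-class synthetic-data module: seeded traces with known ground
truth on the assay grid, plus the full 2 sources × 4 dilutions × 2 radicals
study layout, so every stage is testable by parameter recovery.

## Worked example

```python
from radkin import (SimulationConfig, SOParams, simulate_trace, fit_all,
                    estimate_antioxidant_level)

truth = SOParams(k=0.01, ar0=1.1219, aah0=1.7)   # ground truth
trace = simulate_trace(SimulationConfig("SO", truth, noise_sigma=0.005, seed=42))
comp = fit_all(trace)                             # FO1, FO2, FO3, SO
fit = comp.best
print("selected model:", comp.selected)
print(f"k = {fit.params.k:.5f}, Ar0 = {fit.params.ar0:.4f}, "
      f"AAH0 = {fit.params.aah0:.4f}, R^2 = {fit.r_squared:.5f}")
aah0, traj = estimate_antioxidant_level(fit, trace.times)
print(f"antioxidant left at 1000 s = {traj[-1]:.4f} AU")
```

prints

```
selected model: SO
k = 0.00999, Ar0 = 1.1219, AAH0 = 1.7020, R^2 = 0.99937
antioxidant left at 1000 s = 0.5813 AU
```

The second-order law is correctly selected over all multi-exponential
competitors, the rate constant and both initial levels are recovered to
well under 1% despite the 0.005 AU instrument noise, and the antioxidant
trajectory shows the expected surplus (1.7 − 1.1219 ≈ 0.58 AU) surviving
once the radical is exhausted.

The same workflow is available from a shell:

```sh
radkin simulate --seed 1 --out-dir traces/          # 16-cell study + manifest
radkin fit --in-dir traces/ --out-dir report/       # fits + model comparison
radkin recover --report report/report.json \
               --manifest traces/manifest.json --out errors.csv
radkin report --report report/report.json           # text summary table
```

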