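# replidyn

Analysis of single-cell replicative-aging trajectories in budding yeast:
why nuclear proteasome concentration falls faster than cytoplasmic, which
markers predict an individual mother cell's lifespan, which of two markers
temporally precedes the other, and how to quantify nuclear vs. cytoplasmic
reporter intensity from microscopy z-stacks.

The package is for quantitative biologists working with mother-cell
time-lapse data (microfluidic trapping, one frame every ~20 min over ~72 h,
replicative lifespan = number of divisions before arrest). Every analysis
is driven end-to-end by a synthetic-cohort generator with known ground
truth, so the whole pipeline is testable without any imaging data.

## The model at the core

Nuclear reporter concentration `I_n` in a growing nucleus obeys, per frame,

    ΔI_n = C1 · I_c · Δt / √s_n  −  I_n · ( (3/2) · Δs_n/s_n + γ · Δt )

where `I_c` is cytoplasmic concentration, `s_n` nuclear area, `C1` the
transport efficiency per unit area and `γ` the degradation rate. Import
scales with the nuclear surface (∝ R²) while dilution and degradation
scale with volume (∝ R³): for an isometrically scaling sphere
v ∝ S^(3/2), so relative volume dilution is 3/2 of the relative area
change and the effective input falls as 1/√s_n. Consequence: as the
nucleus enlarges with age, transport cannot keep up and nuclear
concentration declines even at constant cytoplasmic concentration —
faster in short-lived cells, whose nuclear size accelerates earlier.

Around the model sit the other pipeline stages:

* **markers** — frame-by-frame Pearson correlation between a marker and
  the lifespan of still-dividing cells; short/long-lived group
  trajectories; nucleus/cell size-ratio dynamics; area-linearity QC;
  morphology-state fractions.
* **granger** — nonlinear Granger causality between two markers: decision
  trees (depth ⌊√n⌋) for restricted vs. full models, cross-fitted
  residuals, one-sided F-tests, a signed −log10 p matrix with rolling-max /
  2-sd-threshold / Gaussian post-processing.
* **gmmloc** — z-stack background subtraction, slice summation, σ = 3.5
  smoothing, two-component Gaussian-mixture intensity cutoff, region
  statistics and cross-marker validation.
* **simulate** — the synthetic generator: cohorts, induction pairs,
  lag-coupled marker pairs, two-channel z-stacks with pixel-exact masks.

## Worked example

```python
import numpy as np
from replidyn import SynthParams, TransportModel
from replidyn.simulate import gen_cohort
from replidyn import markers, transport

# a default synthetic cohort: 300 mother cells, 20-min frames, 72 h
cohort, truth = gen_cohort(SynthParams(seed=1))
rls = cohort.rls_values()
print(f"short-lived mean RLS {rls[rls < 15].mean():.2f}, "
      f"long-lived {rls[rls >= 15].mean():.2f}")

# lifespan-marker screen: nuclear intensity vs RLS over dividing cells
screen = markers.correlation_series(cohort, "i_nuc", log10_transform=True)
frame, r, p = screen.peak
print(f"peak r = {r:.2f} at {cohort.grid.t_hours(frame):.1f} h "
      f"(p = {p:.2e}, n = {screen.n_dividing[frame]})")

# recover the generating transport parameters from the group dynamics
fit = transport.fit_cohort(cohort)
print(f"fitted C1 = {fit.params.c1:.1f} (truth 30), "
      f"gamma = {fit.params.gamma:.4f} (truth 0.05)")
```

Output:

```
short-lived mean RLS 9.05, long-lived 20.15
peak r = 0.60 at 16.0 h (p = 3.44e-23, n = 225)
fitted C1 = 28.6 (truth 30), gamma = 0.0473 (truth 0.05)
```

The screen finds the planted mid-life peak: cells with higher nuclear
reporter concentration at mid-life live longer, because the generator
couples late-life nuclear enlargement (and hence dilution) to short
lifespan. The fit recovers the generating parameters from noisy data.

A command-line interface runs the same stages on files:

```
replidyn --seed 1 --out-dir results all
```

writes the cohort table, transport-fit report, marker screens, Granger
matrices and segmentation statistics, plus a `run_log.yaml` of every
parameter used. See `docs/methods.md` for the model assumptions, generator
calibration and numerical choices.

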