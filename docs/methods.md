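# Methods

`replidyn` re-implements, as a tested library, a quantitative analysis of
single-mother-cell aging trajectories in budding yeast: a nuclear-transport
dilution model for nuclear reporter concentration, a lifespan-marker
correlation screen, a nonlinear Granger-causality temporal-ordering
procedure, and GMM-based subcellular intensity quantification. All stages
are exercised against a synthetic-cohort generator that plants known
structure, so every claim a test makes is checked against ground truth.

## The transport model

Nuclear concentration `I_n` of a protein imported from the cytoplasm obeys,
per imaging frame,

    ΔI_n = C1 · I_c · Δt / s_n^α − I_n · ( (3/2) · Δs_n / s_n + γ · Δt )

with cytoplasmic concentration `I_c`, nuclear area `s_n`, transport
efficiency per unit area `C1` (a.u.·area^α/frame), and degradation rate `γ`
(1/frame). Both geometric factors follow from a spherical nucleus scaled
isometrically: volume grows as surface^(3/2), so relative volume dilution is
3/2 of the relative area change, and import per unit volume carries
`s_n^(−α)`.

* **α (input exponent).** Exact sphere closure gives S/v ∝ S^(−1/2), i.e.
  α = 1/2, which is the default; α = 1 is retained as a configuration
  option because the distinction is a modelling choice once all sphere
  constants are absorbed into `C1`. Every qualitative property holds for
  either.
* **Projected area as `s_n`.** Measured 2-D nuclear area enters directly;
  proportionality constants between projected area and surface area are
  absorbed into the fitted `C1`, so only relative changes matter.
* **Time unit.** One model step is one imaging frame (20 min by default);
  `γ = 0.05/frame` therefore means a ~7 h degradation time constant.
* **Clipping.** The explicit difference equation can overshoot below zero
  for coarse steps; negative predictions are clipped at zero and flagged.

The model's central prediction: because import scales with R² while
dilution and degradation scale with R³, nuclear concentration falls as the
nucleus grows even at constant cytoplasmic concentration. Short-lived
cells, whose nuclear size accelerates earlier and harder, therefore show a
faster nuclear decline under identical (C1, γ) — the group-dynamics
property the tests verify.

### Fitting

`transport.fit` (single series) minimises the mean squared error between
the forward simulation (seeded at the first observed value) and an observed
nuclear-intensity series, via a log-spaced coarse grid (≥ 20×20 over the
bounds box; ties broken toward smaller parameters) followed by Nelder–Mead
refinement in log-parameter space. With `freeze={"gamma": value}` only `C1`
is fitted — the single-parameter refit mode used to compare induction
against control.

`transport.fit_cohort` (cohort level) targets the per-frame mean nuclear
intensity of the short-lived and long-lived groups over still-dividing
cells, truncated where fewer than 25 cells remain. Three choices matter and
are deliberate:

1. **Ensemble prediction.** The model's counterpart of each observed group
   mean is the average of *per-cell* forward simulations over exactly the
   same survivor sets. The composition of a still-dividing mean drifts as
   short-lived cells arrest; averaging model predictions over the same sets
   makes that drift identical on both sides of the objective, so it cancels
   instead of biasing the parameters (fitting a single simulation on
   averaged inputs biases both parameters low by ~13% on default cohorts).
2. **Joint group fitting.** A single quasi-steady mean curve constrains
   only the ratio `C1/γ`; the short-vs-long contrast in nuclear-size
   dynamics pins the overall rate scale. Both group curves share one
   parameter set.
3. **Input smoothing.** Nuclear-area series enter through `Δs/s`, which
   amplifies frame-to-frame measurement noise (an errors-in-variables
   problem). Each cell's area series is smoothed with a cubic spline whose
   smoothing level comes from that series' own second-difference noise
   estimate; noiseless inputs pass through untouched, so the estimator
   remains exact on clean data.

On default synthetic cohorts (300 cells, 5% multiplicative intensity noise)
this recovers the generating `C1 = 30`, `γ = 0.05` within 10% relative
error on every seed tried (40 seeds; typical error 2–4%).

Identifiability caveat: a series that starts at quasi-steady state and
moves slowly constrains `C1/γ` strongly but `γ` weakly. Informative data —
an import transient, or late-life size acceleration — are needed to pin
both; the tests construct their single-series fixtures accordingly.

## Synthetic cohorts

The generator emulates the study design the analyses assume: 20-min frames
over 72 h, single mother cells tracked to division arrest.

| Parameter | Default | Meaning |
|---|---|---|
| `n_cells` | 300 | cohort size |
| `area_slope` | 2 area/frame | shared linear cell-area growth |
| `area_intercept_mean/sd` | 300 / 30 | initial cell area across cells |
| `nuc_ratio` | 0.15 | early-life nucleus/cell area ratio |
| `t_bend` | frame 30 (~10 h) | onset of late-life nuclear acceleration |
| `accel_delta0`, `accel_rls_ref`, `accel_cap` | 0.3, 15, 1.2 | per-cell end-of-life ratio increase `min(cap, δ0·(ref/rls)²)` |
| `transport` | C1 = 30, γ = 0.05 | generating transport parameters |
| `i_cyt_baseline_mean/sd` | 100 / 10 | cytoplasmic plateau |
| `ar_phi`, `ar_sd` | 0.9, 4 | AR(1) cytoplasmic fluctuations |
| `noise_cv_*` | 2–5% | multiplicative measurement noise per channel |
| `rls_nb_size`, `rls_nb_mean` | 5.75, 13.5 | negative-binomial lifespan law |
| `cycle_base_frames`, `cycle_lengthening` | 5, 0.02 | inter-division interval and its ageing drift |

Construction order matters: nuclear intensity is forward-simulated from the
*noiseless* size and cytoplasm series and only then corrupted with
measurement noise, so the generating `(C1, γ)` remain the recoverable
ground truth. Nuclear acceleration is quadratic past the bend
(`nuc = ρ·cell·(1 + β·(t − t_bend)²)`), the minimal smooth accelerating
form; `β` is set per cell so the nucleus/cell ratio has risen by
`min(1.2, 0.3·(15/rls)²)` at arrest — strongly for short-lived cells,
weakly for long-lived ones, the coupling that plants a positive mid-life
correlation between nuclear intensity and lifespan and a negative one for
nuclear area.

The lifespan law is negative-binomial (size 5.75, mean 13.5, floor 1),
calibrated once so the short (< 15 divisions) and long (≥ 15) groups have
mean RLS ≈ 9.2 and ≈ 20.2 after grid censoring. The split is ~60/40 rather
than 50/50; the subgroup means, which the analyses condition on, are the
calibrated quantities. Divisions are placed by a cycle model whose interval
lengthens 2% per completed division; trajectories truncate at the last
division (the arrest frame), and "still dividing at frame t" means
`arrest_frame ≥ t` (the boundary is a convention; the inclusive choice
keeps a cell in its final productive frame).

Morphology labels (optional) follow a sticky Markov chain (persistence
0.85) whose target occupancy gives the circular state a U-shaped time
course; the chain's marginals are analytically propagatable, which the
tests use as an oracle.

What the generator does *not* emulate: absolute intensity units,
segmentation artefacts, focus drift, cross-channel bleed-through, or any
correlation between cytoplasmic expression level and lifespan. Passing
tests therefore demonstrate that the analysis machinery recovers planted
structure of the assumed form at realistic noise levels — not that real
movies satisfy those assumptions.

### Induction cohorts

Induced and control cohorts are built from identical random draws; after
the induction frame the cytoplasmic series ramps linearly (3 frames) to a
fold-change, optionally the transport efficiency switches to a
post-induction value, and optionally nuclear-area growth is boosted. With a
2.5× cytoplasmic step-up and 2× nuclear-growth boost, the simulated
nuclear fold-change stays below half the cytoplasmic one: the nuclear
response is rate-limited by `γ` (~7 h time constant) and further damped by
growing nuclear size.

### Coupled marker pairs

For the Granger procedure, marker X is a smooth per-cell AR(1) latent
(autocorrelation 0.95) and marker Y echoes `link(X(t − lag))` plus noise;
the default link is a centred quadratic, which has near-zero linear
correlation with X — precisely the dependence a linear Granger test misses
and a tree-based one must catch. Uncoupled pairs pass an independent latent
through the same link, matching marginal moments.

## Marker screens

At each frame, the screen correlates a channel value with RLS over the
cells still dividing at that frame (two-sided Pearson test). Intensity
channels are log10-transformed by default, areas are not. Frames with fewer
than 25 dividing cells are excluded from peak selection, and the peak is
the maximum of −log10 p (ties to the earlier frame). No across-frame
multiple-testing correction is applied — the per-frame screen is
descriptive, and consumers should treat the p-values as raw.

A note on the control-channel bound in the acceptance checks: with n cells
the null sampling sd of r is ≈ 1/√n, so an |r| < 0.15 bound is a property
of independence only while essentially the whole cohort is dividing
(n ≈ 300 → sd ≈ 0.06); the checks therefore evaluate it over frames
retaining ≥ 90% of cells.

Group trajectories split at RLS 15, optionally normalise each cell by its
lifetime maximum, average over still-dividing cells, and truncate below 25
cells. The QC filter keeps cells whose area-vs-time Pearson r exceeds 0.7
(constant-area cells are rejected as zero-variance). The
nucleus-to-cell-area ratio always uses un-normalised sizes.

## Granger temporal ordering

Both markers are first scale-equalised by dividing the cells × frames
matrix by its leading singular value (missing entries are filled with
column means for the decomposition only), then each cell's still-dividing
stretch is mapped to [0, 1]; a zero-range cell maps to 0.5 and is reported.
The singular-value reading of "SVD normalisation" is the minimal one that
equalises scale and is invariance-testable; rank-k reconstruction would
discard signal and is not what a scale-equalisation step needs.

For each ordered frame pair (t1 < t2) with at least 56 cells dividing at
both frames: a restricted tree regressor predicts the target marker at t2
from its own value at t1, and a full tree adds the predictor marker at t1.
Both trees use the squared-error (Friedman) split criterion and maximum
depth `max(1, ⌊√n⌋)`. Residuals are computed **out-of-sample** by 5-fold
cross-fitting with one shared fold assignment: at depth ⌊√n⌋ either model
can memorise the sample, so in-sample residual variances both collapse
toward zero and their ratio is meaningless; held-out residuals measure
predictive value, make the null slightly conservative (the full model pays
for its useless extra feature), and preserve power. The one-sided F-test
`F = var(restricted)/var(full)` with (n−1, n−1) degrees of freedom gives
the p-value; the matrix stores `sign(log F) · (−log10 p)`. The "sign of the
F statistic" is read as the direction of improvement, since F itself is
always positive.

Post-processing follows the stated recipe: 2×2 rolling maximum (excluded
pairs ignored), zeroing of magnitudes below 2× the standard deviation of
the strictly positive entries (population sd — a single positive entry has
sd 0 and survives), then Gaussian smoothing with σ = 1.2 (excluded entries
enter the convolution as 0 and are re-masked).

Single-lag predictors are used (one past frame); the `frame_step` and
`max_horizon` options thin the tested grid so large designs stay tractable.
Measured operating characteristics on 200-cell, 40-frame synthetic pairs:
≤ ~5% of null entries exceed the α = 0.05 cutoff; quadratic coupling at lag
5 is detected on its band in ≈ 100% of replicates and the reverse direction
is weaker in ≈ 100%.

## GMM subcellular quantification

Per z-slice, the median of pixels outside the cell/well occupancy is
subtracted (negatives clipped, clip fraction reported); slices are then
summed — summation rather than max/mean preserves total intensity, which
the per-area quantification divides by region area. The summed image is
smoothed (σ = 3.5) and a two-component Gaussian mixture (≥ 5 restarts,
fixed seed) is fitted to the in-cell smoothed intensities.

Two decisions depart from the most literal reading and are backed by
measurement on ground-truth stacks:

* **Cutoff rule.** The default cutoff is the midpoint of the two component
  means. The posterior-crossing alternative (kept as an option) is dragged
  far below the edge level whenever the smoothing ramp around the bright
  compartment inflates the high component's variance, costing ~0.15 Dice.
* **Classification target.** The mixture is fitted on smoothed values (the
  smoothing accentuates the modes), but the cutoff is applied to the raw
  aggregated image. Thresholding the smoothed image labels the ~2σ ramp
  ring as nuclear, inflating nuclear area by ~15–20% and biasing per-area
  intensity ~11% low; classifying raw pixels removes the halo (Dice ≈ 0.99
  at high contrast, ≥ 0.92 at 5-sd separation). The smoothed-classification
  variant remains available for very low-contrast images.

Region statistics (mean, total, area, total/area) are computed on the
unsmoothed background-subtracted image. When a single nuclear region is
requested, the largest connected high-intensity component is taken; the
full multi-region output is retained. Cross-marker validation segments a
second, nuclear-only channel by half-maximum thresholding and reports
per-cell Dice and the across-cell Pearson correlation of the two
nuclear-area estimates.

Synthetic stacks are sized for an aged mother cell imaged at 63× (~0.1
µm/px): 128×128 px, cell radius 42 px, nucleus radius 18 px, 17 slices with
a Gaussian axial profile. The σ = 3.5 classification blur makes very small
nuclei unreachable at Dice ≥ 0.9 under any threshold, so the geometry
matters and is stated here as the study condition.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script studies use: 300-cell default cohorts
(20 and 10 seeds respectively for parameter recovery); 200-cell, 40-frame
coupled pairs with an 8-frame test horizon (50 power replicates, 8 null
replicates); 6 stacks for the 5-sd segmentation check and 30 for
cross-channel validation. These sizes give stable pass/fail behaviour for
every reported quantity while a full run stays in the minutes range.

## Known limitations

* The generator's couplings are the assumed forms (linear growth, quadratic
  acceleration, AR(1) fluctuations); none of the analyses is validated
  against misspecified dynamics beyond the noise models stated.
* The Granger procedure reports temporal predictiveness, not causal
  identification; directionality on synthetic pairs reflects the planted
  asymmetry.
* Absolute fitted `C1` values are unit-dependent (intensity × area scale);
  only ratios and orderings are meaningful across datasets.
* The per-frame screen's p-values are raw; any confirmatory use needs
  multiplicity control.
* 2-D projected areas stand in for 3-D geometry throughout, consistent
  with the model's absorption of shape constants into `C1`.
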