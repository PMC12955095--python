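"""Synthetic single-mother-cell cohorts with planted, recoverable structure.

The generator emulates the statistical structure of single-cell aging
time-lapse data (20-min frames over 72 h) so that every downstream analysis
has ground truth:

* cell area grows linearly with a slope shared across cells;
* nuclear area is isometric with cell area early in life (fixed ratio ρ) and
  accelerates quadratically past a bend point, more strongly in short-lived
  cells (per-cell curvature decreasing in lifespan) — isometric size scaling
  breaks down late in life;
* cytoplasmic reporter intensity is a per-cell plateau with AR(1)
  fluctuations;
* nuclear reporter intensity is the forward simulation of the
  nuclear-transport difference equation on the *noiseless* size and
  cytoplasm series, so the generating (C1, γ) remain recoverable; only then
  is multiplicative measurement noise applied;
* divisions follow a cell-cycle model (baseline inter-division interval with
  late-life lengthening) until the drawn replicative lifespan is exhausted;
  trajectories are truncated at arrest;
* lifespans are negative-binomial, calibrated so the RLS < 15 / >= 15 split
  gives subgroup means near 9 and 20;
* optional per-frame morphology labels follow a sticky Markov chain whose
  target occupancy gives the circular state a U-shaped time course.

These couplings plant a positive mid-life correlation between nuclear
intensity and lifespan and a negative one between nuclear area and lifespan.

Induction cohorts share all pre-induction randomness with their control;
after the induction frame the cytoplasmic intensity ramps to a fold-change,
the transport efficiency may switch, and nuclear-area growth may be boosted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cohort import STATE_LABELS, CellTrajectory, Cohort, TimeGrid
from .exceptions import ConfigError, ValidationError
from .gmmloc import ImageStack
from .transport import TransportParams, simulate as transport_simulate, steady_state

__all__ = [
    "SynthParams",
    "InductionSpec",
    "ImageSpec",
    "SyntheticStack",
    "gen_cohort",
    "gen_induction_cohort",
    "gen_coupled_pair",
    "gen_image_stack",
    "state_targets",
]


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters (defaults are the study conditions emulated).

    Lifespan acceleration: each cell's nuclear-area curvature is set so that
    by arrest the nucleus/cell ratio has risen by
    ``min(accel_cap, accel_delta0 * (accel_rls_ref / rls)**2)`` — strongly
    for short-lived cells, weakly for long-lived ones.
    """

    n_cells: int = 300
    grid: TimeGrid = field(default_factory=TimeGrid)
    area_slope: float = 2.0  # area units / frame, shared across cells
    area_intercept_mean: float = 300.0
    area_intercept_sd: float = 30.0
    nuc_ratio: float = 0.15  # nuclear/cell area early in life (ρ)
    t_bend: int = 30  # frame where late-life acceleration can begin (~10 h)
    accel_delta0: float = 0.3
    accel_rls_ref: float = 15.0
    accel_cap: float = 1.2
    transport: TransportParams = field(default_factory=TransportParams)
    i_cyt_baseline_mean: float = 100.0
    i_cyt_baseline_sd: float = 10.0
    ar_phi: float = 0.9  # AR(1) autocorrelation of cytoplasmic fluctuations
    ar_sd: float = 4.0  # stationary sd of those fluctuations
    noise_cv_cell_area: float = 0.02
    noise_cv_nuc_area: float = 0.03
    noise_cv_i_nuc: float = 0.05
    noise_cv_i_cyt: float = 0.02
    rls_nb_size: float = 5.75  # negative-binomial size; with the mean below,
    rls_nb_mean: float = 13.5  # the RLS<15 / >=15 split means ~9.2 / ~20.2
    cycle_base_frames: float = 5.0  # baseline inter-division interval
    cycle_lengthening: float = 0.02  # fractional lengthening per division
    state_persistence: float = 0.85  # sticky-chain probability of keeping state
    with_states: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_slope <= 0:
            raise ValidationError("area_slope must be > 0")
        if not (0 < self.nuc_ratio < 1):
            raise ValidationError("nuc_ratio must be in (0, 1)")
        if self.accel_delta0 < 0 or self.accel_cap < 0:
            raise ValidationError("acceleration parameters must be >= 0")
        for name in ("noise_cv_cell_area", "noise_cv_nuc_area",
                     "noise_cv_i_nuc", "noise_cv_i_cyt"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.ar_phi < 1):
            raise ValidationError("ar_phi must be in [0, 1)")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


@dataclass(frozen=True)
class InductionSpec:
    """Estradiol-style induction: cytoplasmic step-up at a chosen frame.

    ``cyt_fold`` is the multiplier the cytoplasmic intensity reaches after a
    linear ramp of ``ramp_frames``; ``c1_post`` optionally replaces the
    transport efficiency from the induction frame on; ``nuc_growth_boost``
    multiplies the nuclear-area growth rate after induction.
    """

    t_induce: int
    cyt_fold: float = 2.5
    c1_post: float | None = None
    nuc_growth_boost: float | None = None
    ramp_frames: int = 3

    def __post_init__(self) -> None:
        if self.cyt_fold <= 0:
            raise ValidationError("cyt_fold must be > 0")
        if self.t_induce < 0:
            raise ValidationError("t_induce must be >= 0")
        if self.ramp_frames < 1:
            raise ValidationError("ramp_frames must be >= 1")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _division_frames(rls_draw: int, p: SynthParams) -> np.ndarray:
    """Integer division frames from the cycle model, truncated to the grid."""
    j = np.arange(1, rls_draw + 1)
    intervals = p.cycle_base_frames * (1.0 + p.cycle_lengthening * (j - 1))
    times = np.cumsum(intervals)
    frames = np.round(times).astype(int)
    # enforce strictly increasing, at least one frame apart, starting >= 1
    for k in range(len(frames)):
        lo = 1 if k == 0 else frames[k - 1] + 1
        if frames[k] < lo:
            frames[k] = lo
    return frames[frames <= p.grid.n_frames - 1]


def _draw_cells(p: SynthParams, seed: int) -> list[dict]:
    """All per-cell randomness, drawn once (shared by induction pairs)."""
    rng = np.random.default_rng(seed)
    nb_p = p.rls_nb_size / (p.rls_nb_size + p.rls_nb_mean)
    n_frames = p.grid.n_frames
    draws = []
    for i in range(p.n_cells):
        draws.append(
            {
                "cell_id": f"cell{i:04d}",
                "rls_draw": max(1, int(rng.negative_binomial(p.rls_nb_size, nb_p))),
                "a0": rng.normal(p.area_intercept_mean, p.area_intercept_sd),
                "baseline": rng.normal(p.i_cyt_baseline_mean, p.i_cyt_baseline_sd),
                "ar_innov": rng.standard_normal(n_frames),
                "z_cell_area": rng.standard_normal(n_frames),
                "z_nuc_area": rng.standard_normal(n_frames),
                "z_i_nuc": rng.standard_normal(n_frames),
                "z_i_cyt": rng.standard_normal(n_frames),
                "state_u": rng.random(n_frames),
            }
        )
    return draws


def _mult_noise(x: np.ndarray, cv: float, z: np.ndarray) -> np.ndarray:
    """Multiplicative lognormal measurement noise with unit mean."""
    if cv == 0:
        return x.copy()
    return x * np.exp(cv * z - 0.5 * cv * cv)


def state_targets(u: np.ndarray) -> np.ndarray:
    """Target state occupancy π(t) over (circular, fragmented, aggregate,
    other) as a function of normalised time u in [0, 1].

    The circular fraction is U-shaped (high early, dips mid-life, recovers);
    the remaining mass is split 30/45/25 between fragmented, aggregate and
    other.
    """
    u = np.asarray(u, dtype=float)
    p_circ = 0.55 - 0.40 * 4.0 * u * (1.0 - u)
    rest = 1.0 - p_circ
    out = np.stack(
        [p_circ, 0.30 * rest, 0.45 * rest, 0.25 * rest], axis=-1
    )
    return out


def _sample_states(p: SynthParams, n_frames: int, u_draws: np.ndarray) -> np.ndarray:
    """Sticky Markov chain over the four morphology labels.

    The chain keeps its state with probability ``state_persistence`` and
    otherwise redraws from the target occupancy π(t) of the new frame, so
    the marginal obeys m(t+1) = h·m(t) + (1-h)·π(t+1).
    """
    h = p.state_persistence
    times = np.arange(n_frames) / max(p.grid.n_frames - 1, 1)
    pis = state_targets(times)
    labels = np.empty(n_frames, dtype=object)
    idx = int(np.searchsorted(np.cumsum(pis[0]), u_draws[0] * pis[0].sum()))
    idx = min(idx, 3)
    labels[0] = STATE_LABELS[idx]
    for t in range(1, n_frames):
        u = u_draws[t]
        if u < h:
            labels[t] = labels[t - 1]
        else:
            v = (u - h) / (1.0 - h)  # re-uniform on [0,1)
            j = int(np.searchsorted(np.cumsum(pis[t]), v * pis[t].sum()))
            labels[t] = STATE_LABELS[min(j, 3)]
    return labels


def _build_cell(
    draw: dict,
    p: SynthParams,
    ind: InductionSpec | None,
) -> tuple[CellTrajectory, dict]:
    divisions = _division_frames(draw["rls_draw"], p)
    if divisions.size == 0:
        divisions = np.array([1])
    arrest = int(divisions[-1])
    rls = int(len(divisions))
    n_obs = arrest + 1
    t = np.arange(n_obs, dtype=float)

    cell_true = draw["a0"] + p.area_slope * t

    delta = min(p.accel_cap, p.accel_delta0 * (p.accel_rls_ref / rls) ** 2)
    if arrest > p.t_bend:
        beta = delta / (arrest - p.t_bend) ** 2
    else:
        beta = 0.0
    accel = 1.0 + beta * np.maximum(0.0, t - p.t_bend) ** 2
    nuc_true = p.nuc_ratio * cell_true * accel

    # cytoplasmic concentration: plateau + AR(1) fluctuations
    innov_sd = p.ar_sd * np.sqrt(1.0 - p.ar_phi**2)
    x = np.empty(n_obs)
    x[0] = p.ar_sd * draw["ar_innov"][0]
    for k in range(1, n_obs):
        x[k] = p.ar_phi * x[k - 1] + innov_sd * draw["ar_innov"][k]
    i_cyt_true = draw["baseline"] + x

    c1_series = None
    if ind is not None and ind.t_induce < n_obs:
        ramp = np.ones(n_obs)
        for k in range(n_obs):
            if k >= ind.t_induce:
                frac = min(1.0, (k - ind.t_induce + 1) / ind.ramp_frames)
                ramp[k] = 1.0 + (ind.cyt_fold - 1.0) * frac
        i_cyt_true = i_cyt_true * ramp
        if ind.c1_post is not None:
            c1_series = np.full(n_obs, p.transport.c1)
            c1_series[ind.t_induce :] = ind.c1_post
        if ind.nuc_growth_boost is not None:
            t0 = ind.t_induce
            boosted = nuc_true.copy()
            boosted[t0:] = nuc_true[t0] + ind.nuc_growth_boost * (
                nuc_true[t0:] - nuc_true[t0]
            )
            nuc_true = boosted

    i_n0 = steady_state(i_cyt_true[0], nuc_true[0], p.transport)
    if n_obs >= 2:
        i_nuc_true = transport_simulate(
            i_cyt_true, nuc_true, p.transport, i_n0, c1_series=c1_series
        )
    else:
        i_nuc_true = np.array([i_n0])

    traj = CellTrajectory(
        cell_id=draw["cell_id"],
        frames=np.arange(n_obs),
        cell_area=_mult_noise(cell_true, p.noise_cv_cell_area, draw["z_cell_area"][:n_obs]),
        nuc_area=_mult_noise(nuc_true, p.noise_cv_nuc_area, draw["z_nuc_area"][:n_obs]),
        i_nuc=_mult_noise(i_nuc_true, p.noise_cv_i_nuc, draw["z_i_nuc"][:n_obs]),
        i_cyt=_mult_noise(i_cyt_true, p.noise_cv_i_cyt, draw["z_i_cyt"][:n_obs]),
        division_frames=divisions,
        state=_sample_states(p, n_obs, draw["state_u"]) if p.with_states else None,
    )
    truth = {
        "cell_id": draw["cell_id"],
        "rls_draw": draw["rls_draw"],
        "rls": rls,
        "beta": beta,
        "a0": draw["a0"],
        "baseline": draw["baseline"],
        "i_nuc_true": i_nuc_true,
        "nuc_area_true": nuc_true,
        "i_cyt_true": i_cyt_true,
    }
    return traj, truth


def gen_cohort(p: SynthParams, seed: int | None = None) -> tuple[Cohort, dict]:
    """Generate a cohort plus its ground-truth record.

    The ground truth carries each cell's nuclear-growth curvature β, the
    drawn lifespan, the noiseless series, and the generating transport
    parameters (recoverable because nuclear intensity is simulated on
    noiseless inputs before measurement noise).
    """
    seed = p.seed if seed is None else seed
    draws = _draw_cells(p, seed)
    cells, truths = [], []
    for d in draws:
        traj, truth = _build_cell(d, p, None)
        cells.append(traj)
        truths.append(truth)
    cohort = Cohort(
        grid=p.grid,
        cells=cells,
        meta={"generator": "gen_cohort", "seed": seed,
              "transport": {"c1": p.transport.c1, "gamma": p.transport.gamma,
                            "alpha": p.transport.alpha}},
    )
    truth = {
        "transport": p.transport,
        "params": p,
        "seed": seed,
        "cells": {t["cell_id"]: t for t in truths},
    }
    return cohort, truth


def gen_induction_cohort(
    p: SynthParams,
    ind: InductionSpec,
    seed: int | None = None,
) -> tuple[Cohort, Cohort]:
    """Paired (induced, control) cohorts sharing all pre-induction randomness."""
    if ind.t_induce >= p.grid.n_frames:
        raise ValidationError("t_induce beyond the time grid")
    seed = p.seed if seed is None else seed
    draws = _draw_cells(p, seed)
    control_cells = [_build_cell(d, p, None)[0] for d in draws]
    induced_cells = [_build_cell(d, p, ind)[0] for d in draws]
    meta = {"seed": seed, "t_induce": ind.t_induce, "cyt_fold": ind.cyt_fold,
            "c1_post": ind.c1_post, "nuc_growth_boost": ind.nuc_growth_boost}
    induced = Cohort(grid=p.grid, cells=induced_cells,
                     meta={"generator": "gen_induction_cohort", "arm": "induced", **meta})
    control = Cohort(grid=p.grid, cells=control_cells,
                     meta={"generator": "gen_induction_cohort", "arm": "control", **meta})
    return induced, control


# ---------------------------------------------------------------------------
# Coupled marker pairs (ground truth for the Granger procedure)
# ---------------------------------------------------------------------------

_LINKS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "quadratic": lambda x: x**2 - 1.0,  # centred for a standard-normal input
    "linear": lambda x: x,
    "abs": lambda x: np.abs(x),
}


def gen_coupled_pair(
    p: SynthParams,
    lag: int,
    link: str = "quadratic",
    noise_sd: float = 0.1,
    coupled: bool = True,
    seed: int | None = None,
    latent_phi: float = 0.95,
) -> Cohort:
    """Cohort with two marker channels, optionally coupled at a fixed lag.

    Marker X is a smooth per-cell AR(1) latent (stationary sd 1); if
    ``coupled``, marker Y(t) = link(X(t - lag)) + noise, so Y carries a
    nonlinear echo of X exactly ``lag`` frames later.  If not coupled, Y is
    built from an independent latent passed through the same link, matching
    the marginal moments.  The channels are stored as ``i_cyt`` (X) and
    ``i_nuc`` (Y); areas and divisions come from the usual growth and cycle
    models so that alive masks behave like a real cohort.
    """
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    if link not in _LINKS:
        raise ConfigError(f"unknown link {link!r}; options: {sorted(_LINKS)}")
    fn = _LINKS[link]
    seed = p.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    nb_p = p.rls_nb_size / (p.rls_nb_size + p.rls_nb_mean)
    innov_sd = np.sqrt(1.0 - latent_phi**2)
    cells = []
    for i in range(p.n_cells):
        rls_draw = max(1, int(rng.negative_binomial(p.rls_nb_size, nb_p)))
        divisions = _division_frames(rls_draw, p)
        if divisions.size == 0:
            divisions = np.array([1])
        arrest = int(divisions[-1])
        n_obs = arrest + 1
        t = np.arange(n_obs, dtype=float)
        a0 = rng.normal(p.area_intercept_mean, p.area_intercept_sd)
        cell_area = a0 + p.area_slope * t

        def _latent(n: int) -> np.ndarray:
            x = np.empty(n)
            x[0] = rng.standard_normal()
            for k in range(1, n):
                x[k] = latent_phi * x[k - 1] + innov_sd * rng.standard_normal()
            return x

        x = _latent(n_obs)
        src = x if coupled else _latent(n_obs)
        lagged = src[np.maximum(0, np.arange(n_obs) - lag)]
        y = fn(lagged) + noise_sd * rng.standard_normal(n_obs)
        cells.append(
            CellTrajectory(
                cell_id=f"cell{i:04d}",
                frames=np.arange(n_obs),
                cell_area=cell_area,
                nuc_area=p.nuc_ratio * cell_area,
                i_nuc=y,
                i_cyt=x,
                division_frames=divisions,
            )
        )
    return Cohort(
        grid=p.grid,
        cells=cells,
        meta={"generator": "gen_coupled_pair", "seed": seed, "lag": lag,
              "link": link, "coupled": coupled, "noise_sd": noise_sd,
              "channels": {"x": "i_cyt", "y": "i_nuc"}},
    )


# ---------------------------------------------------------------------------
# Synthetic two-channel z-stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and intensities of a synthetic two-channel z-stack.

    Channel 1 is a cytoplasmic disk with a brighter nuclear blob; channel 2
    carries the nuclear blob only (the independent nuclear marker).  Each
    slice is scaled by the axial attenuation profile, then constant
    background and additive Gaussian noise are applied.  ``background`` may
    be a scalar or one offset per slice.
    """

    shape: tuple[int, int] = (128, 128)
    n_slices: int = 17
    cell_radius: float = 42.0
    nucleus_radius: float = 18.0
    cytoplasm: float = 200.0
    nucleus: float = 1000.0
    nucleus_ch2: float = 800.0
    background: float | tuple = 20.0
    noise_sd: float = 10.0
    nucleus_offset: tuple[float, float] = (3.0, -2.0)
    axial_profile: tuple | None = None  # default: Gaussian bump, peak 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise ValidationError("nucleus radius must be < cell radius")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        for name in ("cytoplasm", "nucleus", "nucleus_ch2", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def profile(self) -> np.ndarray:
        if self.axial_profile is not None:
            prof = np.asarray(self.axial_profile, dtype=float)
            if len(prof) != self.n_slices:
                raise ValidationError("axial_profile length must equal n_slices")
            return prof
        s = np.arange(self.n_slices, dtype=float)
        c = (self.n_slices - 1) / 2.0
        width = max(self.n_slices / 4.0, 1.0)
        return np.exp(-0.5 * ((s - c) / width) ** 2)

    def backgrounds(self) -> np.ndarray:
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim == 0:
            return np.full(self.n_slices, float(bg))
        if len(bg) != self.n_slices:
            raise ValidationError("background length must equal n_slices")
        return bg


@dataclass
class SyntheticStack:
    """Two-channel stack with pixel-exact ground-truth masks."""

    channel1: ImageStack
    channel2: ImageStack
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    spec: ImageSpec


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def gen_image_stack(spec: ImageSpec, seed: int | None = None) -> SyntheticStack:
    """Render the synthetic stack described by ``spec``.

    Slice s of channel 1 equals
    ``profile[s] * (cytoplasm on the cell disk, nucleus on the nuclear
    blob) + background[s] + noise``; channel 2 carries only the nuclear
    blob.  Masks are returned pixel-exact.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    nuc_center = (center[0] + spec.nucleus_offset[0], center[1] + spec.nucleus_offset[1])
    cell = _disk_mask(spec.shape, center, spec.cell_radius)
    nucleus = _disk_mask(spec.shape, nuc_center, spec.nucleus_radius) & cell
    prof = spec.profile()
    bgs = spec.backgrounds()

    base1 = np.where(nucleus, spec.nucleus, np.where(cell, spec.cytoplasm, 0.0))
    base2 = np.where(nucleus, spec.nucleus_ch2, 0.0)
    ch1 = np.empty((spec.n_slices, h, w))
    ch2 = np.empty((spec.n_slices, h, w))
    for s in range(spec.n_slices):
        n1 = rng.normal(0.0, spec.noise_sd, (h, w)) if spec.noise_sd > 0 else 0.0
        n2 = rng.normal(0.0, spec.noise_sd, (h, w)) if spec.noise_sd > 0 else 0.0
        ch1[s] = np.maximum(prof[s] * base1 + bgs[s] + n1, 0.0)
        ch2[s] = np.maximum(prof[s] * base2 + bgs[s] + n2, 0.0)
    return SyntheticStack(
        channel1=ImageStack(data=ch1, cell_mask=cell),
        channel2=ImageStack(data=ch2, cell_mask=cell),
        cell_mask=cell,
        nucleus_mask=nucleus,
        spec=spec,
    )
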