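"""Lifespan-marker screens and morphology-fraction analyses.

The central screen correlates, frame by frame, a marker value with the
replicative lifespan of the cells that are *still dividing* at that frame
(arrest frame >= frame).  Frames where fewer than ``min_cells`` cells remain
are flagged and excluded from peak selection — with few survivors the
correlation estimate is dominated by sampling noise.  Intensity channels are
log10-transformed by default; area channels are not.  p-values are raw
(no across-frame multiple-testing correction is applied; the per-frame
screens are descriptive, not a family of confirmatory tests).

Group trajectories split cells into short-lived (RLS < 15) and long-lived
(RLS >= 15) groups and report per-frame mean ± SEM over still-dividing
cells, optionally after dividing each cell's series by its lifetime maximum;
output is truncated once fewer than ``min_alive`` cells remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import STATE_LABELS, CellTrajectory, Cohort
from .exceptions import ValidationError

__all__ = [
    "CorrelationSeries",
    "GroupSeries",
    "StateFractionSeries",
    "dividing_at",
    "correlation_series",
    "group_series",
    "mean_series",
    "size_ratio_series",
    "qc_filter",
    "state_fractions",
    "majority_state_compare",
]

#: Channels that are log10-transformed by default in the correlation screen.
INTENSITY_CHANNELS = ("i_nuc", "i_cyt")


@dataclass
class CorrelationSeries:
    """Per-frame marker-vs-lifespan Pearson correlation screen."""

    channel: str
    frames: np.ndarray
    r: np.ndarray
    p: np.ndarray
    n_dividing: np.ndarray
    min_cells: int
    log10_transform: bool
    n_excluded_log: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def admissible(self) -> np.ndarray:
        """Frames that enter peak selection (n >= min_cells, finite r)."""
        return (self.n_dividing >= self.min_cells) & np.isfinite(self.r)

    @property
    def peak(self) -> tuple[int, float, float]:
        """(frame*, r*, p*) at the maximum -log10 p among admissible frames.

        Ties are broken by the earlier frame.
        """
        ok = self.admissible
        if not ok.any():
            raise ValidationError("no admissible frames for peak selection")
        neglog = np.where(ok, -np.log10(np.maximum(self.p, 1e-300)), -np.inf)
        idx = int(np.argmax(neglog))  # argmax returns the first maximum
        return int(self.frames[idx]), float(self.r[idx]), float(self.p[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frames, "r": self.r, "p": self.p, "n_dividing": self.n_dividing}
        )


@dataclass
class GroupSeries:
    """Per-frame mean ± SEM of one channel over one lifespan group."""

    label: str
    frames: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    normalized: bool
    truncation_frame: int  # first frame with n < min_alive (== len if never)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frames, "mean": self.mean, "sem": self.sem, "n": self.n,
             "group": self.label}
        )


@dataclass
class StateFractionSeries:
    """Per-frame morphology-state composition among still-dividing cells."""

    frames: np.ndarray
    fractions: pd.DataFrame  # columns = STATE_LABELS, rows aligned to frames
    n_alive: np.ndarray


def dividing_at(cohort: Cohort, frame: int) -> list[CellTrajectory]:
    """Cells still dividing at ``frame`` (arrest_frame >= frame, inclusive)."""
    return [c for c in cohort.cells if c.arrest_frame >= frame]


def correlation_series(
    cohort: Cohort,
    channel: str,
    log10_transform: bool | None = None,
    min_cells: int = 25,
) -> CorrelationSeries:
    """Per-frame Pearson correlation between a marker and lifespan.

    At each frame, the channel value of every still-dividing cell is
    correlated (two-sided Pearson test) with that cell's RLS.  With
    ``log10_transform`` (default: on for intensity channels, off for areas),
    non-positive values are excluded per frame and their count reported.
    """
    if min_cells < 3:
        raise ValidationError("min_cells must be >= 3")
    if log10_transform is None:
        log10_transform = channel in INTENSITY_CHANNELS
    values = cohort.channel_matrix(channel)
    alive = cohort.alive_matrix()
    rls = cohort.rls_values().astype(float)
    n_frames = cohort.grid.n_frames
    r = np.full(n_frames, np.nan)
    p = np.full(n_frames, np.nan)
    n_div = np.zeros(n_frames, dtype=int)
    n_excl = np.zeros(n_frames, dtype=int)
    for t in range(n_frames):
        sel = alive[:, t] & np.isfinite(values[:, t])
        x = values[sel, t]
        y = rls[sel]
        if log10_transform:
            pos = x > 0
            n_excl[t] = int((~pos).sum())
            x, y = np.log10(x[pos]), y[pos]
        n_div[t] = len(x)
        if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            res = stats.pearsonr(x, y)
            r[t], p[t] = res.statistic, res.pvalue
    return CorrelationSeries(
        channel=channel,
        frames=cohort.grid.frames,
        r=r,
        p=p,
        n_dividing=n_div,
        min_cells=min_cells,
        log10_transform=log10_transform,
        n_excluded_log=n_excl,
    )


def _series_over(
    cohort: Cohort,
    channel: str,
    sel: np.ndarray,
    label: str,
    normalize: bool,
    min_alive: int,
) -> GroupSeries:
    alive = cohort.alive_matrix()[sel]
    mat = cohort.channel_matrix(channel)[sel]
    if normalize:
        with np.errstate(invalid="ignore"):
            mx = np.nanmax(np.where(alive, mat, np.nan), axis=1, keepdims=True)
        mat = mat / mx
    mat = np.where(alive, mat, np.nan)
    n = np.isfinite(mat).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = sd / np.sqrt(np.maximum(n, 1))
    below = np.flatnonzero(n < min_alive)
    stop = int(below[0]) if below.size else cohort.grid.n_frames
    fr = cohort.grid.frames[:stop]
    return GroupSeries(
        label=label,
        frames=fr,
        mean=mean[:stop],
        sem=sem[:stop],
        n=n[:stop],
        normalized=normalize,
        truncation_frame=stop,
    )


def group_series(
    cohort: Cohort,
    channel: str,
    rls_threshold: int = 15,
    normalize: bool = False,
    min_alive: int = 25,
) -> tuple[GroupSeries, GroupSeries]:
    """Short-lived / long-lived group trajectories of one channel.

    Cells with RLS < ``rls_threshold`` form the short-lived group; the rest
    the long-lived group.  With ``normalize`` each cell's series is divided
    by its lifetime maximum before averaging.  Output stops at the first
    frame where fewer than ``min_alive`` cells are still dividing.
    """
    rls = cohort.rls_values()
    short_sel = rls < rls_threshold
    long_sel = ~short_sel
    out = []
    for label, sel in (("short", short_sel), ("long", long_sel)):
        if not sel.any():
            warnings.warn(f"group {label!r} is empty")
            out.append(
                GroupSeries(label, np.array([], int), np.array([]), np.array([]),
                            np.array([], int), normalize, 0)
            )
        else:
            out.append(_series_over(cohort, channel, sel, label, normalize, min_alive))
    return out[0], out[1]


def mean_series(
    cohort: Cohort,
    channel: str,
    normalize: bool = False,
    min_alive: int = 25,
) -> GroupSeries:
    """All-cells per-frame mean ± SEM over still-dividing cells."""
    sel = np.ones(cohort.n_cells, dtype=bool)
    return _series_over(cohort, channel, sel, "all", normalize, min_alive)


def size_ratio_series(
    cohort: Cohort,
    rls_threshold: int = 15,
    min_alive: int = 25,
) -> tuple[np.ndarray, GroupSeries, GroupSeries]:
    """Nucleus/cell area ratio per cell plus short/long group means.

    The ratio uses un-normalized sizes.  Returns the (n_cells, n_frames)
    per-cell ratio matrix (NaN where unobserved) and the two group series.
    """
    for c in cohort.cells:
        if np.any(c.cell_area == 0):
            raise ValidationError(f"cell {c.cell_id!r}: zero cell area")
    ratio = cohort.channel_matrix("ratio")
    short, long_ = group_series(
        cohort, "ratio", rls_threshold=rls_threshold, normalize=False, min_alive=min_alive
    )
    return ratio, short, long_


def qc_filter(cohort: Cohort, r_min: float = 0.7) -> tuple[Cohort, pd.DataFrame]:
    """Keep cells whose cell area grows linearly with time (Pearson r > r_min).

    Mirrors the tracking-pipeline outlier filter: cell area is expected to
    increase linearly with time, so a low area-vs-time correlation indicates
    a tracking or segmentation failure.  Constant-area cells (undefined
    correlation) are rejected with reason ``zero variance``.
    """
    rows = []
    kept = []
    for c in cohort.cells:
        if c.n_frames < 3:
            rows.append({"cell_id": c.cell_id, "r": np.nan, "kept": False,
                         "reason": "fewer than 3 frames"})
            continue
        if np.std(c.cell_area) == 0:
            rows.append({"cell_id": c.cell_id, "r": np.nan, "kept": False,
                         "reason": "zero variance"})
            continue
        r = float(stats.pearsonr(c.frames.astype(float), c.cell_area).statistic)
        keep = r > r_min
        rows.append({"cell_id": c.cell_id, "r": r, "kept": keep,
                     "reason": "" if keep else f"r <= {r_min}"})
        if keep:
            kept.append(c.cell_id)
    report = pd.DataFrame(rows, columns=["cell_id", "r", "kept", "reason"])
    return cohort.subset(kept), report


def state_fractions(cohort: Cohort) -> StateFractionSeries:
    """Fractions of morphology states among still-dividing cells per frame."""
    n_frames = cohort.grid.n_frames
    counts = np.zeros((n_frames, len(STATE_LABELS)))
    n_alive = np.zeros(n_frames, dtype=int)
    index = {s: i for i, s in enumerate(STATE_LABELS)}
    for c in cohort.cells:
        if c.state is None:
            raise ValidationError(f"cell {c.cell_id!r} has no state channel")
        stop = min(c.arrest_frame, c.frames[-1]) if c.arrest_frame >= 0 else -1
        for t_idx, f in enumerate(c.frames):
            if f > stop:
                break
            lab = c.state[t_idx]
            if lab not in index:
                raise ValidationError(f"unknown state label {lab!r}")
            counts[f, index[lab]] += 1
            n_alive[f] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = counts / n_alive[:, None]
    return StateFractionSeries(
        frames=cohort.grid.frames,
        fractions=pd.DataFrame(fractions, columns=list(STATE_LABELS)),
        n_alive=n_alive,
    )


def majority_state_compare(
    cohort: Cohort,
    states: tuple[str, str] = ("circular", "aggregate"),
) -> dict:
    """Compare lifespan and division pace between plurality-state groups.

    Each cell is assigned to whichever of the two queried states it occupies
    for more of its still-dividing frames; exact ties are left unassigned
    (and reported).  For each group the mean RLS and the mean inter-division
    interval (frames alive per division) are reported, together with
    Wilcoxon rank-sum tests between the groups.
    """
    for s in states:
        if s not in STATE_LABELS:
            raise ValidationError(f"unknown state label {s!r}")
    groups: dict[str, list[CellTrajectory]] = {s: [] for s in states}
    unassigned: list[str] = []
    for c in cohort.cells:
        if c.state is None:
            raise ValidationError(f"cell {c.cell_id!r} has no state channel")
        stop = c.arrest_frame
        alive_states = [c.state[i] for i, f in enumerate(c.frames) if f <= stop]
        n0 = sum(1 for s in alive_states if s == states[0])
        n1 = sum(1 for s in alive_states if s == states[1])
        if n0 > n1:
            groups[states[0]].append(c)
        elif n1 > n0:
            groups[states[1]].append(c)
        else:
            unassigned.append(c.cell_id)
    out: dict = {"states": states, "unassigned": unassigned, "groups": {}}
    for s in states:
        cells = groups[s]
        rls = np.array([c.rls for c in cells], dtype=float)
        interval = np.array(
            [(c.arrest_frame + 1) / c.rls for c in cells if c.rls > 0], dtype=float
        )
        out["groups"][s] = {
            "n": len(cells),
            "mean_rls": float(rls.mean()) if len(cells) else np.nan,
            "mean_interdivision_frames": float(interval.mean()) if len(interval) else np.nan,
        }
    if all(len(groups[s]) >= 2 for s in states):
        a, b = (np.array([c.rls for c in groups[s]], dtype=float) for s in states)
        out["rls_ranksum_p"] = float(stats.ranksums(a, b).pvalue)
        ia, ib = (
            np.array([(c.arrest_frame + 1) / c.rls for c in groups[s] if c.rls > 0])
            for s in states
        )
        if len(ia) >= 2 and len(ib) >= 2:
            out["interval_ranksum_p"] = float(stats.ranksums(ia, ib).pvalue)
    else:
        warnings.warn("fewer than 2 cells in a group; comparison skipped")
        out["rls_ranksum_p"] = np.nan
    return out
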