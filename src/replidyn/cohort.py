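"""Core data model for single-mother-cell aging trajectories.

A :class:`CellTrajectory` holds the sampled time series of one yeast mother
cell followed through replicative aging: projected cell area, projected
nuclear area, nuclear and cytoplasmic reporter intensities, the frames at
which a division (bud emergence) was observed, and an optional categorical
morphology state per frame.  A :class:`Cohort` is a set of trajectories on a
shared :class:`TimeGrid` (default: one frame every 20 min, 216 frames = 72 h).

Replicative lifespan (RLS) is the number of divisions a mother completes; the
*arrest frame* is the frame of its last observed division.  A cell is "still
dividing" (alive for screening purposes) at frame ``f`` iff
``f <= arrest_frame`` — the boundary is inclusive, keeping the cell in its
last productive frame.

Trajectory tables are long-format delimited text (comma or tab, sniffed) with
one row per (cell, frame).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import SchemaError, TrajectoryFormatError, ValidationError

__all__ = [
    "TimeGrid",
    "CellTrajectory",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "STATE_LABELS",
]

#: Recognised morphology states (coarse-grained organelle topology labels).
STATE_LABELS = ("circular", "fragmented", "aggregate", "other")

REQUIRED_COLUMNS = (
    "cell_id",
    "frame",
    "time_min",
    "cell_area",
    "nuc_area",
    "i_nuc",
    "i_cyt",
    "divided_this_frame",
)


@dataclass(frozen=True)
class TimeGrid:
    """Common imaging time axis: consecutive integer frames from 0.

    Parameters
    ----------
    frame_interval_min : float
        Minutes between consecutive frames (default 20).
    n_frames : int
        Number of frames on the grid (default 216, i.e. 72 h).
    """

    frame_interval_min: float = 20.0
    n_frames: int = 216

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValidationError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")

    def t_min(self, frame: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(frame) * self.frame_interval_min

    def t_hours(self, frame: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(frame) * self.frame_interval_min / 60.0

    def frame_at_hours(self, hours: float) -> int:
        """Nearest frame to a wall-clock time in hours."""
        return int(round(hours * 60.0 / self.frame_interval_min))

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.n_frames)


@dataclass
class CellTrajectory:
    """One mother cell's observed time series.

    Series are aligned to ``frames`` (consecutive integers starting at the
    first observed frame, typically 0) and truncated at the end of
    observation.  Division frames index into the same axis.
    """

    cell_id: str
    frames: np.ndarray
    cell_area: np.ndarray
    nuc_area: np.ndarray
    i_nuc: np.ndarray
    i_cyt: np.ndarray
    division_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    state: np.ndarray | None = None  # per-frame labels from STATE_LABELS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.cell_area = np.asarray(self.cell_area, dtype=float)
        self.nuc_area = np.asarray(self.nuc_area, dtype=float)
        self.i_nuc = np.asarray(self.i_nuc, dtype=float)
        self.i_cyt = np.asarray(self.i_cyt, dtype=float)
        self.division_frames = np.asarray(self.division_frames, dtype=int)
        if self.state is not None:
            self.state = np.asarray(self.state, dtype=object)
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def rls(self) -> int:
        """Replicative lifespan: number of observed divisions."""
        return int(len(self.division_frames))

    @property
    def arrest_frame(self) -> int:
        """Frame of the last observed division (-1 if the cell never divided)."""
        if self.rls == 0:
            return -1
        return int(self.division_frames.max())

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def alive_at(self, frame: int) -> bool:
        """Still dividing at ``frame`` (inclusive of the last division frame)."""
        return self.arrest_frame >= frame

    # -- checks -------------------------------------------------------------

    def validate(self) -> None:
        n = len(self.frames)
        for name in ("cell_area", "nuc_area", "i_nuc", "i_cyt"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValidationError(
                    f"cell {self.cell_id!r}: series {name!r} has length "
                    f"{len(arr)}, expected {n}"
                )
        if self.state is not None and len(self.state) != n:
            raise ValidationError(f"cell {self.cell_id!r}: state series length mismatch")
        if n and np.any(np.diff(self.frames) != 1):
            raise TrajectoryFormatError(
                f"cell {self.cell_id!r}: frames are not consecutive integers"
            )
        for name in ("cell_area", "nuc_area"):
            arr = getattr(self, name)
            bad = np.flatnonzero(~(arr > 0))
            if bad.size:
                raise ValidationError(
                    f"cell {self.cell_id!r}: non-positive {name} at frame "
                    f"{int(self.frames[bad[0]])}"
                )
        if self.division_frames.size:
            extra = set(self.division_frames.tolist()) - set(self.frames.tolist())
            if extra:
                raise ValidationError(
                    f"cell {self.cell_id!r}: division frames {sorted(extra)} "
                    "outside observed frames"
                )


@dataclass
class Cohort:
    """A set of trajectories on a common time grid plus provenance metadata."""

    grid: TimeGrid
    cells: list[CellTrajectory]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValidationError("cell_ids are not unique")
        for c in self.cells:
            if c.n_frames and c.frames[-1] >= self.grid.n_frames:
                raise ValidationError(
                    f"cell {c.cell_id!r} extends beyond the grid "
                    f"({int(c.frames[-1])} >= {self.grid.n_frames})"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def channel_matrix(self, channel: str) -> np.ndarray:
        """(n_cells, n_frames) matrix of one channel, NaN where unobserved.

        ``channel`` is one of cell_area | nuc_area | i_nuc | i_cyt | ratio
        (ratio = nuc_area / cell_area on observed frames).
        """
        out = np.full((self.n_cells, self.grid.n_frames), np.nan)
        for i, c in enumerate(self.cells):
            if channel == "ratio":
                vals = c.nuc_area / c.cell_area
            else:
                try:
                    vals = getattr(c, channel)
                except AttributeError:
                    raise ValidationError(f"unknown channel {channel!r}") from None
            out[i, c.frames] = vals
        return out

    def alive_matrix(self) -> np.ndarray:
        """(n_cells, n_frames) boolean: cell still dividing at frame."""
        arr = np.zeros((self.n_cells, self.grid.n_frames), dtype=bool)
        for i, c in enumerate(self.cells):
            if c.arrest_frame >= 0:
                arr[i, : c.arrest_frame + 1] = True
        return arr

    def rls_values(self) -> np.ndarray:
        return np.array([c.rls for c in self.cells], dtype=int)

    def arrest_frames(self) -> np.ndarray:
        return np.array([c.arrest_frame for c in self.cells], dtype=int)

    def subset(self, cell_ids: Iterable[str]) -> "Cohort":
        keep = set(cell_ids)
        return Cohort(
            grid=self.grid,
            cells=[c for c in self.cells if c.cell_id in keep],
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_cohort(path: str | Path, grid: TimeGrid | None = None) -> Cohort:
    """Read a long-format trajectory table into a :class:`Cohort`.

    The table must carry the columns ``cell_id, frame, time_min, cell_area,
    nuc_area, i_nuc, i_cyt, divided_this_frame`` and may carry ``state``.
    Rows are grouped by ``cell_id``; division frames are the frames whose
    divided flag is set.  If ``grid`` is omitted it is inferred from the
    table's time column and maximum frame.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"table {path} is missing mandatory columns: {missing}")
    has_state = "state" in df.columns

    if grid is None:
        if len(df):
            frames = df["frame"].to_numpy()
            times = df["time_min"].to_numpy(dtype=float)
            nz = frames > 0
            interval = float(np.median(times[nz] / frames[nz])) if nz.any() else 20.0
            n_frames = max(int(frames.max()) + 1, 2)
        else:
            interval, n_frames = 20.0, 216
        grid = TimeGrid(frame_interval_min=interval, n_frames=n_frames)

    cells: list[CellTrajectory] = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        frames = g["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) <= 0):
            raise TrajectoryFormatError(
                f"cell {cell_id!r}: frames are not strictly increasing"
            )
        divided = g["divided_this_frame"].to_numpy().astype(bool)
        cells.append(
            CellTrajectory(
                cell_id=str(cell_id),
                frames=frames,
                cell_area=g["cell_area"].to_numpy(dtype=float),
                nuc_area=g["nuc_area"].to_numpy(dtype=float),
                i_nuc=g["i_nuc"].to_numpy(dtype=float),
                i_cyt=g["i_cyt"].to_numpy(dtype=float),
                division_frames=frames[divided],
                state=g["state"].to_numpy(dtype=object) if has_state else None,
            )
        )
    return Cohort(grid=grid, cells=cells, meta={"source": str(path)})


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame view of a cohort (deterministic row order)."""
    rows = []
    any_state = any(c.state is not None for c in cohort.cells)
    for c in sorted(cohort.cells, key=lambda c: c.cell_id):
        div = np.zeros(c.n_frames, dtype=int)
        div[np.isin(c.frames, c.division_frames)] = 1
        rec = {
            "cell_id": c.cell_id,
            "frame": c.frames,
            "time_min": cohort.grid.t_min(c.frames),
            "cell_area": c.cell_area,
            "nuc_area": c.nuc_area,
            "i_nuc": c.i_nuc,
            "i_cyt": c.i_cyt,
            "divided_this_frame": div,
        }
        if any_state:
            rec["state"] = c.state if c.state is not None else np.full(c.n_frames, "", object)
        rows.append(pd.DataFrame(rec))
    if not rows:
        cols = list(REQUIRED_COLUMNS) + (["state"] if any_state else [])
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as a comma-delimited long-format table.

    Row order is (cell_id, frame); floats are written with 10 significant
    digits so that read → write is idempotent (byte-identical second file).
    """
    path = Path(path)
    df = cohort_to_frame(cohort)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path
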