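"""Nonlinear Granger-causality temporal ordering between two markers.

The question asked is directional and predictive: does marker 1 at frame t1
help predict marker 2 at a later frame t2, beyond what marker 2's own value
at t1 already predicts?  Tree regressors replace the linear models of the
classical Granger construction so that nonlinear (e.g. quadratic)
dependencies are captured.

Procedure per ordered frame pair (t1 < t2), over the cells still dividing at
both frames (pairs with fewer than ``min_cells`` such cells are excluded):

1. restricted model — a decision-tree regressor predicting f2[:, t2] from
   f2[:, t1] alone; full model — the same tree class predicting f2[:, t2]
   from (f2[:, t1], f1[:, t1]).  Both use the Friedman MSE split criterion
   and maximum depth ``max(1, floor(sqrt(n)))``.
2. residuals of both models are obtained out-of-sample by K-fold
   cross-fitting with a shared fold assignment (in-sample residuals of
   depth-sqrt(n) trees are degenerate: either model can memorise the sample,
   so only held-out residuals measure predictive value).
3. the residual variances are compared with a one-sided F-test; the signed
   -log10 p-value is stored at (t1, t2).

The raw matrix is post-processed by a rolling maximum (window 2), a
two-standard-deviation threshold computed over the strictly positive
entries, and Gaussian smoothing (sigma 1.2).

Inputs are first normalised: the cells x frames matrix is divided by its
leading singular value to equalise scale between the two markers, then each
cell's still-dividing stretch is mapped to [0, 1] by its min/max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .exceptions import ConfigError, ValidationError

__all__ = [
    "FeatureMatrix",
    "GrangerMatrix",
    "normalize_features",
    "granger_pair",
    "variance_f_test",
    "postprocess_matrix",
    "GrangerTemporalOrdering",
]

ALPHA_DEFAULT = 0.05


@dataclass
class FeatureMatrix:
    """One marker's cells x frames matrix after scale equalisation.

    ``values`` holds the per-cell 0-1 normalised series (NaN outside the
    alive mask); ``scaled`` is the intermediate matrix right after division
    by the leading singular value; ``scale`` is that singular value.
    """

    values: np.ndarray
    alive: np.ndarray
    scale: float
    scaled: np.ndarray
    cell_min: np.ndarray
    cell_max: np.ndarray
    constant_cells: list[int] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class GrangerMatrix:
    """Signed -log10 p over (predictor frame t1, target frame t2) pairs."""

    values: np.ndarray  # NaN at excluded / inadmissible pairs
    n_cells: np.ndarray
    excluded: np.ndarray  # True where no admissible test was run
    frames: np.ndarray  # frame labels of the rows/columns
    stage: str = "raw"
    min_cells: int = 56
    random_state: int = 0

    def admissible_values(self) -> np.ndarray:
        return self.values[~self.excluded]

    def significant(self, alpha: float = ALPHA_DEFAULT) -> np.ndarray:
        """Boolean matrix: |entry| exceeds the -log10(alpha) cutoff."""
        cut = -np.log10(alpha)
        with np.errstate(invalid="ignore"):
            return np.where(self.excluded, False, np.abs(self.values) > cut)


def normalize_features(
    raw: np.ndarray,
    alive: np.ndarray | None = None,
) -> FeatureMatrix:
    """SVD scale equalisation followed by per-cell 0-1 range normalisation.

    The matrix is divided by its leading singular value (computed with
    missing entries filled by column means, the fill used only for the
    decomposition); each cell's alive-frame series is then mapped to [0, 1]
    by its min/max.  A cell with zero range is mapped to a constant 0.5 and
    recorded in ``constant_cells``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 cells and >= 2 frames")
    if alive is None:
        alive = np.isfinite(raw)
    alive = np.asarray(alive, dtype=bool) & np.isfinite(raw)

    filled = np.where(alive, raw, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(filled, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    filled = np.where(alive, raw, col_means[None, :])

    s1 = float(np.linalg.svd(filled, compute_uv=False)[0])
    if s1 <= 0:
        raise ValidationError("leading singular value is zero (all-zero matrix)")
    scaled = np.where(alive, raw / s1, np.nan)

    values = np.full_like(scaled, np.nan)
    n_cells = raw.shape[0]
    cell_min = np.full(n_cells, np.nan)
    cell_max = np.full(n_cells, np.nan)
    constant: list[int] = []
    for i in range(n_cells):
        m = alive[i]
        if not m.any():
            continue
        lo, hi = np.nanmin(scaled[i, m]), np.nanmax(scaled[i, m])
        cell_min[i], cell_max[i] = lo, hi
        if hi > lo:
            values[i, m] = (scaled[i, m] - lo) / (hi - lo)
        else:
            values[i, m] = 0.5
            constant.append(i)
    return FeatureMatrix(
        values=values,
        alive=alive,
        scale=s1,
        scaled=scaled,
        cell_min=cell_min,
        cell_max=cell_max,
        constant_cells=constant,
    )


def variance_f_test(
    res_restricted: np.ndarray,
    res_full: np.ndarray,
) -> tuple[float, float, int]:
    """One-sided F-test comparing two residual sets' variances.

    ``F = var(res_restricted) / var(res_full)`` with sample variances
    (n - 1 denominator); the p-value is the upper tail of F(n-1, n-1) for
    the alternative var_restricted > var_full (i.e. the full model predicts
    better).  ``sign`` is +1 if F > 1, -1 if F < 1, 0 if F == 1.

    A zero full-model variance yields the smallest positive p, flagged by
    F = inf.
    """
    a = np.asarray(res_restricted, dtype=float)
    b = np.asarray(res_full, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("residual sets must be 1-D and equally long")
    n = len(a)
    if n < 3:
        raise ValidationError("need at least 3 residuals")
    var_r = float(np.var(a, ddof=1))
    var_f = float(np.var(b, ddof=1))
    if var_f == 0.0:
        if var_r == 0.0:
            return 1.0, 0.5, 0
        return float("inf"), float(np.nextafter(0, 1)), 1
    f_stat = var_r / var_f
    p = float(stats.f.sf(f_stat, n - 1, n - 1))
    sign = 0 if f_stat == 1.0 else (1 if f_stat > 1.0 else -1)
    return f_stat, p, sign


def _max_depth_sqrt(n: int) -> int:
    return max(1, int(np.floor(np.sqrt(n))))


def granger_pair(
    f1: FeatureMatrix,
    f2: FeatureMatrix,
    min_cells: int = 56,
    max_depth_rule=_max_depth_sqrt,
    random_state: int = 0,
    n_splits: int = 5,
    frame_step: int = 1,
    max_horizon: int | None = None,
    frames: np.ndarray | None = None,
) -> GrangerMatrix:
    """Raw signed -log10 p matrix for "f1 at t1 predicts f2 at t2".

    ``frame_step`` thins the frame grid and ``max_horizon`` bounds t2 - t1
    (both in frames) to keep large matrices tractable; by default every
    ordered pair is tested.
    """
    if f1.values.shape != f2.values.shape:
        raise ValidationError("feature matrices must share cells and grid")
    n_frames = f1.n_frames
    if frames is None:
        frames = np.arange(0, n_frames, frame_step)
    frames = np.asarray(frames, dtype=int)
    k = len(frames)
    values = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    excluded = np.ones((k, k), dtype=bool)
    alive_both = f1.alive & f2.alive
    rng_master = np.random.RandomState(random_state)
    tree_seed = int(rng_master.randint(0, 2**31 - 1))
    any_tested = False
    for i, t1 in enumerate(frames):
        for j, t2 in enumerate(frames):
            if t2 <= t1:
                continue
            if max_horizon is not None and t2 - t1 > max_horizon:
                continue
            cells = np.flatnonzero(alive_both[:, t1] & alive_both[:, t2])
            n_mat[i, j] = len(cells)
            if len(cells) < min_cells:
                continue
            own = f2.values[cells, t1]
            pred = f1.values[cells, t1]
            target = f2.values[cells, t2]
            depth = max_depth_rule(len(cells))
            res_r, res_f = _crossfit_residuals(
                own, pred, target, depth, tree_seed, n_splits
            )
            _, p, sign = variance_f_test(res_r, res_f)
            values[i, j] = sign * (-np.log10(max(p, 1e-300)))
            excluded[i, j] = False
            any_tested = True
    if not any_tested:
        warnings.warn("no admissible (t1, t2) pair; Granger matrix is empty")
    return GrangerMatrix(
        values=values,
        n_cells=n_mat,
        excluded=excluded,
        frames=frames,
        stage="raw",
        min_cells=min_cells,
        random_state=random_state,
    )


def _crossfit_residuals(
    own: np.ndarray,
    pred: np.ndarray,
    target: np.ndarray,
    depth: int,
    seed: int,
    n_splits: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-sample residuals of the restricted and full tree models.

    The same K-fold split is used for both models so their residuals are
    paired observation by observation.
    """
    n = len(target)
    x_r = own[:, None]
    x_f = np.column_stack([own, pred])
    res_r = np.empty(n)
    res_f = np.empty(n)
    kf = KFold(n_splits=min(n_splits, n), shuffle=True, random_state=seed)
    if depth < 1:
        # constant predictors: both models reduce to the training mean
        for train, test in kf.split(x_r):
            mean = target[train].mean()
            res_r[test] = target[test] - mean
            res_f[test] = target[test] - mean
        return res_r, res_f
    # "squared_error" is sklearn's name for the Friedman MSE split criterion in
    # regression trees (the two were always equivalent; "friedman_mse" is
    # deprecated as an alias since sklearn 1.9)
    for train, test in kf.split(x_r):
        tree_r = DecisionTreeRegressor(
            criterion="squared_error", max_depth=depth, random_state=seed
        ).fit(x_r[train], target[train])
        tree_f = DecisionTreeRegressor(
            criterion="squared_error", max_depth=depth, random_state=seed
        ).fit(x_f[train], target[train])
        res_r[test] = target[test] - tree_r.predict(x_r[test])
        res_f[test] = target[test] - tree_f.predict(x_f[test])
    return res_r, res_f


def postprocess_matrix(
    m: GrangerMatrix,
    window: int = 2,
    z_mult: float = 2.0,
    sigma: float = 1.2,
    stop_after: str = "smoothed",
) -> GrangerMatrix:
    """Rolling-max, threshold and smooth a raw Granger matrix.

    Stage 1 (``windowed``): each admissible entry is replaced by the maximum
    over its ``window`` x ``window`` neighbourhood (excluded entries are
    ignored).  Stage 2 (``thresholded``): the standard deviation is computed
    over entries with value > 0 (population sd, so a single positive entry
    gives sd 0 and survives); entries with magnitude below ``z_mult`` x sd
    are zeroed.  Stage 3 (``smoothed``): Gaussian filter with ``sigma``,
    excluded entries treated as 0 for the convolution and re-masked after.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    if stop_after not in ("windowed", "thresholded", "smoothed"):
        raise ConfigError(f"unknown stage {stop_after!r}")
    vals = np.where(m.excluded, -np.inf, np.where(np.isnan(m.values), -np.inf, m.values))
    windowed = ndimage.maximum_filter(vals, size=window, mode="constant", cval=-np.inf)
    windowed = np.where(m.excluded, np.nan, windowed)
    windowed = np.where(np.isneginf(windowed), np.nan, windowed)
    out = windowed
    stage = "windowed"
    if stop_after != "windowed":
        finite = out[np.isfinite(out)]
        positive = finite[finite > 0]
        sd = float(np.std(positive)) if positive.size else 0.0
        thresholded = np.where(
            np.isfinite(out) & (np.abs(out) < z_mult * sd), 0.0, out
        )
        out = thresholded
        stage = "thresholded"
    if stop_after == "smoothed":
        filled = np.where(np.isfinite(out), out, 0.0)
        smoothed = ndimage.gaussian_filter(filled, sigma=sigma)
        out = np.where(m.excluded, np.nan, smoothed)
        stage = "smoothed"
    return GrangerMatrix(
        values=out,
        n_cells=m.n_cells,
        excluded=m.excluded,
        frames=m.frames,
        stage=stage,
        min_cells=m.min_cells,
        random_state=m.random_state,
    )


class GrangerTemporalOrdering(BaseEstimator):
    """Estimator wrapper: normalise two markers, test all frame pairs,
    post-process.

    Parameters mirror the procedure defaults: ``min_cells=56`` excluded-pair
    rule, K-fold cross-fitting (``n_splits``), rolling-max ``window=2``,
    ``z_mult=2`` threshold and Gaussian ``sigma=1.2``.  ``frame_step`` /
    ``max_horizon`` thin the tested grid for large cohorts.

    Attributes after ``fit(X1, X2, alive=...)``:

    raw_matrix_ : GrangerMatrix
        Signed -log10 p per (t1, t2) pair.
    matrix_ : GrangerMatrix
        Post-processed (windowed, thresholded, smoothed) matrix.
    f1_, f2_ : FeatureMatrix
        The normalised inputs.
    """

    def __init__(
        self,
        min_cells: int = 56,
        n_splits: int = 5,
        random_state: int = 0,
        frame_step: int = 1,
        max_horizon: int | None = None,
        window: int = 2,
        z_mult: float = 2.0,
        sigma: float = 1.2,
    ):
        self.min_cells = min_cells
        self.n_splits = n_splits
        self.random_state = random_state
        self.frame_step = frame_step
        self.max_horizon = max_horizon
        self.window = window
        self.z_mult = z_mult
        self.sigma = sigma

    def fit(self, X1, X2, alive: np.ndarray | None = None):
        self.f1_ = normalize_features(np.asarray(X1, float), alive)
        self.f2_ = normalize_features(np.asarray(X2, float), alive)
        self.raw_matrix_ = granger_pair(
            self.f1_,
            self.f2_,
            min_cells=self.min_cells,
            random_state=self.random_state,
            n_splits=self.n_splits,
            frame_step=self.frame_step,
            max_horizon=self.max_horizon,
        )
        self.matrix_ = postprocess_matrix(
            self.raw_matrix_, window=self.window, z_mult=self.z_mult, sigma=self.sigma
        )
        return self
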