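"""Pipeline orchestration: run analysis stages from a configuration.

Stages (all driven by the synthetic generator so a run is self-contained):

* ``simulate`` — generate a cohort and write its trajectory table;
* ``fit-transport`` — fit the transport model to the cohort's averaged
  nuclear-intensity dynamics and write the parameter report;
* ``markers`` — correlation screens, group trajectories and the area-vs-time
  QC report;
* ``granger`` — temporal-ordering matrix between two cohort channels;
* ``segment`` — synthetic z-stack segmentation, region statistics and
  cross-channel validation.

Every stage writes its result tables plus a ``run_log.yaml`` recording the
parameters used; outputs are a pure function of (config, seed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gmmloc, granger, markers, transport
from .cohort import Cohort, read_cohort, write_cohort
from .exceptions import ConfigError
from .simulate import (
    ImageSpec,
    SynthParams,
    TimeGrid,
    gen_cohort,
    gen_coupled_pair,
    gen_image_stack,
)

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "fit-transport", "markers", "granger", "segment")


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _synth_params(cfg: dict, seed: int) -> SynthParams:
    grid = TimeGrid(
        frame_interval_min=cfg.get("frame_interval_min", 20.0),
        n_frames=cfg.get("n_frames", 216),
    )
    keys = (
        "n_cells", "area_slope", "area_intercept_mean", "area_intercept_sd",
        "nuc_ratio", "t_bend", "accel_delta0", "accel_cap",
        "i_cyt_baseline_mean", "i_cyt_baseline_sd", "ar_phi", "ar_sd",
        "noise_cv_cell_area", "noise_cv_nuc_area", "noise_cv_i_nuc",
        "noise_cv_i_cyt", "with_states",
    )
    kwargs = {k: cfg[k] for k in keys if k in cfg}
    return SynthParams(grid=grid, seed=seed, **kwargs)


def _stage_simulate(cfg: dict, out: Path, seed: int) -> dict:
    p = _synth_params(cfg, seed)
    cohort, truth = gen_cohort(p)
    path = out / "cohort.csv"
    write_cohort(cohort, path)
    with open(out / "cohort_truth.txt", "w", encoding="utf-8") as fh:
        fh.write(f"c1\t{p.transport.c1}\n")
        fh.write(f"gamma\t{p.transport.gamma}\n")
        fh.write(f"alpha\t{p.transport.alpha}\n")
        fh.write(f"seed\t{seed}\n")
    return {"n_cells": p.n_cells, "n_frames": p.grid.n_frames, "seed": seed}


def _require_cohort(out: Path, cfg: dict) -> Cohort:
    path = Path(cfg.get("cohort", out / "cohort.csv"))
    if not path.exists():
        raise ConfigError(
            f"no cohort table at {path}; run the simulate stage first or set "
            "the 'cohort' key"
        )
    return read_cohort(path)


def _stage_fit_transport(cfg: dict, out: Path, seed: int) -> dict:
    cohort = _require_cohort(out, cfg)
    freeze = {"gamma": cfg["freeze_gamma"]} if "freeze_gamma" in cfg else None
    result = transport.fit_cohort(
        cohort,
        alpha=cfg.get("alpha", 0.5),
        freeze=freeze,
        rls_threshold=cfg.get("rls_threshold", 15),
        min_alive=cfg.get("min_alive", 25),
    )
    with open(out / "fit_transport.txt", "w", encoding="utf-8") as fh:
        fh.write(f"c1\t{result.params.c1:.8g}\n")
        fh.write(f"gamma\t{result.params.gamma:.8g}\n")
        fh.write(f"alpha\t{result.params.alpha}\n")
        fh.write(f"mse\t{result.mse:.8g}\n")
        fh.write(f"n_points\t{result.n_points}\n")
        fh.write(f"frozen\t{result.frozen}\n")
    pred = transport.predict_cohort(cohort, result.params, aggregate="group_mean")
    rows = []
    for label, series in pred["predictions"].items():
        obs = pred["observed"][label]
        for t, (ph, oh) in enumerate(zip(series, obs)):
            rows.append({"group": label, "frame": t, "predicted": ph, "observed": oh})
    pd.DataFrame(rows).to_csv(out / "fit_transport_groups.csv", index=False)
    return {"c1": result.params.c1, "gamma": result.params.gamma, "mse": result.mse}


def _stage_markers(cfg: dict, out: Path, seed: int) -> dict:
    cohort = _require_cohort(out, cfg)
    cohort, qc_report = markers.qc_filter(cohort, r_min=cfg.get("qc_r_min", 0.7))
    qc_report.to_csv(out / "markers_qc.csv", index=False)
    channels = cfg.get("channels", ["i_nuc", "nuc_area", "i_cyt"])
    frames = []
    for ch in channels:
        cs = markers.correlation_series(
            cohort, ch, min_cells=cfg.get("min_cells", 25)
        )
        df = cs.to_frame()
        df.insert(0, "channel", ch)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(out / "markers_correlation.csv", index=False)
    gframes = []
    for ch in channels:
        short, long_ = markers.group_series(
            cohort, ch,
            rls_threshold=cfg.get("rls_threshold", 15),
            normalize=cfg.get("normalize", True),
            min_alive=cfg.get("min_alive", 25),
        )
        for gs in (short, long_):
            df = gs.to_frame()
            df.insert(0, "channel", ch)
            gframes.append(df)
    pd.concat(gframes, ignore_index=True).to_csv(out / "markers_groups.csv", index=False)
    return {"channels": channels, "n_cells_after_qc": cohort.n_cells}


def _stage_granger(cfg: dict, out: Path, seed: int) -> dict:
    marker1 = cfg.get("marker1")
    marker2 = cfg.get("marker2")
    if not marker1 or not marker2:
        raise ConfigError("granger stage needs two markers (marker1 and marker2)")
    if marker1 == marker2:
        raise ConfigError("granger stage needs two distinct markers")
    cohort = _require_cohort(out, cfg)
    alive = cohort.alive_matrix()
    est = granger.GrangerTemporalOrdering(
        min_cells=cfg.get("min_cells", 56),
        random_state=seed,
        frame_step=cfg.get("frame_step", 1),
        max_horizon=cfg.get("max_horizon"),
    ).fit(
        cohort.channel_matrix(marker1),
        cohort.channel_matrix(marker2),
        alive=alive,
    )
    for name, m in (("raw", est.raw_matrix_), ("smoothed", est.matrix_)):
        pd.DataFrame(m.values, index=m.frames, columns=m.frames).to_csv(
            out / f"granger_{name}.csv"
        )
    pd.DataFrame(
        est.raw_matrix_.excluded.astype(int),
        index=est.raw_matrix_.frames,
        columns=est.raw_matrix_.frames,
    ).to_csv(out / "granger_mask.csv")
    return {"marker1": marker1, "marker2": marker2,
            "n_admissible": int((~est.raw_matrix_.excluded).sum())}


def _stage_segment(cfg: dict, out: Path, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    n_cells = cfg.get("n_cells", 8)
    sigma = cfg.get("sigma", 3.5)
    rows = []
    masks_gmm, masks_ref = [], []
    for i in range(n_cells):
        spec = ImageSpec(
            nucleus_radius=float(rng.uniform(14, 22)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        stack = gen_image_stack(spec)
        corrected, _ = gmmloc.background_subtract(stack.channel1)
        agg = gmmloc.aggregate(corrected)
        cutoff, high, low = gmmloc.gmm_segment(agg, stack.cell_mask, sigma=sigma)
        nucleus = gmmloc.largest_component(high)
        if i == 0:
            gmmloc.write_stack(stack.channel1, out / "segment_cell0_ch1.tif",
                               mask_path=out / "segment_cell0_cellmask.tif")
            import tifffile

            tifffile.imwrite(out / "segment_cell0_nucmask.tif",
                             nucleus.astype("uint8"))
        stats_pair = gmmloc.region_quantify(
            agg, {"nuclear": nucleus, "cytoplasmic": stack.cell_mask & ~nucleus}
        )
        corrected2, _ = gmmloc.background_subtract(stack.channel2)
        agg2 = gmmloc.aggregate(corrected2)
        ref_mask = agg2 >= 0.5 * agg2.max()
        masks_gmm.append(nucleus)
        masks_ref.append(ref_mask)
        nuc_stats = stats_pair["nuclear"]
        cyt_stats = stats_pair["cytoplasmic"]
        rows.append({
            "cell": i,
            "cutoff": cutoff,
            "dice_truth": gmmloc.dice_coefficient(nucleus, stack.nucleus_mask),
            "nuclear_per_area": nuc_stats.per_area if nuc_stats else np.nan,
            "cytoplasmic_per_area": cyt_stats.per_area if cyt_stats else np.nan,
            "nuclear_area": nuc_stats.area if nuc_stats else 0,
        })
    _, areas, r = gmmloc.cross_validate_nuclear(masks_gmm, masks_ref)
    df = pd.DataFrame(rows)
    df.to_csv(out / "segment_stats.csv", index=False)
    areas.to_csv(out / "segment_validation_areas.csv", index=False)
    return {"n_cells": n_cells, "cross_channel_r": r,
            "mean_dice": float(df["dice_truth"].mean())}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "fit-transport": _stage_fit_transport,
    "markers": _stage_markers,
    "granger": _stage_granger,
    "segment": _stage_segment,
}


def run_pipeline(config=None, seed: int = 0, out_dir="results") -> Path:
    """Run the configured stages and write result tables to ``out_dir``.

    ``config`` is a mapping (or YAML path) with an optional ``stages`` list
    and one sub-mapping per stage.  Identical (config, seed) pairs produce
    identical outputs.  Unknown stage names raise :class:`ConfigError`;
    stage failures propagate with the stage label prefixed.
    """
    cfg = _load_config(config)
    stages = cfg.get("stages", list(STAGES))
    for st in stages:
        if st not in STAGES:
            raise ConfigError(f"unknown stage {st!r}; valid stages: {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # per-stage seeds derived from the master seed, stable across stage subsets
    ss = {st: int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
          for i, st in enumerate(STAGES)}
    log: dict = {"seed": seed, "stages": {}}
    for st in stages:
        stage_cfg = cfg.get(st.replace("-", "_"), cfg.get(st, {})) or {}
        try:
            summary = _STAGE_FN[st](stage_cfg, out, ss[st])
        except Exception as exc:
            raise type(exc)(f"[stage {st}] {exc}") from exc
        log["stages"][st] = {"params": stage_cfg, "summary": summary}
    with open(out / "run_log.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return out
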