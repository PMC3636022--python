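"""File formats and the demo pipeline.

All positions are stored in nm; a single flag converts pixel inputs at
64 nm/px.  Scalar results go to JSON, curves and point clouds to CSV,
images to TIFF.  Every result bundle embeds the seed, a config hash and the
package version.
"""

from __future__ import annotations

import hashlib
import json

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .spt import (TrajectoryEnsemble, REQUIRED_COLUMNS, PIXEL_NM,
                  filter_trajectories, elongation_correction, msd,
                  estimate_D, partition_by_intensity, stokes_einstein_fit,
                  initial_position_histogram)
from .pole_density import rho_profile, classify_localization
from . import synthetic

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_sim_record",
    "load_config",
    "run_pipeline",
    "PipelineError",
]


class PipelineError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


def read_trajectories(path, pixels: bool = False,
                      sampling: str = "LF") -> TrajectoryEnsemble:
    """Read a trajectory CSV and validate it.

    Required columns: trajectory_id, cell_id, frame, t_s, x_nm, y_nm,
    half_length_nm, intensity.  With ``pixels=True`` the position and
    half-length columns are interpreted as pixels and converted at 64 nm/px.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} missing columns: {missing}")
    if (df["half_length_nm"] <= 0).any():
        raise ValueError("non-positive cell half-length")
    for tid, g in df.groupby("trajectory_id", sort=False):
        if len(g) > 1 and np.diff(g["t_s"].to_numpy()).min() <= 0:
            raise ValueError(f"non-increasing times in trajectory {tid}")
    if pixels:
        for col in ("x_nm", "y_nm", "half_length_nm"):
            df[col] = df[col] * PIXEL_NM
    return TrajectoryEnsemble(df, sampling=sampling)


def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    ensemble.data.to_csv(path, index=False, float_format="%.12g")


def write_sim_record(record, out_dir, thresholds=(30,)) -> None:
    """SimRecord to CSV (one row per sampled time per aggregate) + JSON summary."""
    from .simulate import first_detections
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for step, cnt, pos in zip(record.sample_steps, record.counts,
                              record.positions):
        for aid in range(len(cnt)):
            rows.append((int(step), aid, int(cnt[aid]), *pos[aid]))
    pd.DataFrame(rows, columns=["time_step", "id", "count", "x", "y", "z"]) \
        .to_csv(out / "record.csv", index=False, float_format="%.6g")
    summary = {
        "seed": record.seed,
        "version": __version__,
        "n_particles": record.n_particles,
        "first_detections": {
            str(t): list(map(float, first_detections(record, t)))
            for t in thresholds
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the requested stages in dependency order and write results.

    Stages (selected via ``config['stages']``, default all):
    ``synth_trajectories`` -> ``msd_analysis`` -> ``stokes_fit`` and
    ``clouds`` -> ``rho``.  Any stage failure aborts with the stage name.
    Outputs embed seed, config hash and package version; re-running with the
    same config and seed reproduces them exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages",
                        ["synth_trajectories", "msd_analysis", "stokes_fit",
                         "clouds", "rho"])
    results = {"seed": seed, "config_hash": _config_hash(config),
               "version": __version__}
    ensemble = None
    class_curves = None

    if "synth_trajectories" in stages:
        try:
            cfg = synthetic.SynthTrajectoryConfig(
                seed=seed, **config.get("trajectories", {}))
            ensemble, truth = synthetic.gen_trajectories(cfg)
            write_trajectories(ensemble, out / "trajectories.csv")
            synthetic.write_truth(truth, out / "trajectories_truth.json")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("synth_trajectories", e)

    if "msd_analysis" in stages:
        if ensemble is None:
            traj_path = config.get("trajectories_csv")
            if not traj_path:
                raise PipelineError("msd_analysis",
                                    ValueError("no trajectory input available"))
            ensemble = read_trajectories(traj_path)
        try:
            ens = filter_trajectories(ensemble)
            corr = elongation_correction(ens)
            classes = partition_by_intensity(ens)
            class_curves = []
            rows = []
            for i, cls in enumerate(classes):
                if len(cls) == 0:
                    continue
                cx = msd(cls, "x", correction=elongation_correction(cls))
                cy = msd(cls, "y")
                class_curves.append((i, cx, cy))
                for curve in (cx, cy):
                    for lag, val in zip(curve.lags, curve.values):
                        rows.append((i, curve.axis, lag, val))
            pd.DataFrame(rows, columns=["class", "axis", "lag_s", "msd_nm2"]) \
                .to_csv(out / "msd.csv", index=False, float_format="%.12g")
            edges, hist = initial_position_histogram(ens)
            results["initial_position_histogram"] = hist.tolist()
            results["n_trajectories"] = len(ens)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("msd_analysis", e)

    if "stokes_fit" in stages:
        if class_curves is None:
            raise PipelineError("stokes_fit",
                                ValueError("stokes_fit requires msd_analysis"))
        try:
            window = float(config.get("d_window_seconds", 15.0))
            Ds, rs = [], []
            truth_r = config.get("class_radii",
                                 list(synthetic.CLASS_RADII))
            for (i, cx, cy) in class_curves:
                Dx, _ = estimate_D(cx, window)
                Dy, _ = estimate_D(cy, window)
                Ds.append((Dx + Dy) / 2)
                rs.append(truth_r[i])
            fit = stokes_einstein_fit(rs, Ds, mode="linear_inv_r")
            results["stokes_C0_nm3_s"] = fit.c0
            results["class_D_nm2_s"] = Ds
        except Exception as e:  # noqa: BLE001
            raise PipelineError("stokes_fit", e)

    if "clouds" in stages or "rho" in stages:
        try:
            n = int(config.get("cloud_n", 10_000))
            rho_out = {}
            for off, kind in enumerate(("bulk", "membrane", "control2d")):
                pts, truth = synthetic.gen_position_clouds(
                    kind, n=n, rng=np.random.default_rng(seed + 101 * (off + 1)))
                pts.to_csv(out / f"cloud_{kind}.csv", index=False,
                           float_format="%.6g")
                prof = rho_profile(pts.to_numpy())
                label, slope, p = classify_localization(prof)
                rho_out[kind] = {"classification": label, "slope": slope,
                                 "p_value": p}
            results["rho"] = rho_out
        except Exception as e:  # noqa: BLE001
            raise PipelineError("rho", e)

    (out / "results.json").write_text(json.dumps(results, indent=2,
                                                 default=float))
    return results
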