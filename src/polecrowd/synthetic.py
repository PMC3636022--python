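"""Synthetic data generators with known ground truth.

Everything the analysis stack consumes can be generated here: confined
Brownian trajectory ensembles with cell-elongation drift and localization
noise, pole position clouds (3D bulk / 3D membrane / 2D control), and
Gaussian-PSF spot images.  Each generator is deterministic given its seed
and returns (or writes) a ground-truth sidecar alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import pole_density
from .confined import CLASS_RADII, CLASS_D, _reflected_axis_positions
from .spt import TrajectoryEnsemble, CLASS_BOUNDARIES

__all__ = [
    "SynthTrajectoryConfig",
    "gen_trajectories",
    "gen_position_clouds",
    "gen_spot_images",
]

# intensity intervals per class: the interior class edges plus synthetic
# outer limits for the open-ended first and last classes
_INTENSITY_EDGES = (800.0, *CLASS_BOUNDARIES, 8000.0)


@dataclass
class SynthTrajectoryConfig:
    """Conditions emulated by the trajectory generator.

    Defaults reproduce the study conditions: five aggregate size classes
    with the estimated (r_i, D_i), confinement box L_X = 650 nm and
    L_YZ = 750 nm, LF sampling (one frame per 3 s for 5 min) or HF (0.6 s
    for 2 min), linear cell half-length growth of 0.05 um/min, and Gaussian
    localization noise of 30 nm per coordinate.
    """

    class_radii: tuple = CLASS_RADII
    class_D: tuple = CLASS_D
    L_X: float = 650.0
    L_YZ: float = 750.0
    mode: str = "LF"                      # "LF" (3 s, 300 s) | "HF" (0.6 s, 120 s)
    growth_nm_per_s: float = 50.0 / 60.0  # 0.05 um/min
    sigma_loc: float = 30.0
    n_per_class: int = 60
    initial_half_length: float = 1500.0
    seed: int = 0

    @property
    def frame_interval(self) -> float:
        return {"LF": 3.0, "HF": 0.6}[self.mode]

    @property
    def duration(self) -> float:
        return {"LF": 300.0, "HF": 120.0}[self.mode]


def gen_trajectories(config: SynthTrajectoryConfig, rng=None):
    """Generate a confined-Brownian trajectory ensemble with known truth.

    Each trajectory is a sphere of its class radius diffusing in the truth
    box (fixed-step walk, specular walls), observed at the acquisition
    cadence.  The x coordinate rides on the growing cell pole (the pole
    recedes at the elongation rate, dragging the confinement region with
    it), and Gaussian localization noise is added per coordinate.  Returns
    ``(TrajectoryEnsemble, truth_dict)``.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    interval = config.frame_interval
    n_frames = int(round(config.duration / interval)) + 1
    rows = []
    tid = 0
    for ci, (r, D) in enumerate(zip(config.class_radii, config.class_D)):
        n = config.n_per_class
        # substeps keep single steps below half the sphere radius
        dt_max = (r / 2.0) ** 2 / (6.0 * D)
        n_sub = int(np.clip(np.ceil(interval / dt_max), 1, 256))
        dt = interval / n_sub
        d = np.sqrt(6.0 * D * dt)
        total_steps = (n_frames - 1) * n_sub

        c = rng.uniform(-1, 1, (total_steps, n))
        theta = rng.uniform(0, 2 * np.pi, (total_steps, n))
        s = np.sqrt(1 - c * c)
        inc_x = d * s * np.cos(theta)
        inc_y = d * s * np.sin(theta)

        x0 = rng.uniform(r, config.L_X - r, n)
        y0 = rng.uniform(r, config.L_YZ - r, n)
        x_loc = _reflected_axis_positions(x0, inc_x, r, config.L_X - r)
        y_loc = _reflected_axis_positions(y0, inc_y, r, config.L_YZ - r)
        x_frames = np.vstack([x0, x_loc[n_sub - 1::n_sub]])
        y_frames = np.vstack([y0, y_loc[n_sub - 1::n_sub]])

        t = np.arange(n_frames) * interval
        half_len = config.initial_half_length + config.growth_nm_per_s * t
        # absolute long-axis position: pole-anchored confinement region
        x_abs = half_len[:, None] - config.L_X + x_frames
        y_abs = y_frames - config.L_YZ / 2.0
        x_abs = x_abs + rng.normal(0.0, config.sigma_loc, x_abs.shape)
        y_abs = y_abs + rng.normal(0.0, config.sigma_loc, y_abs.shape)

        lo, hi = _INTENSITY_EDGES[ci], _INTENSITY_EDGES[ci + 1]
        inten = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
        for j in range(n):
            for f in range(n_frames):
                rows.append((tid, tid, f, t[f], x_abs[f, j], y_abs[f, j],
                             half_len[f], inten[j]))
            tid += 1
    df = pd.DataFrame(rows, columns=["trajectory_id", "cell_id", "frame",
                                     "t_s", "x_nm", "y_nm",
                                     "half_length_nm", "intensity"])
    truth = {
        "config": asdict(config),
        "class_radii": list(config.class_radii),
        "class_D": list(config.class_D),
        "L_X": config.L_X,
        "L_YZ": config.L_YZ,
        "growth_nm_per_s": config.growth_nm_per_s,
        "sigma_loc": config.sigma_loc,
        "n_trajectories": tid,
    }
    return TrajectoryEnsemble(df, sampling=config.mode), truth


def gen_position_clouds(kind: str, n: int = 10_000,
                        a_x: float = pole_density.DEFAULT_AX,
                        a_y: float = pole_density.DEFAULT_AY,
                        a_z: float | None = None, rng=None):
    """Generate a 2D projected position cloud of the requested kind.

    ``bulk``: uniform in the 3D semi-ellipsoidal pole; ``membrane``: uniform
    on its curved surface; ``control2d``: uniform directly in the projected
    2D semi-ellipse.  Returns ``(DataFrame[x_nm, y_nm], truth_dict)``.
    """
    a_z = a_y if a_z is None else a_z
    rng = np.random.default_rng(rng)
    if kind == "bulk":
        pts = pole_density.sample_bulk_semi_ellipsoid(n, a_x, a_y, a_z, rng)
    elif kind == "membrane":
        pts = pole_density.sample_membrane_semi_ellipsoid(n, a_x, a_y, a_z, rng)
    elif kind == "control2d":
        pts = pole_density.sample_uniform_semi_ellipse(n, a_x, a_y, rng)
    else:
        raise ValueError(f"unknown cloud kind {kind!r}")
    df = pd.DataFrame(pts, columns=["x_nm", "y_nm"])
    truth = {"kind": kind, "n": n, "a_x": a_x, "a_y": a_y, "a_z": a_z}
    return df, truth


def gen_spot_images(n_spots: int, sigma: float = 3.0,
                    peak_to_noise: float = 10.0, shape=(200, 200),
                    background: float = 100.0, noise_sigma: float = 10.0,
                    rng=None):
    """Synthetic spot image: background + Gaussians at random subpixel
    centres + additive Gaussian noise (``peak_to_noise = inf`` for noiseless).

    Spot centres sit on a jittered grid with >= 6 sigma separation; a layout
    that cannot host ``n_spots`` raises.  Returns ``(image, truth_df)`` where
    the truth lists exact centres and amplitudes.
    """
    rng = np.random.default_rng(rng)
    margin = int(np.ceil(3 * sigma)) + 4
    pitch = int(np.ceil(6 * sigma)) + 2
    grid_r = np.arange(margin, shape[0] - margin, pitch)
    grid_c = np.arange(margin, shape[1] - margin, pitch)
    capacity = len(grid_r) * len(grid_c)
    if n_spots > capacity:
        raise ValueError(f"layout holds at most {capacity} spots, "
                         f"{n_spots} requested")
    cells = [(r, c) for r in grid_r for c in grid_c]
    chosen = rng.choice(len(cells), size=n_spots, replace=False)
    amp = peak_to_noise * noise_sigma if np.isfinite(peak_to_noise) else 100.0
    image = np.full(shape, background, dtype=float)
    rows = []
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for k in chosen:
        r0, c0 = cells[k]
        center = (r0 + rng.uniform(-1, 1), c0 + rng.uniform(-1, 1))
        image += amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                              / (2 * sigma**2))
        rows.append((center[0], center[1], amp))
    if np.isfinite(peak_to_noise):
        image += rng.normal(0.0, noise_sigma, shape)
    truth = pd.DataFrame(rows, columns=["row_px", "col_px", "amplitude"])
    return image, truth


def write_truth(truth: dict, path) -> None:
    """Write a ground-truth sidecar as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float))
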