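"""Trajectory statistics for single-particle tracking of fluorescent foci.

Operates on ensembles of per-frame records (time, long-axis position x,
short-axis position y, cell half-length, fluorescence intensity) and computes
elongation-corrected mean displacements, mean-squared displacements (MSD),
diffusion constants, anomalous exponents, intensity-class partitions and
Stokes-Einstein fits of the size/mobility relation.

Conventions: positions in nm, times in seconds; the long axis is x with the
poles at +-L(t) where L(t) is the cell half-length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TrajectoryEnsemble",
    "MSDCurve",
    "DriftCorrection",
    "StokesFit",
    "CLASS_BOUNDARIES",
    "PIXEL_NM",
    "filter_trajectories",
    "elongation_correction",
    "mean_displacement",
    "msd",
    "estimate_D",
    "anomalous_exponent",
    "partition_by_intensity",
    "stokes_einstein_fit",
    "initial_position_histogram",
]

#: Fluorescence-intensity class boundaries separating the five aggregate
#: size classes (arbitrary units); bins are half-open [lo, hi).
CLASS_BOUNDARIES = (1459.0, 2015.0, 2905.0, 4727.0)

#: Camera pixel size used to convert pixel inputs to nm.
PIXEL_NM = 64.0

REQUIRED_COLUMNS = ("trajectory_id", "cell_id", "frame", "t_s", "x_nm",
                    "y_nm", "half_length_nm", "intensity")


@dataclass
class TrajectoryEnsemble:
    """Per-frame records grouped into trajectories.

    ``data`` holds one row per frame with the standard columns; ``sampling``
    labels the acquisition cadence ("LF" 0.33 Hz or "HF" 1.67 Hz).
    """

    data: pd.DataFrame
    sampling: str = "LF"

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing trajectory columns: {missing}")
        self.data = self.data.sort_values(["trajectory_id", "t_s"]).reset_index(drop=True)
        for tid, g in self.data.groupby("trajectory_id"):
            dt = np.diff(g["t_s"].to_numpy())
            if len(dt) and dt.min() <= 0:
                raise ValueError(f"non-increasing times in trajectory {tid}")

    def __len__(self):
        return self.data["trajectory_id"].nunique()

    def groups(self):
        return self.data.groupby("trajectory_id", sort=True)

    def column_matrix(self, column: str) -> np.ndarray:
        """(n_traj, n_frames) matrix aligned on frame index, NaN-padded."""
        series = [g[column].to_numpy() for _, g in self.groups()]
        width = max(len(s) for s in series)
        out = np.full((len(series), width), np.nan)
        for i, s in enumerate(series):
            out[i, :len(s)] = s
        return out

    def lag_times(self) -> np.ndarray:
        """Common lag-time grid (relative to each trajectory's first frame)."""
        rel = [g["t_s"].to_numpy() - g["t_s"].iloc[0] for _, g in self.groups()]
        width = max(len(r) for r in rel)
        out = np.full((len(rel), width), np.nan)
        for i, r in enumerate(rel):
            out[i, :len(r)] = r
        return np.nanmedian(out, axis=0)


@dataclass
class MSDCurve:
    """Mean-squared displacement versus lag time for one axis/class."""

    lags: np.ndarray            # s
    values: np.ndarray          # nm^2
    counts: np.ndarray = None   # trajectories contributing per lag
    ci95: np.ndarray = None     # 95% half-widths, nm^2
    axis: str = "x"
    label: str = ""

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.counts is None:
            self.counts = np.full(len(self.lags), np.nan)
        if self.ci95 is None:
            self.ci95 = np.full(len(self.lags), np.nan)


@dataclass
class DriftCorrection:
    """Per-lag correction u_c(t): cumulative mean elongation for x, constant
    recentring offset for y."""

    lags: np.ndarray
    u_c: np.ndarray
    axis: str = "x"


@dataclass
class StokesFit:
    """Fit of the diffusion-constant/size relation D(r) = C0 / r**b."""

    c0: float
    b: float = 1.0
    intercept: float = 0.0
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    mode: str = "linear_inv_r"


def filter_trajectories(ensemble: TrajectoryEnsemble,
                        min_frames: int = 10) -> TrajectoryEnsemble:
    """Drop trajectories shorter than ``min_frames`` frames."""
    sizes = ensemble.data.groupby("trajectory_id").size()
    keep = sizes.index[sizes >= min_frames]
    return TrajectoryEnsemble(
        ensemble.data[ensemble.data["trajectory_id"].isin(keep)].copy(),
        sampling=ensemble.sampling)


def elongation_correction(ensemble: TrajectoryEnsemble) -> DriftCorrection:
    """Cumulative ensemble-mean half-length increment, the x-axis drift term.

    u_c(t_k) = sum_{j<k} <L(t_{j+1}) - L(t_j)> where the average runs over
    the trajectories still recorded at frame j+1.  This removes the ballistic
    component that cell elongation imposes on pole-proximal foci.
    """
    if ensemble.data["half_length_nm"].isna().any():
        raise ValueError("half_length_nm contains missing values")
    L = ensemble.column_matrix("half_length_nm")
    inc = np.diff(L, axis=1)
    mean_inc = np.nanmean(inc, axis=0)
    mean_inc = np.nan_to_num(mean_inc)
    u_c = np.concatenate([[0.0], np.cumsum(mean_inc)])
    return DriftCorrection(lags=ensemble.lag_times(), u_c=u_c, axis="x")


def _displacements(ensemble, axis, correction):
    col = {"x": "x_nm", "y": "y_nm"}[axis]
    u = ensemble.column_matrix(col)
    disp = u - u[:, :1]
    if isinstance(correction, DriftCorrection):
        disp = disp - correction.u_c[None, :disp.shape[1]]
    return disp


def mean_displacement(ensemble: TrajectoryEnsemble, axis: str = "x",
                      correction: DriftCorrection | None = None):
    """Corrected mean displacement <u(t) - u(0) - u_c(t)> with 95% CI.

    For the y axis the conventional correction is the time-average of the
    uncorrected series (recentring it on zero); pass ``correction="recenter"``
    to apply it.
    """
    recenter = correction == "recenter"
    disp = _displacements(ensemble, axis, None if recenter else correction)
    mean = np.nanmean(disp, axis=0)
    n = np.sum(~np.isnan(disp), axis=0)
    se = np.nanstd(disp, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    if recenter:
        mean = mean - np.nanmean(mean)
    return ensemble.lag_times(), mean, 1.96 * se


def msd(ensemble: TrajectoryEnsemble, axis: str = "x",
        correction: DriftCorrection | None = None,
        mode: str = "origin") -> MSDCurve:
    """Ensemble MSD.

    ``mode="origin"`` (default) measures displacement from each trajectory's
    first frame, MSD(t_j) = <(u(t_j) - u(0) - u_c(t_j))^2>; ``mode="sliding"``
    averages over all start frames at each lag (time-averaged estimator).
    """
    col = {"x": "x_nm", "y": "y_nm"}[axis]
    u = ensemble.column_matrix(col)
    n_lags = u.shape[1]
    u_c = correction.u_c[:n_lags] if isinstance(correction, DriftCorrection) \
        else np.zeros(n_lags)
    if mode == "origin":
        sq = (u - u[:, :1] - u_c[None, :]) ** 2
    elif mode == "sliding":
        sq = np.full_like(u, np.nan)
        sq[:, 0] = 0.0
        for k in range(1, n_lags):
            d = u[:, k:] - u[:, :-k] - (u_c[k:] - u_c[:-k])[None, :]
            sq[:, k] = np.nanmean(d ** 2, axis=1)
    else:
        raise ValueError(f"unknown MSD mode {mode!r}")
    values = np.nanmean(sq, axis=0)
    counts = np.sum(~np.isnan(sq), axis=0)
    se = np.nanstd(sq, axis=0, ddof=1) / np.sqrt(np.maximum(counts, 1))
    return MSDCurve(lags=ensemble.lag_times(), values=values, counts=counts,
                    ci95=1.96 * se, axis=axis)


def estimate_D(curve: MSDCurve, window_seconds: float = 15.0):
    """Least-squares line MSD = 2 D t + c over lags in (0, window].

    The intercept c absorbs the static localization-noise floor (for a 1D
    coordinate with noise sigma, c ~ 2 sigma^2).  Returns (D, c).
    """
    sel = (curve.lags > 0) & (curve.lags <= window_seconds) \
        & np.isfinite(curve.values)
    if sel.sum() < 3:
        raise ValueError("need at least 3 lags inside the fit window")
    slope, intercept = np.polyfit(curve.lags[sel], curve.values[sel], 1)
    return slope / 2.0, intercept


def anomalous_exponent(curve: MSDCurve, window_seconds: float = 21.0) -> float:
    """Slope alpha of log MSD vs log t over the initial window (MSD ~ t^alpha)."""
    sel = (curve.lags > 0) & (curve.lags <= window_seconds) \
        & np.isfinite(curve.values)
    if sel.sum() < 2:
        raise ValueError("need at least 2 lags inside the fit window")
    if np.any(curve.values[sel] <= 0):
        raise ValueError("non-positive MSD values inside the fit window")
    alpha, _ = np.polyfit(np.log(curve.lags[sel]), np.log(curve.values[sel]), 1)
    return alpha


def trajectory_initial_intensity(ensemble: TrajectoryEnsemble,
                                 n_initial: int = 5) -> pd.Series:
    """Initial median fluorescence per trajectory (median of the first frames)."""
    return ensemble.data.groupby("trajectory_id")["intensity"] \
        .apply(lambda s: float(np.median(s.iloc[:n_initial])))


def partition_by_intensity(ensemble: TrajectoryEnsemble,
                           boundaries=CLASS_BOUNDARIES):
    """Split the ensemble into len(boundaries)+1 classes of increasing initial
    median fluorescence.  Bins are half-open [lo, hi): a trajectory exactly at
    a boundary joins the upper class.  Returns a list of ensembles."""
    inten = trajectory_initial_intensity(ensemble)
    edges = np.concatenate([[-np.inf], np.asarray(boundaries, float), [np.inf]])
    classes = []
    for k in range(len(edges) - 1):
        ids = inten.index[(inten >= edges[k]) & (inten < edges[k + 1])]
        sub = ensemble.data[ensemble.data["trajectory_id"].isin(ids)].copy()
        classes.append(TrajectoryEnsemble(sub, sampling=ensemble.sampling))
    return classes


def stokes_einstein_fit(radii, diffusion, mode: str = "linear_inv_r") -> StokesFit:
    """Fit D(r) against the Stokes-Einstein form.

    - ``linear_inv_r``: OLS of D on 1/r with intercept; slope reported as C0.
    - ``through_origin``: OLS of D on 1/r without intercept.
    - ``power``: unweighted nonlinear least squares of D = C0 / r**b.
    """
    r = np.asarray(radii, dtype=float)
    D = np.asarray(diffusion, dtype=float)
    if len(r) < 2 and mode != "through_origin":
        raise ValueError("need at least 2 (r, D) pairs")
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    if mode == "linear_inv_r":
        X = np.vstack([np.ones_like(r), 1.0 / r]).T
        coef, *_ = np.linalg.lstsq(X, D, rcond=None)
        resid = D - X @ coef
        return StokesFit(c0=float(coef[1]), b=1.0, intercept=float(coef[0]),
                         residuals=resid, mode=mode)
    if mode == "through_origin":
        inv = 1.0 / r
        c0 = float(np.dot(inv, D) / np.dot(inv, inv))
        return StokesFit(c0=c0, b=1.0, residuals=D - c0 * inv, mode=mode)
    if mode == "power":
        popt, _ = optimize.curve_fit(lambda r, c0, b: c0 / r**b, r, D,
                                     p0=[float(np.median(D * r)), 1.0],
                                     maxfev=20000)
        c0, b = popt
        if c0 <= 0:
            raise ValueError("degenerate power-law fit (C0 <= 0)")
        return StokesFit(c0=float(c0), b=float(b), residuals=D - c0 / r**b,
                         mode=mode)
    raise ValueError(f"unknown fit mode {mode!r}")


def initial_position_histogram(ensemble: TrajectoryEnsemble, n_bins: int = 25):
    """Histogram of first-frame x positions rescaled by the cell half-length.

    The poles map to -1 and +1.  Returns (bin_edges, unit-mass histogram).
    """
    firsts = ensemble.data.groupby("trajectory_id").head(1)
    L0 = firsts["half_length_nm"].to_numpy()
    if np.any(L0 <= 0):
        raise ValueError("non-positive cell half-length at first frame")
    rel = firsts["x_nm"].to_numpy() / L0
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(np.clip(rel, -1, 1), bins=edges)
    return edges, hist / max(hist.sum(), 1)
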