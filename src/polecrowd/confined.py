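"""Confined-diffusion simulation and evolutionary-strategy parameter fit.

The observed class-wise MSD curves saturate because each aggregate is
confined: along the cell long axis by the nucleoid-delimited pole region of
length L_X, and transversally by the membrane (L_Y = L_Z = L_YZ).  A sphere
of radius r diffusing in a reflective box explores the interval
[r, L - 2r + r] per axis, so the long-time MSD plateau per axis is the
variance of the uniform distribution on an interval of length L - 2r, i.e.
(L - 2r)^2 / 6, while the short-time slope is 2 D.

``fit`` recovers the 12-parameter vector {L_X, L_YZ, r_1..5, D_1..5} by
matching simulated to observed curves with CMA-ES, separately on the x and
y data (the transverse box size does not enter the x-direction MSD and vice
versa), then averages the shared parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cmaes import minimize as cma_minimize

__all__ = [
    "FitParams",
    "FitResult",
    "simulate_confined_msd",
    "saturation_closed_form",
    "cost",
    "fit",
    "CLASS_RADII",
    "CLASS_D",
]

#: Per-class aggregate radii (nm) and diffusion constants (nm^2/s) estimated
#: for the five fluorescence-intensity classes (smallest to largest foci).
CLASS_RADII = (54.0, 105.0, 141.0, 174.0, 273.0)
CLASS_D = (837.0, 550.0, 437.0, 261.0, 92.0)


@dataclass
class FitParams:
    """The 12 confined-diffusion parameters (nm, nm^2/s)."""

    L_X: float = 650.0
    L_YZ: float = 750.0
    radii: tuple = CLASS_RADII
    D: tuple = CLASS_D

    def validate(self):
        vals = [self.L_X, self.L_YZ, *self.radii, *self.D]
        if any(v <= 0 for v in vals):
            raise ValueError("all parameters must be positive")
        if any(2 * r >= min(self.L_X, self.L_YZ) for r in self.radii):
            raise ValueError("sphere diameter exceeds the confining box")

    def to_vector(self, axis: str) -> np.ndarray:
        L = self.L_X if axis == "x" else self.L_YZ
        return np.array([L, *self.radii, *self.D], dtype=float)


@dataclass
class FitResult:
    params_x: FitParams
    params_y: FitParams
    params_mean: FitParams
    params_range: dict
    cost_x: float
    cost_y: float
    trace_x: np.ndarray
    trace_y: np.ndarray


def saturation_closed_form(L: float, r: float) -> float:
    """Long-time MSD plateau (L - 2r)^2 / 6 of a reflected walk per axis."""
    if L <= 2 * r:
        raise ValueError("sphere does not fit: L <= 2r")
    return (L - 2.0 * r) ** 2 / 6.0


def _reflected_axis_positions(x0, increments, lo, hi):
    """Fold the free cumulative path into [lo, hi].

    Specular reflection of a piecewise-linear path equals the triangle-wave
    fold of the unreflected path, so the whole (n_steps x n_particles) block
    vectorises.
    """
    free = x0[None, :] + np.cumsum(increments, axis=0)
    width = hi - lo
    t = np.mod(free - lo, 2.0 * width)
    return lo + np.where(t > width, 2.0 * width - t, t)


def simulate_confined_msd(L_X: float, L_YZ: float, r: float, D: float,
                          n_particles: int = 5000,
                          sample_interval: float = 3.0,
                          duration: float = 300.0,
                          rng=None, max_substeps: int = 256,
                          step_fraction: float = 0.5):
    """Simulate reflective-box diffusion of spheres and return the MSD pair.

    Fixed-step-length random walks (step sqrt(6 D dt), isotropic direction)
    in a box L_X x L_YZ x L_YZ with no obstacles and no aggregation; the
    sphere centre is confined to [r, L - r] per axis.  Positions are sampled
    every ``sample_interval`` seconds (0.33 Hz emulates the low-frequency
    acquisition) and MSDs use a single time origin.  Returns
    ``(lags, msd_x, msd_y)``.
    """
    if min(L_X, L_YZ) <= 2 * r:
        raise ValueError("sphere does not fit in the box")
    rng = np.random.default_rng(rng)
    # substep small enough that one step stays below step_fraction * r
    dt_max = (step_fraction * r) ** 2 / (6.0 * D) if r > 0 else sample_interval
    n_sub = int(np.clip(np.ceil(sample_interval / dt_max), 1, max_substeps))
    dt = sample_interval / n_sub
    d = np.sqrt(6.0 * D * dt)
    n_frames = int(round(duration / sample_interval))

    lims = np.array([[r, L_X - r], [r, L_YZ - r], [r, L_YZ - r]])
    x0 = np.column_stack([rng.uniform(lo, hi, n_particles) for lo, hi in lims])
    sampled = np.empty((n_frames + 1, n_particles, 2))
    sampled[0] = x0[:, :2]
    free = x0.copy()
    for f in range(n_frames):
        c = rng.uniform(-1.0, 1.0, (n_sub, n_particles))
        theta = rng.uniform(0.0, 2.0 * np.pi, (n_sub, n_particles))
        s = np.sqrt(1.0 - c * c)
        free[:, 0] += (d * s * np.cos(theta)).sum(axis=0)
        free[:, 1] += (d * s * np.sin(theta)).sum(axis=0)
        free[:, 2] += (d * c).sum(axis=0)
        for ax in range(2):
            lo, hi = lims[ax]
            width = hi - lo
            t = np.mod(free[:, ax] - lo, 2.0 * width)
            sampled[f + 1, :, ax] = lo + np.where(t > width, 2 * width - t, t)

    lags = np.arange(n_frames + 1) * sample_interval
    disp = sampled - sampled[:1]
    msd_x = (disp[:, :, 0] ** 2).mean(axis=1)
    msd_y = (disp[:, :, 1] ** 2).mean(axis=1)
    return lags, msd_x, msd_y


def cost(params: FitParams, observed: dict, axis_mode: str = "joint",
         n_particles: int = 5000, seed: int = 0,
         step_fraction: float = 0.5, max_substeps: int = 256) -> float:
    """Sum of squared residuals between simulated and observed MSD curves.

    ``observed`` maps class index (0..4) to a dict with keys ``lags``,
    ``msd_x``, ``msd_y`` (nm^2 on a common lag grid).  Simulated curves are
    interpolated onto the observed lags.  A fixed ``seed`` gives common
    random numbers across evaluations so the optimizer sees a deterministic
    landscape.
    """
    total = 0.0
    for i, obs in observed.items():
        r, D = params.radii[i], params.D[i]
        lags = np.asarray(obs["lags"], dtype=float)
        sim_lags, sx, sy = simulate_confined_msd(
            params.L_X, params.L_YZ, r, D, n_particles=n_particles,
            sample_interval=float(lags[1] - lags[0]) if len(lags) > 1 else 3.0,
            duration=float(lags[-1]),
            rng=np.random.default_rng(seed + 1000 * i),
            step_fraction=step_fraction, max_substeps=max_substeps)
        if axis_mode in ("x", "joint"):
            total += float(np.sum((np.interp(lags, sim_lags, sx)
                                   - np.asarray(obs["msd_x"])) ** 2))
        if axis_mode in ("y", "joint"):
            total += float(np.sum((np.interp(lags, sim_lags, sy)
                                   - np.asarray(obs["msd_y"])) ** 2))
    return total


def _heuristic_init(observed, axis: str) -> np.ndarray:
    """Start the search from curve-derived guesses.

    D_i from the early-lag slope (free-diffusion limit), the available width
    w_i = L - 2 r_i from the plateau via w = sqrt(6 * plateau); the box size
    is seeded slightly above the largest width and the radii follow as
    r_i = (L - w_i) / 2.
    """
    key = "msd_x" if axis == "x" else "msd_y"
    D0, widths = [], []
    for i in sorted(observed):
        lags = np.asarray(observed[i]["lags"], float)
        vals = np.asarray(observed[i][key], float)
        k = min(5, len(lags) - 1)
        slope = np.polyfit(lags[1:k + 1], vals[1:k + 1], 1)[0]
        D0.append(max(slope / 2.0, 1.0))
        plateau = max(float(np.mean(vals[-max(len(vals) // 4, 1):])), 1.0)
        widths.append(np.sqrt(6.0 * plateau))
    L0 = 1.15 * max(widths)
    r0 = np.maximum((L0 - np.asarray(widths)) / 2.0, 5.0)
    return np.array([L0, *r0, *D0])


def _axis_cost_factory(observed, axis, n_particles, seed,
                       step_fraction=1.0, max_substeps=64):
    scale = max(np.max([np.max(observed[i]["msd_" + axis]) for i in observed]),
                1.0)

    def f(z):
        vec = np.exp(z)
        L = vec[0]
        radii = vec[1:6]
        penalty = 0.0
        for r in radii:
            if 2 * r >= 0.95 * L:
                penalty += 100.0 * scale**2 * (2 * r / L) ** 2
        radii = np.minimum(radii, 0.47 * L)
        p = FitParams(L_X=L, L_YZ=L, radii=tuple(radii), D=tuple(vec[6:11]))
        return cost(p, observed, axis_mode=axis, n_particles=n_particles,
                    seed=seed, step_fraction=step_fraction,
                    max_substeps=max_substeps) + penalty
    return f


def fit(observed: dict, init: FitParams | None = None, popsize: int = 12,
        generations: int = 400, n_particles: int = 5000,
        seed: int = 0, sigma0: float = 0.3,
        step_fraction: float = 1.0, max_substeps: int = 64) -> FitResult:
    """Fit {L_X, L_YZ, r_i, D_i} to observed class-wise MSD curves.

    Runs CMA-ES separately on the x data (which constrains L_X) and the y
    data (which constrains L_YZ); parameters are optimized in log space with
    a penalty keeping 2 r_i < L.  The returned ``params_mean`` averages the
    shared r_i/D_i between the two axis fits; ``params_range`` records their
    min-max spread.  Deterministic given ``seed``.

    Note the structural degeneracy of box-confined diffusion: the MSD
    depends on the box size and sphere radius only through the available
    width L - 2r, so the absolute scale of L and r along the flat direction
    (L + d, r_i + d/2) is fixed by the initial guess, not by the data.  Pass
    ``init`` to anchor it; the default curve-derived guess places L slightly
    above the widest class's plateau width.
    """
    results = {}
    for k, axis in enumerate(("x", "y")):
        if init is not None:
            L = init.L_X if axis == "x" else init.L_YZ
            x0 = np.array([L, *init.radii, *init.D])
        else:
            x0 = _heuristic_init(observed, axis)
        f = _axis_cost_factory(observed, axis, n_particles, seed + 7 * k,
                               step_fraction, max_substeps)
        res = cma_minimize(f, np.log(x0), sigma0, popsize=popsize,
                           generations=generations, seed=seed + 13 * k)
        vec = np.exp(res.x)
        vec[1:6] = np.minimum(vec[1:6], 0.47 * vec[0])
        results[axis] = (vec, res)

    vx, resx = results["x"]
    vy, resy = results["y"]
    mean_r = tuple((vx[1:6] + vy[1:6]) / 2.0)
    mean_D = tuple((vx[6:11] + vy[6:11]) / 2.0)
    p_range = {
        "radii": tuple(zip(np.minimum(vx[1:6], vy[1:6]),
                           np.maximum(vx[1:6], vy[1:6]))),
        "D": tuple(zip(np.minimum(vx[6:11], vy[6:11]),
                       np.maximum(vx[6:11], vy[6:11]))),
    }
    return FitResult(
        params_x=FitParams(L_X=float(vx[0]), L_YZ=float(vy[0]),
                           radii=tuple(vx[1:6]), D=tuple(vx[6:11])),
        params_y=FitParams(L_X=float(vx[0]), L_YZ=float(vy[0]),
                           radii=tuple(vy[1:6]), D=tuple(vy[6:11])),
        params_mean=FitParams(L_X=float(vx[0]), L_YZ=float(vy[0]),
                              radii=mean_r, D=mean_D),
        params_range=p_range,
        cost_x=resx.fun, cost_y=resy.fun,
        trace_x=resx.trace, trace_y=resy.trace)
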