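"""3D individual-based diffusion–aggregation simulator with nucleoid crowding.

Models a rod-shaped bacterium as a box with reflective walls containing two
nucleoid regions densely packed with immobile spherical obstacles.  Monomeric
proteins perform lattice-free fixed-step random walks; moves that would
overlap an obstacle are rejected, which hinders diffusion inside the
nucleoids.  Overlapping proteins aggregate irreversibly with probability
``p_ag`` per encounter; aggregates keep a spherical shape at constant
internal density, so the radius grows as the cube root of the monomer count
and the diffusion constant shrinks according to a Stokes-Einstein law
``D = D0 * r0 / r`` (or an optional steeper power law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

__all__ = [
    "CellDomain",
    "Aggregate",
    "SimConfig",
    "SimRecord",
    "DEFAULT_GEOMETRY",
    "build_domain",
    "init_particles",
    "diffuse_step",
    "merge",
    "step",
    "run",
    "run_ensemble",
    "first_detections",
    "first_detection_histogram",
    "count_probabilities",
    "detected_counts",
]

# Default cell geometry (nm): box cell with two nucleoid boxes, each starting
# 540 nm from its pole, centred on the long axis.
DEFAULT_GEOMETRY = {
    "length_x": 4000.0,
    "width_y": 1000.0,
    "depth_z": 1000.0,
    "nucleoid_x_start": 540.0,
    "nucleoid_x_len": 1220.0,
    "nucleoid_yz_len": 532.0,
    "obstacle_radius": 10.0,
}


class ConfigurationError(ValueError):
    """Raised for geometry or parameter combinations that cannot be realised."""


@dataclass(frozen=True)
class CellDomain:
    """Simulation geometry: cell box, nucleoid boxes and immobile obstacles.

    ``nucleoid_boxes`` is a list of ``(x_start, x_len, y_len, z_len)`` tuples;
    each box is centred on the cell long axis.  ``obstacles`` holds the
    obstacle centres, shape ``(n, 3)``, all of radius ``obstacle_radius``.
    """

    length_x: float
    width_y: float
    depth_z: float
    nucleoid_boxes: tuple
    obstacles: np.ndarray
    obstacle_radius: float = 10.0
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for (x0, xl, yl, zl) in self.nucleoid_boxes:
            if x0 < 0 or x0 + xl > self.length_x:
                raise ConfigurationError("nucleoid box exceeds cell along x")
            if yl > self.width_y or zl > self.depth_z:
                raise ConfigurationError("nucleoid box exceeds cell cross-section")
        if len(self.obstacles):
            object.__setattr__(self, "_tree", cKDTree(self.obstacles))

    @property
    def dims(self) -> np.ndarray:
        return np.array([self.length_x, self.width_y, self.depth_z])

    def box_bounds(self, box) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of a nucleoid box in cell coordinates."""
        x0, xl, yl, zl = box
        lo = np.array([x0, (self.width_y - yl) / 2, (self.depth_z - zl) / 2])
        hi = lo + np.array([xl, yl, zl])
        return lo, hi

    def obstacle_overlap(self, positions: np.ndarray, radius: float) -> np.ndarray:
        """Boolean mask: does each position overlap any obstacle?"""
        positions = np.atleast_2d(positions)
        if self._tree is None:
            return np.zeros(len(positions), dtype=bool)
        d, _ = self._tree.query(positions, k=1)
        return d < radius + self.obstacle_radius

    def nucleoid_volume_fraction(self) -> float:
        v = sum(xl * yl * zl for (_, xl, yl, zl) in self.nucleoid_boxes)
        return v / (self.length_x * self.width_y * self.depth_z)


@dataclass
class Aggregate:
    """A mobile sphere: ``r**3 = monomer_count * r0**3`` at constant density."""

    id: int
    position: np.ndarray
    radius: float
    monomer_count: int = 1

    def diffusion_constant(self, d0: float, r0: float, law: str = "stokes_einstein") -> float:
        if law == "stokes_einstein":
            return d0 * r0 / self.radius
        if law == "power6":
            return d0 * (r0 / self.radius) ** 6
        raise ValueError(f"unknown diffusion law {law!r}")


@dataclass
class SimConfig:
    """Parameters of one simulation run.

    Units: nm, seconds.  ``d0`` is the monomer diffusion constant
    (4.4 um^2/s = 4.4e6 nm^2/s) and ``r0`` the monomer radius.  The stability
    bound ``dt < (8/3) r0^2 / d0`` keeps the elementary step below four
    monomer radii so particles cannot jump over each other.
    """

    n_particles: int = 100
    p_ag: float = 1.0
    dt: float = 1e-6
    n_steps: int = 2_000_000
    r0: float = 3.0
    d0: float = 4.4e6
    detection_threshold: int = 30
    diffusion_law: str = "stokes_einstein"
    init_mode: str = "free_space"
    n_obstacles: int = 50_000
    sample_stride: int = 1000
    boundary: str = "reflect"  # "reflect" | "none" (free space, for oracles)
    seed: int = 0
    n_run: int = 1000

    def __post_init__(self):
        if not (0.0 <= self.p_ag <= 1.0):
            raise ConfigurationError("p_ag must lie in [0, 1]")
        if self.dt >= self.stability_bound():
            raise ConfigurationError(
                f"dt={self.dt} violates stability bound {self.stability_bound():.3g} s"
            )
        if self.diffusion_law not in ("stokes_einstein", "power6"):
            raise ConfigurationError(f"unknown diffusion law {self.diffusion_law!r}")
        if self.init_mode not in ("free_space", "in_nucleoid", "nucleoid_shell_20nm"):
            raise ConfigurationError(f"unknown init mode {self.init_mode!r}")

    def stability_bound(self) -> float:
        """Largest admissible time step, (8/3) r0^2 / d0 (seconds)."""
        return (8.0 / 3.0) * self.r0**2 / self.d0

    def step_length(self, radius: float | None = None) -> float:
        """Elementary displacement d = sqrt(6 D dt) for a sphere of ``radius``."""
        r = self.r0 if radius is None else radius
        if self.diffusion_law == "power6":
            d = self.d0 * (self.r0 / r) ** 6
        else:
            d = self.d0 * self.r0 / r
        return math.sqrt(6.0 * d * self.dt)


@dataclass
class SimRecord:
    """Sampled output of one run.

    ``sample_steps[k]`` is the step index of sample ``k``; ``counts[k]`` and
    ``positions[k]`` list the monomer counts and centres of the aggregates
    alive at that step.  ``merges`` is a ``(n_merge, 6)`` array with rows
    ``(step, new_count, larger_parent_count, x, y, z)``, from which first
    detections at any monomer-count threshold can be reconstructed.
    """

    n_particles: int
    cell_length_x: float
    dt: float
    sample_steps: np.ndarray
    counts: list
    positions: list
    merges: np.ndarray
    seed: int

    def total_monomers(self) -> np.ndarray:
        return np.array([c.sum() for c in self.counts])


# ---------------------------------------------------------------------------
# Domain construction and initial placement
# ---------------------------------------------------------------------------

def build_domain(geometry: dict | None = None, n_obstacles: int = 50_000,
                 rng: np.random.Generator | int | None = None) -> CellDomain:
    """Build the cell geometry and scatter obstacles uniformly in the nucleoids.

    Obstacle centres are drawn uniformly inside the two nucleoid boxes, split
    evenly between them; obstacles may mutually overlap (only protein–obstacle
    overlap is forbidden during the simulation).
    """
    g = dict(DEFAULT_GEOMETRY)
    if geometry:
        g.update(geometry)
    rng = np.random.default_rng(rng)

    lx, ly, lz = g["length_x"], g["width_y"], g["depth_z"]
    x0, xl, yzl = g["nucleoid_x_start"], g["nucleoid_x_len"], g["nucleoid_yz_len"]
    boxes = (
        (x0, xl, yzl, yzl),
        (lx - x0 - xl, xl, yzl, yzl),
    )
    per_box = [n_obstacles // 2 + n_obstacles % 2, n_obstacles // 2]
    centers = []
    for box, n in zip(boxes, per_box):
        bx0, bxl, byl, bzl = box
        lo = np.array([bx0, (ly - byl) / 2, (lz - bzl) / 2])
        size = np.array([bxl, byl, bzl])
        centers.append(lo + rng.random((n, 3)) * size)
    obstacles = np.vstack(centers) if n_obstacles else np.empty((0, 3))
    return CellDomain(lx, ly, lz, boxes, obstacles, g["obstacle_radius"])


def _sample_in_box(lo, hi, n, rng):
    return lo + rng.random((n, 3)) * (np.asarray(hi) - np.asarray(lo))


def init_particles(domain: CellDomain, config: SimConfig,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Place ``n_particles`` non-overlapping monomers according to ``init_mode``.

    Returns an ``(n, 3)`` array of centres.  Monomers never overlap each other
    (centre distance > 2 r0) nor any obstacle.
    """
    rng = np.random.default_rng(rng)
    n = config.n_particles
    r0 = config.r0
    placed = np.empty((0, 3))
    max_rounds = 200
    for _ in range(max_rounds):
        need = n - len(placed)
        if need == 0:
            break
        batch = max(2 * need, 64)
        cand = _draw_candidates(domain, config, batch, rng)
        ok = ~domain.obstacle_overlap(cand, r0)
        cand = cand[ok]
        if len(placed):
            d, _ = cKDTree(placed).query(cand, k=1)
            cand = cand[d > 2 * r0]
        # thin mutual overlaps within the batch
        if len(cand) > 1:
            pairs = cKDTree(cand).query_pairs(2 * r0, output_type="ndarray")
            drop = np.zeros(len(cand), dtype=bool)
            drop[pairs[:, 1]] = True
            cand = cand[~drop]
        placed = np.vstack([placed, cand[:need]])
    else:
        raise ConfigurationError(
            f"could not place {n} monomers in init_mode={config.init_mode!r}: "
            "region too full"
        )
    return placed


def _draw_candidates(domain, config, n, rng):
    mode = config.init_mode
    r0 = config.r0
    if mode == "free_space":
        lo = np.full(3, r0)
        hi = domain.dims - r0
        return _sample_in_box(lo, hi, n, rng)
    if mode == "in_nucleoid":
        out = []
        for box in domain.nucleoid_boxes:
            lo, hi = domain.box_bounds(box)
            out.append(_sample_in_box(lo, hi, n // len(domain.nucleoid_boxes) + 1, rng))
        return np.vstack(out)[:n]
    # 20 nm shell immediately around the nucleoid boxes
    shell = 20.0
    out = []
    for box in domain.nucleoid_boxes:
        lo, hi = domain.box_bounds(box)
        cand = _sample_in_box(lo - shell, hi + shell,
                              3 * (n // len(domain.nucleoid_boxes) + 1), rng)
        inside = np.all((cand > lo) & (cand < hi), axis=1)
        cand = cand[~inside]
        cand = np.clip(cand, r0, domain.dims - r0)
        out.append(cand)
    return np.vstack(out)[:n]


# ---------------------------------------------------------------------------
# Elementary moves (reference Python implementations, used by the unit tests
# and for single aggregates; the ensemble run uses the numba kernel below)
# ---------------------------------------------------------------------------

def _fold(x: float, lo: float, hi: float) -> float:
    """Specular reflection of a coordinate into [lo, hi] (triangle-wave fold)."""
    if hi <= lo:
        return 0.5 * (lo + hi)
    period = 2.0 * (hi - lo)
    t = (x - lo) % period
    if t > hi - lo:
        t = period - t
    return lo + t


def spherical_step(d: float, theta: float, c: float) -> np.ndarray:
    """Displacement of length ``d`` from polar draws theta ~ U[0,2pi], c ~ U[-1,1]."""
    s = math.sin(math.acos(c))
    return np.array([d * s * math.cos(theta), d * s * math.sin(theta), d * c])


def diffuse_step(aggregate: Aggregate, domain: CellDomain, dt: float,
                 rng: np.random.Generator, d0: float = 4.4e6, r0: float = 3.0,
                 diffusion_law: str = "stokes_einstein") -> np.ndarray:
    """One attempted move of a single aggregate; returns the new position.

    The candidate is rejected (position unchanged) if it overlaps any
    obstacle; a candidate outside the cell box is reflected specularly on the
    violated wall(s).
    """
    dp = aggregate.diffusion_constant(d0, r0, diffusion_law)
    d = math.sqrt(6.0 * dp * dt)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    c = rng.uniform(-1.0, 1.0)
    cand = aggregate.position + spherical_step(d, theta, c)
    r = aggregate.radius
    for ax, length in enumerate(domain.dims):
        cand[ax] = _fold(cand[ax], r, length - r)
    if not np.isfinite(cand).all():
        raise FloatingPointError("non-finite candidate position")
    if domain.obstacle_overlap(cand[None, :], r)[0]:
        return aggregate.position.copy()
    return cand


def merge(a: Aggregate, b: Aggregate, config: SimConfig) -> Aggregate:
    """Merge two overlapping aggregates into one at their centre of mass.

    The product radius satisfies ``r_c^3 = r_a^3 + r_b^3`` (volume
    conservation at constant density); the centre of mass is volume-weighted.
    """
    dist = np.linalg.norm(a.position - b.position)
    if dist >= a.radius + b.radius:
        raise ValueError("merge() requires overlapping aggregates")
    wa, wb = a.radius**3, b.radius**3
    pos = (wa * a.position + wb * b.position) / (wa + wb)
    rc = (wa + wb) ** (1.0 / 3.0)
    return Aggregate(id=min(a.id, b.id), position=pos, radius=rc,
                     monomer_count=a.monomer_count + b.monomer_count)


# ---------------------------------------------------------------------------
# Numba kernel: full run
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim_kernel(pos, cnt, r0, d0, law_pow, p_ag, dt, n_steps,
                lx, ly, lz, reflect,
                obs_pos, obs_r, grid_lo, grid_cs, grid_n, cell_start, cell_obs,
                near_lo, near_hi,
                sample_stride, seed,
                samp_counts, samp_pos, merges):
    np.random.seed(seed)
    n = pos.shape[0]
    npart = n
    radius = np.empty(npart)
    dconst = np.empty(npart)
    for i in range(n):
        radius[i] = r0 * cnt[i] ** (1.0 / 3.0)
        dconst[i] = d0 * (r0 / radius[i]) ** law_pow
    pair_i = np.empty(npart * 8, dtype=np.int64)
    pair_j = np.empty(npart * 8, dtype=np.int64)
    merged_flag = np.zeros(npart, dtype=np.uint8)
    n_merges = 0
    n_samples = 0

    # sample at step 0
    samp_counts[0, :n] = cnt[:n]
    samp_pos[0, :n] = pos[:n]
    n_samples = 1

    for stepk in range(1, n_steps + 1):
        # --- diffusion ---
        for i in range(n):
            d = math.sqrt(6.0 * dconst[i] * dt)
            theta = np.random.uniform(0.0, 2.0 * math.pi)
            c = np.random.uniform(-1.0, 1.0)
            s = math.sqrt(max(0.0, 1.0 - c * c))
            cx = pos[i, 0] + d * s * math.cos(theta)
            cy = pos[i, 1] + d * s * math.sin(theta)
            cz = pos[i, 2] + d * c
            ri = radius[i]
            if reflect:
                cx = _fold_nb(cx, ri, lx - ri)
                cy = _fold_nb(cy, ri, ly - ri)
                cz = _fold_nb(cz, ri, lz - ri)
            # obstacle rejection: only near the nucleoid regions
            rejected = False
            if obs_pos.shape[0] > 0:
                reach = ri + obs_r
                if (near_lo[0] - reach < cx < near_hi[0] + reach and
                        near_lo[1] - reach < cy < near_hi[1] + reach and
                        near_lo[2] - reach < cz < near_hi[2] + reach):
                    rejected = _hits_obstacle(cx, cy, cz, reach, obs_pos,
                                              grid_lo, grid_cs, grid_n,
                                              cell_start, cell_obs)
            if not rejected:
                pos[i, 0] = cx
                pos[i, 1] = cy
                pos[i, 2] = cz

        # --- aggregation ---
        if p_ag > 0.0 and n > 1:
            npairs = 0
            for i in range(n - 1):
                xi = pos[i, 0]
                ri = radius[i]
                rmax = ri + radius[0]  # upper bound refined per j below
                for j in range(i + 1, n):
                    rr = ri + radius[j]
                    dx = pos[j, 0] - xi
                    if dx > rr or dx < -rr:
                        continue
                    dy = pos[j, 1] - pos[i, 1]
                    if dy > rr or dy < -rr:
                        continue
                    dz = pos[j, 2] - pos[i, 2]
                    if dx * dx + dy * dy + dz * dz < rr * rr:
                        if npairs < pair_i.shape[0]:
                            pair_i[npairs] = i
                            pair_j[npairs] = j
                            npairs += 1
            if npairs > 0:
                # random enumeration order (Fisher-Yates)
                for k in range(npairs - 1, 0, -1):
                    m = np.random.randint(0, k + 1)
                    pair_i[k], pair_i[m] = pair_i[m], pair_i[k]
                    pair_j[k], pair_j[m] = pair_j[m], pair_j[k]
                for i in range(n):
                    merged_flag[i] = 0
                any_merge = False
                for k in range(npairs):
                    i = pair_i[k]
                    j = pair_j[k]
                    if merged_flag[i] or merged_flag[j] or cnt[j] == 0:
                        continue
                    if p_ag < 1.0 and np.random.random() >= p_ag:
                        continue
                    wa = radius[i] ** 3
                    wb = radius[j] ** 3
                    tot = wa + wb
                    for ax in range(3):
                        pos[i, ax] = (wa * pos[i, ax] + wb * pos[j, ax]) / tot
                    big = cnt[i] if cnt[i] > cnt[j] else cnt[j]
                    cnt[i] = cnt[i] + cnt[j]
                    cnt[j] = 0
                    radius[i] = r0 * cnt[i] ** (1.0 / 3.0)
                    dconst[i] = d0 * (r0 / radius[i]) ** law_pow
                    merged_flag[i] = 1
                    merged_flag[j] = 1
                    merges[n_merges, 0] = stepk
                    merges[n_merges, 1] = cnt[i]
                    merges[n_merges, 2] = big
                    merges[n_merges, 3] = pos[i, 0]
                    merges[n_merges, 4] = pos[i, 1]
                    merges[n_merges, 5] = pos[i, 2]
                    n_merges += 1
                    any_merge = True
                if any_merge:
                    # compact the alive slots
                    w = 0
                    for i in range(n):
                        if cnt[i] > 0:
                            if w != i:
                                cnt[w] = cnt[i]
                                radius[w] = radius[i]
                                dconst[w] = dconst[i]
                                for ax in range(3):
                                    pos[w, ax] = pos[i, ax]
                            w += 1
                    for i in range(w, n):
                        cnt[i] = 0
                    n = w

        if stepk % sample_stride == 0:
            samp_counts[n_samples, :n] = cnt[:n]
            samp_pos[n_samples, :n] = pos[:n]
            n_samples += 1

    return n_merges, n_samples


@njit(cache=True, inline="always")
def _fold_nb(x, lo, hi):
    if hi <= lo:
        return 0.5 * (lo + hi)
    period = 2.0 * (hi - lo)
    t = (x - lo) % period
    if t > hi - lo:
        t = period - t
    return lo + t


@njit(cache=True)
def _hits_obstacle(cx, cy, cz, reach, obs_pos, grid_lo, grid_cs, grid_n,
                   cell_start, cell_obs):
    span = int(reach / grid_cs) + 1
    ix = int((cx - grid_lo[0]) / grid_cs)
    iy = int((cy - grid_lo[1]) / grid_cs)
    iz = int((cz - grid_lo[2]) / grid_cs)
    r2 = reach * reach
    for ax in range(max(0, ix - span), min(grid_n[0], ix + span + 1)):
        for ay in range(max(0, iy - span), min(grid_n[1], iy + span + 1)):
            for az in range(max(0, iz - span), min(grid_n[2], iz + span + 1)):
                cidx = (ax * grid_n[1] + ay) * grid_n[2] + az
                for p in range(cell_start[cidx], cell_start[cidx + 1]):
                    o = cell_obs[p]
                    dx = obs_pos[o, 0] - cx
                    dy = obs_pos[o, 1] - cy
                    dz = obs_pos[o, 2] - cz
                    if dx * dx + dy * dy + dz * dz < r2:
                        return True
    return False


def _obstacle_grid(domain: CellDomain, cell_size: float = 40.0):
    """Uniform-grid spatial hash of the obstacle centres (CSR layout)."""
    obs = domain.obstacles
    if len(obs) == 0:
        lo = np.zeros(3)
        return (lo, cell_size, np.ones(3, dtype=np.int64),
                np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64),
                np.zeros(3), np.zeros(3))
    lo = obs.min(axis=0) - 1e-9
    hi = obs.max(axis=0) + 1e-9
    n = np.maximum(1, np.ceil((hi - lo) / cell_size)).astype(np.int64)
    idx = np.floor((obs - lo) / cell_size).astype(np.int64)
    idx = np.minimum(idx, n - 1)
    flat = (idx[:, 0] * n[1] + idx[:, 1]) * n[2] + idx[:, 2]
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    ncell = int(n.prod())
    cell_start = np.zeros(ncell + 1, dtype=np.int64)
    np.add.at(cell_start, flat_sorted + 1, 1)
    cell_start = np.cumsum(cell_start)
    return lo, cell_size, n, cell_start, order, lo, hi


def run(config: SimConfig, domain: CellDomain | None = None,
        rng: np.random.Generator | int | None = None,
        initial_positions: np.ndarray | None = None,
        initial_counts: np.ndarray | None = None) -> SimRecord:
    """Run one replicate and return the sampled record.

    Reproducible given ``config.seed`` (or an explicit ``rng``/seed argument,
    which takes precedence for the stochastic draws).
    """
    seed = config.seed if rng is None else rng
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31 - 1))
    seed = int(seed) % (2**31 - 1)
    rng_init = np.random.default_rng(seed)

    if domain is None:
        domain = build_domain(n_obstacles=config.n_obstacles, rng=rng_init)
    if initial_positions is None:
        pos = init_particles(domain, config, rng_init)
    else:
        pos = np.array(initial_positions, dtype=float)

    npart = len(pos)
    cnt = np.ones(npart, dtype=np.int64) if initial_counts is None \
        else np.asarray(initial_counts, dtype=np.int64).copy()
    glo, gcs, gn, cell_start, cell_obs, near_lo, near_hi = _obstacle_grid(domain)

    n_samples = config.n_steps // config.sample_stride + 1
    samp_counts = np.zeros((n_samples, npart), dtype=np.int64)
    samp_pos = np.zeros((n_samples, npart, 3))
    merges = np.zeros((max(npart - 1, 1), 6))
    law_pow = 6.0 if config.diffusion_law == "power6" else 1.0

    kernel_seed = int(rng_init.integers(2**31 - 1))
    n_merges, n_rec = _sim_kernel(
        pos.copy(), cnt, config.r0, config.d0, law_pow, config.p_ag,
        config.dt, config.n_steps,
        domain.length_x, domain.width_y, domain.depth_z,
        config.boundary == "reflect",
        domain.obstacles, domain.obstacle_radius,
        glo, gcs, gn, cell_start, cell_obs, near_lo, near_hi,
        config.sample_stride, kernel_seed,
        samp_counts, samp_pos, merges)

    steps = np.arange(n_rec) * config.sample_stride
    counts, positions = [], []
    for k in range(n_rec):
        alive = samp_counts[k] > 0
        counts.append(samp_counts[k][alive].copy())
        positions.append(samp_pos[k][alive].copy())
    return SimRecord(
        n_particles=npart, cell_length_x=domain.length_x, dt=config.dt,
        sample_steps=steps, counts=counts, positions=positions,
        merges=merges[:n_merges].copy(), seed=seed)


def run_ensemble(config: SimConfig, n_run: int | None = None,
                 seed: int | None = None,
                 domain: CellDomain | None = None) -> list[SimRecord]:
    """Run ``n_run`` replicates with deterministically derived seeds."""
    n_run = config.n_run if n_run is None else n_run
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    records = []
    for child in ss.spawn(n_run):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        records.append(run(replace(config, seed=rep_seed), domain=domain))
    return records


# ---------------------------------------------------------------------------
# Reference single-step driver (small systems; mirrors the kernel rules)
# ---------------------------------------------------------------------------

def step(aggregates: list[Aggregate], domain: CellDomain, config: SimConfig,
         rng: np.random.Generator) -> list[Aggregate]:
    """One full step: every aggregate moves once, then overlapping pairs are
    enumerated in random order and merge with probability ``p_ag``.  A merge
    product is not re-tested within the same step."""
    for a in aggregates:
        a.position = diffuse_step(a, domain, config.dt, rng, config.d0,
                                  config.r0, config.diffusion_law)
    pairs = []
    for i in range(len(aggregates) - 1):
        for j in range(i + 1, len(aggregates)):
            a, b = aggregates[i], aggregates[j]
            if np.linalg.norm(a.position - b.position) < a.radius + b.radius:
                pairs.append((i, j))
    rng.shuffle(pairs)
    merged: dict[int, Aggregate] = {}
    consumed: set[int] = set()
    out: dict[int, Aggregate] = {i: a for i, a in enumerate(aggregates)}
    touched: set[int] = set()
    for (i, j) in pairs:
        if i in touched or j in touched or i in consumed or j in consumed:
            continue
        if rng.random() < config.p_ag:
            out[i] = merge(out[i], out[j], config)
            del out[j]
            consumed.add(j)
            touched.update((i, j))
    return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# Detection statistics
# ---------------------------------------------------------------------------

def first_detections(record: SimRecord, threshold: int) -> np.ndarray:
    """Normalized long-axis positions at which aggregates first reached
    ``threshold`` monomers.  Positions are rescaled to [-1, 1] with the poles
    at the extremes."""
    half = record.cell_length_x / 2.0
    events = []
    if threshold <= 1:
        x = record.positions[0][:, 0]
        events.extend((x - half) / half)
    else:
        m = record.merges
        if len(m):
            hit = (m[:, 1] >= threshold) & (m[:, 2] < threshold)
            events.extend((m[hit, 3] - half) / half)
    return np.asarray(events)


def first_detection_histogram(records, threshold: int, n_bins: int = 20):
    """Unit-mass histogram of first-detection positions over [-1, 1]."""
    events = np.concatenate([first_detections(r, threshold) for r in records]) \
        if records else np.array([])
    if len(events) == 0:
        raise ValueError("no first-detection events at this threshold")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(events, bins=edges)
    return edges, hist / hist.sum()


def detected_counts(record: SimRecord, threshold: int) -> np.ndarray:
    """Number of detectable aggregates (count >= threshold) at each sample."""
    return np.array([(c >= threshold).sum() for c in record.counts])


def count_probabilities(records, threshold: int):
    """P(exactly k detected aggregates), k in {0, 1, 2, 3, >=4}, per sample time.

    Returns ``(sample_steps, probs)`` with ``probs`` of shape ``(n_samples, 5)``
    whose columns are P(0), P(1), P(2), P(3), P(>=4); rows sum to 1.
    """
    if not records:
        raise ValueError("need at least one replicate")
    steps = records[0].sample_steps
    nk = np.stack([detected_counts(r, threshold) for r in records])
    probs = np.zeros((len(steps), 5))
    for col, k in enumerate(range(4)):
        probs[:, col] = (nk == k).mean(axis=0)
    probs[:, 4] = (nk >= 4).mean(axis=0)
    return steps, probs
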