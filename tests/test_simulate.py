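import math

import numpy as np
import pytest

from polecrowd.simulate import (Aggregate, CellDomain, ConfigurationError,
                                SimConfig, build_domain, count_probabilities,
                                detected_counts, diffuse_step,
                                first_detection_histogram, first_detections,
                                init_particles, merge, run, run_ensemble, step)


def small_domain(n_obstacles=500, seed=0):
    return build_domain(n_obstacles=n_obstacles, rng=seed)


class TestConfig:
    def test_monomer_step_length_is_about_5nm(self):
        cfg = SimConfig()
        assert cfg.step_length() == pytest.approx(math.sqrt(6 * 4.4e6 * 1e-6))
        assert round(cfg.step_length()) == 5

    def test_stability_bound_is_about_5us(self):
        assert SimConfig().stability_bound() == pytest.approx((8 / 3) * 9 / 4.4e6)
        with pytest.raises(ConfigurationError):
            SimConfig(dt=6e-6)

    def test_p_ag_range_enforced(self):
        with pytest.raises(ConfigurationError):
            SimConfig(p_ag=1.5)


class TestDomain:
    def test_obstacles_split_evenly_and_inside_boxes(self):
        dom = build_domain(n_obstacles=2000, rng=1)
        assert len(dom.obstacles) == 2000
        per_box = []
        for box in dom.nucleoid_boxes:
            lo, hi = dom.box_bounds(box)
            inside = np.all((dom.obstacles >= lo) & (dom.obstacles <= hi), axis=1)
            per_box.append(inside.sum())
        assert per_box == [1000, 1000]

    def test_obstacle_free_domain(self):
        dom = build_domain(n_obstacles=0)
        assert len(dom.obstacles) == 0
        assert not dom.obstacle_overlap(np.array([[100.0, 500, 500]]), 3.0)[0]

    def test_nucleoid_volume_fraction(self):
        # two 1220 x 532 x 532 boxes in a 4000 x 1000 x 1000 cell
        assert build_domain(n_obstacles=0).nucleoid_volume_fraction() == \
            pytest.approx(2 * 1220 * 532**2 / 4e9, rel=1e-12)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            build_domain({"nucleoid_x_len": 3600.0}, n_obstacles=0)

    def test_deterministic_given_seed(self):
        a = build_domain(n_obstacles=100, rng=5).obstacles
        b = build_domain(n_obstacles=100, rng=5).obstacles
        np.testing.assert_array_equal(a, b)


class TestInitParticles:
    def test_free_space_nonoverlapping(self):
        dom = small_domain()
        cfg = SimConfig(n_particles=100, n_obstacles=500)
        pos = init_particles(dom, cfg, rng=2)
        assert pos.shape == (100, 3)
        from scipy.spatial.distance import pdist
        assert pdist(pos).min() > 2 * cfg.r0
        assert not dom.obstacle_overlap(pos, cfg.r0).any()

    def test_in_nucleoid_mode(self):
        dom = small_domain()
        cfg = SimConfig(n_particles=2, init_mode="in_nucleoid")
        pos = init_particles(dom, cfg, rng=3)
        in_any = np.zeros(2, dtype=bool)
        for box in dom.nucleoid_boxes:
            lo, hi = dom.box_bounds(box)
            in_any |= np.all((pos >= lo) & (pos <= hi), axis=1)
        assert in_any.all()

    def test_shell_mode_stays_in_20nm_layer(self):
        dom = small_domain()
        cfg = SimConfig(n_particles=50, init_mode="nucleoid_shell_20nm")
        pos = init_particles(dom, cfg, rng=4)
        for p in pos:
            dists = []
            for box in dom.nucleoid_boxes:
                lo, hi = dom.box_bounds(box)
                inside = np.all((p > lo) & (p < hi))
                assert not inside
                # distance to the expanded box must be zero
                d = np.maximum(np.maximum(lo - 20 - p, p - (hi + 20)), 0)
                dists.append(np.linalg.norm(d))
            assert min(dists) == pytest.approx(0.0, abs=1e-9)

    def test_heat_shock_count_placed(self):
        dom = small_domain(n_obstacles=2000)
        pos = init_particles(dom, SimConfig(n_particles=7000), rng=5)
        assert len(pos) == 7000


class TestDiffuseStep:
    def test_vertical_step_when_c_is_one(self):
        from polecrowd.simulate import spherical_step
        d = 5.14
        np.testing.assert_allclose(spherical_step(d, 0.3, 1.0),
                                   [0, 0, d], atol=1e-12)

    def test_rejection_inside_obstacle(self):
        # one obstacle right next to the particle: every candidate within
        # reach is rejected, so after a tiny step the position is unchanged
        dom = CellDomain(4000, 1000, 1000, (), np.array([[2000.0, 500, 500]]),
                         obstacle_radius=50.0)
        agg = Aggregate(0, np.array([2000.0, 500, 545.0]), radius=3.0)
        rng = np.random.default_rng(0)
        new = diffuse_step(agg, dom, 1e-6, rng)
        np.testing.assert_array_equal(new, agg.position)

    def test_free_step_has_exact_length(self):
        dom = CellDomain(4000, 1000, 1000, (), np.empty((0, 3)))
        agg = Aggregate(0, np.array([2000.0, 500, 500]), radius=3.0)
        new = diffuse_step(agg, dom, 1e-6, np.random.default_rng(1))
        assert np.linalg.norm(new - agg.position) == \
            pytest.approx(math.sqrt(6 * 4.4e6 * 1e-6))


class TestMerge:
    def test_equal_monomers(self):
        a = Aggregate(0, np.array([0.0, 0, 0]), 3.0, 1)
        b = Aggregate(1, np.array([4.0, 0, 0]), 3.0, 1)
        c = merge(a, b, SimConfig())
        assert c.radius == pytest.approx(3 * 2 ** (1 / 3))
        assert c.monomer_count == 2
        np.testing.assert_allclose(c.position, [2.0, 0, 0])

    def test_unequal_counts_cube_sum(self):
        a = Aggregate(0, np.zeros(3), 3.0, 1)
        b = Aggregate(1, np.array([1.0, 0, 0]), 3 * 2 ** (1 / 3), 2)
        c = merge(a, b, SimConfig())
        assert c.radius == pytest.approx(3 * 3 ** (1 / 3))
        assert c.monomer_count == 3

    def test_stokes_einstein_after_merge(self):
        c = Aggregate(0, np.zeros(3), 6.0, 8)
        assert c.diffusion_constant(4.4e6, 3.0) == pytest.approx(2.2e6)

    def test_non_overlapping_rejected(self):
        a = Aggregate(0, np.zeros(3), 3.0, 1)
        b = Aggregate(1, np.array([10.0, 0, 0]), 3.0, 1)
        with pytest.raises(ValueError):
            merge(a, b, SimConfig())


class TestStep:
    def test_zero_probability_conserves_count(self):
        dom = CellDomain(4000, 1000, 1000, (), np.empty((0, 3)))
        cfg = SimConfig(p_ag=0.0, n_particles=10)
        rng = np.random.default_rng(3)
        aggs = [Aggregate(i, np.array([100.0 + 10 * i, 500, 500]), 3.0)
                for i in range(10)]
        for _ in range(5):
            aggs = step(aggs, dom, cfg, rng)
        assert len(aggs) == 10

    def test_certain_merge_of_overlapping_pair(self):
        dom = CellDomain(4000, 1000, 1000, (), np.empty((0, 3)))
        cfg = SimConfig(p_ag=1.0, dt=1e-9)
        aggs = [Aggregate(0, np.array([2000.0, 500, 500]), 3.0),
                Aggregate(1, np.array([2001.0, 500, 500]), 3.0)]
        out = step(aggs, dom, cfg, np.random.default_rng(4))
        assert len(out) == 1 and out[0].monomer_count == 2

    def test_monomer_conservation(self):
        dom = CellDomain(500, 200, 200, (), np.empty((0, 3)))
        cfg = SimConfig(p_ag=0.5, n_particles=30)
        rng = np.random.default_rng(5)
        aggs = [Aggregate(i, rng.uniform(10, 190, 3) + [0, 0, 0], 3.0)
                for i in range(30)]
        for _ in range(10):
            aggs = step(aggs, dom, cfg, rng)
        assert sum(a.monomer_count for a in aggs) == 30


class TestRun:
    def test_monomer_and_volume_conservation(self):
        dom = small_domain(2000)
        cfg = SimConfig(n_particles=60, n_steps=20_000, sample_stride=2000,
                        dt=4e-6, seed=9)
        rec = run(cfg, domain=dom)
        assert set(rec.total_monomers().tolist()) == {60}
        for cnt in rec.counts:
            r3 = (3.0 * cnt.astype(float) ** (1 / 3)) ** 3
            assert r3.sum() == pytest.approx(60 * 27.0, rel=1e-9)

    def test_detected_count_pigeonhole_and_monotonicity(self):
        dom = small_domain(1000)
        cfg = SimConfig(n_particles=100, n_steps=50_000, sample_stride=5000,
                        dt=4e-6, seed=10)
        rec = run(cfg, domain=dom)
        assert (detected_counts(rec, 30) <= 100 // 30).all()
        for t_lo, t_hi in [(1, 5), (5, 30), (30, 100)]:
            assert (detected_counts(rec, t_lo) >= detected_counts(rec, t_hi)).all()

    def test_threshold_one_reproduces_initial_placement(self):
        dom = small_domain(500)
        cfg = SimConfig(n_particles=40, n_steps=1000, sample_stride=1000,
                        dt=4e-6, seed=12)
        rec = run(cfg, domain=dom)
        fd = first_detections(rec, 1)
        assert len(fd) == 40
        np.testing.assert_allclose(
            np.sort(fd), np.sort((rec.positions[0][:, 0] - 2000) / 2000))

    def test_reproducible_given_seed(self):
        dom = small_domain(500)
        cfg = SimConfig(n_particles=30, n_steps=5000, sample_stride=1000,
                        dt=4e-6, seed=33)
        r1 = run(cfg, domain=dom)
        r2 = run(cfg, domain=dom)
        np.testing.assert_array_equal(r1.positions[-1], r2.positions[-1])

    def test_free_space_msd_matches_2Dt(self):
        # obstacle-free, wall-free ensemble: per-axis MSD = 2 D t
        cfg = SimConfig(n_particles=1000, n_steps=2000, sample_stride=200,
                        n_obstacles=0, p_ag=0.0, boundary="none", seed=3)
        dom = build_domain(n_obstacles=0, rng=4)
        rec = run(cfg, domain=dom)
        pos = np.stack(rec.positions)
        t = rec.sample_steps * cfg.dt
        for ax in range(3):
            disp2 = (pos[:, :, ax] - pos[:1, :, ax]) ** 2
            msd = disp2.mean(axis=1)
            se = disp2.std(axis=1, ddof=1) / np.sqrt(disp2.shape[1])
            expect = 2 * cfg.d0 * t
            assert (np.abs(msd[1:] - expect[1:]) < 3 * se[1:]).all()

    def test_crowding_excludes_large_aggregates_from_nucleoid(self):
        # a 30-mer's centre should sit inside the nucleoids less often than
        # the nucleoid volume fraction
        dom = build_domain(rng=6)
        cfg = SimConfig(n_particles=8, p_ag=0.0, n_steps=200_000,
                        sample_stride=2000, dt=4e-6, seed=21)
        rng = np.random.default_rng(8)
        pos0 = init_particles(dom, cfg, rng)
        rec = run(cfg, domain=dom, initial_positions=pos0,
                  initial_counts=np.full(8, 30))
        inside = 0
        total = 0
        for p in rec.positions[10:]:
            for box in dom.nucleoid_boxes:
                lo, hi = dom.box_bounds(box)
                inside += np.all((p >= lo) & (p <= hi), axis=1).sum()
            total += len(p)
        assert inside / total < dom.nucleoid_volume_fraction()


class TestDetectionStats:
    def test_histogram_single_location(self):
        rec = run(SimConfig(n_particles=5, n_steps=1000, sample_stride=1000,
                            n_obstacles=0, p_ag=0.0, dt=4e-6, seed=2),
                  domain=build_domain(n_obstacles=0, rng=2),
                  initial_positions=np.tile([2000.0, 500, 500], (5, 1)),
                  initial_counts=np.ones(5, dtype=int))
        edges, hist = first_detection_histogram([rec], threshold=1, n_bins=21)
        assert hist[10] == pytest.approx(1.0)

    def test_flat_histogram_for_uniform_monomers(self):
        dom = build_domain(n_obstacles=0, rng=5)
        cfg = SimConfig(n_particles=400, n_steps=1000, sample_stride=1000,
                        n_obstacles=0, p_ag=0.0, dt=4e-6)
        recs = run_ensemble(cfg, n_run=4, seed=17, domain=dom)
        _, hist = first_detection_histogram(recs, threshold=1, n_bins=8)
        assert hist.max() / hist.min() < 1.6  # flat within sampling error

    def test_count_probabilities_normalized(self, nonstressed_ensemble):
        records, _ = nonstressed_ensemble
        steps, probs = count_probabilities(records, 30)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_zero_probability_means_no_detection(self):
        dom = build_domain(n_obstacles=0, rng=9)
        cfg = SimConfig(n_particles=20, n_steps=2000, sample_stride=500,
                        n_obstacles=0, p_ag=0.0, dt=4e-6, seed=19)
        recs = [run(cfg, domain=dom)]
        _, probs = count_probabilities(recs, threshold=2)
        assert (probs[:, 0] == 1.0).all()

    def test_no_events_raises(self):
        dom = build_domain(n_obstacles=0, rng=9)
        cfg = SimConfig(n_particles=5, n_steps=1000, sample_stride=1000,
                        n_obstacles=0, p_ag=0.0, dt=4e-6, seed=20)
        rec = run(cfg, domain=dom)
        with pytest.raises(ValueError):
            first_detection_histogram([rec], threshold=3)
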