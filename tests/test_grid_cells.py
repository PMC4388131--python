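"""Modulo grid code: discretization, residues, conjunctions, diffusion."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gridpi as gp
from gridpi.grid_cells import (
    GridLayerSpec,
    GridPopulation,
    RandomProjectionPopulation,
    diffuse,
    discretize,
    grid_activity,
    grid_from_position,
    modulo_project,
    phase_history,
)
from gridpi.path_integration import PIField


class TestDiscretize:
    def test_bin_edges(self):
        assert discretize(0.0, 60, 1.0) == 0
        assert discretize(0.5, 60, 1.0) == 30
        assert discretize(1.0, 60, 1.0) == 59  # top bin closed

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discretize(-0.1, 60, 1.0)
        with pytest.raises(ValueError):
            discretize(1.2, 60, 1.0)

    @given(st.integers(0, 59), st.integers(2, 30))
    @settings(deadline=None, max_examples=50)
    def test_modulo_periodicity(self, b, mg):
        assert modulo_project(b, mg) == modulo_project(b + mg, mg)
        assert 0 <= modulo_project(b, mg) < mg

    def test_modulo_examples(self):
        assert modulo_project(7, 4) == 3
        assert modulo_project(0, 9) == 0


class TestGridLayer:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GridLayerSpec(modulo=1, pi_pair=(0, 10))
        with pytest.raises(ValueError):
            GridLayerSpec(modulo=9, pi_pair=(3, 3))

    def test_default_layers_are_sixty_degree_pairs(self):
        for spec in gp.default_layers():
            assert spec.pair_separation(60) == pytest.approx(np.pi / 3)

    def test_zero_state_activates_phase_of_zero_level(self, pi_signed):
        # in signed mode the zero level D_max/2 discretizes to the middle bin
        spec = gp.default_layers(moduli=(9,))[0]
        g = grid_activity(spec, pi_signed)
        assert g.sum() == 1.0
        mid_bin = discretize(pi_signed.zero_level, spec.n_e, pi_signed.d_max)
        expect = mid_bin % 9
        assert g[expect, expect] == 1.0

    def test_one_hot_for_any_state(self, pi_signed):
        spec = gp.default_layers(moduli=(25,))[0]
        rng = np.random.default_rng(1)
        for _ in range(20):
            pi_signed.update(rng.uniform(0, 2 * np.pi), 0.1)
            assert grid_activity(spec, pi_signed).sum() == 1.0

    def test_straight_sweep_hits_each_phase_twice(self, hex_arena):
        # a straight run of 2*MG bins along the paired axis cycles every
        # residue of that neuron exactly twice
        pi = PIField.for_arena(hex_arena)
        spec = GridLayerSpec(modulo=4, pi_pair=(0, 10), n_e=60)
        bin_m = spec.bin_size_m(pi)
        theta0 = pi.theta[0]
        n_bins = 2 * spec.modulo
        # sample one point per bin, at bin centres, moving along theta_0
        d0 = pi.state_for_displacement(0, 0)[0]
        start_offset = (np.floor(d0 * spec.n_e / pi.d_max) + 0.5) * (
            pi.d_max / spec.n_e
        ) - d0  # distance (in D units) to the current bin centre
        states = []
        for k in range(n_bins):
            dist = start_offset * pi.meters_per_unit / pi.alpha + k * bin_m
            states.append(
                pi.state_for_displacement(dist * np.cos(theta0), dist * np.sin(theta0))
            )
        ph = phase_history(spec, np.array(states), pi.d_max)[:, 0]
        counts = np.bincount(ph, minlength=spec.modulo)
        assert np.all(counts == 2)

    def test_spacing_law_one_dimensional(self, hex_arena):
        # the residue of a paired neuron repeats with period MG * bin size
        pi = PIField.for_arena(hex_arena)
        spec = gp.default_layers(moduli=(9,))[0]
        period = spec.spacing_m(pi)
        theta0 = pi.theta[spec.pi_pair[0]]
        s = np.arange(0.0, 3.2, 0.01)
        states = np.array(
            [pi.state_for_displacement(d * np.cos(theta0), d * np.sin(theta0)) for d in s]
        )
        ph = phase_history(spec, states, pi.d_max)[:, 0]
        changes = s[np.flatnonzero(np.diff(ph)) + 1]
        gaps = np.diff(changes)
        bin_m = spec.bin_size_m(pi)
        assert np.allclose(gaps, bin_m, atol=0.011)
        # full residue cycle: same phase recurs after MG bins
        recur = s[ph == ph[0]]
        runs = recur[np.flatnonzero(np.diff(recur) > 0.02) + 1]
        assert abs(runs[0] - period) <= bin_m


class TestDiffusion:
    def test_sigma_zero_is_identity(self):
        g = np.zeros((9, 9))
        g[2, 5] = 1.0
        np.testing.assert_array_equal(diffuse(g, 0.0), g)

    def test_peak_preserved_and_normalized(self):
        g = np.zeros((9, 9))
        g[4, 1] = 1.0
        d = diffuse(g, 1.0)
        assert np.unravel_index(np.argmax(d), d.shape) == (4, 1)
        assert d.max() == pytest.approx(1.0)
        assert d.min() >= 0.0

    def test_gaussian_value_at_unit_distance(self):
        g = np.zeros((9, 9))
        g[4, 4] = 1.0
        d = diffuse(g, 1.0)
        assert d[4, 5] == pytest.approx(np.exp(-0.5))
        assert d[5, 5] == pytest.approx(np.exp(-1.0))

    def test_wraps_around_torus(self):
        g = np.zeros((9, 9))
        g[0, 0] = 1.0
        d = diffuse(g, 1.0)
        assert d[8, 0] == pytest.approx(np.exp(-0.5))  # neighbour across the edge


class TestPositionOracle:
    def test_origin_phase(self, pi_signed):
        spec = gp.default_layers(moduli=(9,))[0]
        g = grid_from_position((0.0, 0.0), spec, pi_signed)
        pi_signed.reset()
        np.testing.assert_array_equal(g, grid_activity(spec, pi_signed))

    def test_lattice_periodicity(self, pi_signed):
        spec = gp.default_layers(moduli=(4,))[0]
        period = spec.spacing_m(pi_signed)
        theta0 = pi_signed.theta[spec.pi_pair[0]]
        p0 = (0.13, 0.06)
        # shift by one full period along the first paired axis leaves the
        # first residue unchanged
        p1 = (p0[0] + period * np.cos(theta0), p0[1] + period * np.sin(theta0))
        g0 = grid_from_position(p0, spec, pi_signed)
        g1 = grid_from_position(p1, spec, pi_signed)
        assert np.argmax(g0.sum(axis=1)) == np.argmax(g1.sum(axis=1))

    def test_out_of_range_rejected(self, pi_signed):
        spec = gp.default_layers(moduli=(9,))[0]
        with pytest.raises(ValueError):
            grid_from_position((100.0, 0.0), spec, pi_signed)

    def test_incremental_integration_matches_oracle(self, hex_arena):
        # 100 random noise-free paths: temporal integration and the direct
        # position code select the same phase cell
        rng = np.random.default_rng(0)
        spec = gp.default_layers(moduli=(9,))[0]
        pi = PIField.for_arena(hex_arena)
        agree = 0
        for _ in range(100):
            target = rng.uniform(-1.5, 1.5, 2)
            wps = np.vstack([[0, 0], rng.uniform(-1.8, 1.8, (3, 2)), target])
            pts = [np.zeros((0, 2))]
            for a, b in zip(wps[:-1], wps[1:]):
                n = max(int(np.hypot(*(b - a)) / 0.02), 2)
                pts.append(np.linspace(a, b, n, endpoint=False))
            pts = np.vstack(pts + [target[None, :]])
            pi.reset()
            pi.integrate(gp.Trajectory.from_positions(pts), use_measured=False)
            agree += np.array_equal(
                grid_activity(spec, pi), grid_from_position(target, spec, pi)
            )
        assert agree == 100


class TestGridPopulation:
    def test_flat_vector_length(self, pi_signed):
        pop = GridPopulation(gp.default_layers())
        assert pop.n_cells == 4**2 + 9**2 + 25**2
        assert pop.flat_activities(pi_signed).shape == (pop.n_cells,)

    def test_diffused_equals_direct_convolution(self, pi_signed):
        layers = gp.default_layers(diffusion_sigma=1.0)
        pop = GridPopulation(layers)
        pi_signed.update(0.7, 0.9)
        for spec, fast in zip(layers, pop.activities(pi_signed, diffused=True)):
            slow = diffuse(grid_activity(spec, pi_signed), spec.diffusion_sigma)
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestRandomProjections:
    def test_empty_population(self):
        pop = RandomProjectionPopulation.sample(n_pi=60, n_cells=0, seed=0)
        assert pop.n_cells == 0

    def test_fan_two_with_layer_scales_reduces_to_grid_cell(self, pi_signed):
        spec = gp.default_layers(moduli=(9,))[0]
        pi_signed.update(1.1, 0.8)
        k1, k2 = np.unravel_index(
            np.argmax(grid_activity(spec, pi_signed)), (9, 9)
        )
        pop = RandomProjectionPopulation(
            indices=[np.array(spec.pi_pair)],
            scales=[np.array([9, 9])],
            targets=[np.array([k1, k2])],
            n_e=spec.n_e,
        )
        act = pop.activities(pi_signed.d[None, :], pi_signed.d_max)
        assert act[0, 0] == 1.0

    def test_population_contains_gridlike_and_non_gridlike_cells(self):
        # scaled-down screening: a random-projection population rate-mapped
        # over a long walk shows both positive- and negative-gridness cells
        arena = gp.rectangular_arena(10.0, 10.0, origin=(-5, -5))
        traj = gp.generate_random_walk(arena, 20000, turn_sd=0.1, seed=3)
        pi = PIField.for_arena(arena)
        hist = pi.integrate(traj, use_measured=False)
        pop = RandomProjectionPopulation.sample(n_pi=60, n_cells=200, seed=7)
        acts = pop.activities(hist, pi.d_max)
        order = np.argsort(-acts.mean(axis=0))[:30]
        scores = []
        for c in order:
            rmap = gp.rate_map(traj.x, traj.y, acts[:, c], 0.12, 0.12)
            res = gp.gridness_from_rate_map(rmap)
            if not res.degenerate:
                scores.append(res.score)
        scores = np.asarray(scores)
        assert (scores > 0).any() and (scores < 0).any()


class TestHexagonality:
    def test_sixty_degree_pair_yields_hexagonal_rotational_peaks(self, hex_arena):
        # noise-free walk; rotational-correlation curve of one phase cell
        # has 60/120-degree maxima above the 30/90/150-degree values
        traj = gp.generate_random_walk(hex_arena, 20000, turn_sd=0.1, seed=5)
        pi = PIField.for_arena(hex_arena)
        hist = pi.integrate(traj, use_measured=False)
        spec = gp.default_layers(moduli=(9,))[0]
        ph = phase_history(spec, hist, pi.d_max)
        flat = ph[:, 0] * 9 + ph[:, 1]
        best = np.argmax(np.bincount(flat))
        act = (flat == best).astype(float)
        rmap = gp.rate_map(traj.x, traj.y, act, 0.05, 0.05)
        res = gp.gridness_from_rate_map(rmap)
        at = lambda a: res.curve[int(a)]
        assert min(at(60), at(120)) > max(at(30), at(90), at(150))
        assert res.score > 0

    def test_orientation_law(self, hex_arena):
        # rotating the direction pair by 30 deg rotates the lattice by 30 deg:
        # the autocorrelogram peak directions shift accordingly
        traj = gp.generate_random_walk(hex_arena, 20000, turn_sd=0.1, seed=6)
        pi = PIField.for_arena(hex_arena)
        hist = pi.integrate(traj, use_measured=False)
        angles = {}
        for base, tag in ((0, "a"), (5, "b")):  # 5 index steps = 30 degrees
            spec = GridLayerSpec(modulo=9, pi_pair=(base, base + 10), n_e=60)
            ph = phase_history(spec, hist, pi.d_max)
            flat = ph[:, 0] * 9 + ph[:, 1]
            best = np.argmax(np.bincount(flat))
            rmap = gp.rate_map(traj.x, traj.y, (flat == best).astype(float), 0.05, 0.05)
            ac = gp.spatial_autocorrelation(rmap)
            cy, cx = (np.array(ac.shape) - 1) // 2
            yy, xx = np.indices(ac.shape)
            r = np.hypot(yy - cy, xx - cx)
            ring = np.isfinite(ac) & (r > 14) & (r < 34)  # first peak ring
            vals = np.where(ring, ac, -np.inf)
            iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
            angles[tag] = np.degrees(np.arctan2(iy - cy, ix - cx)) % 60
        diff = abs(angles["a"] - angles["b"])
        diff = min(diff, 60 - diff)
        assert diff == pytest.approx(30.0, abs=6.0)
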