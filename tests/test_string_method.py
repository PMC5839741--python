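"""Mean-forces string method: mean forces, projections, updates, drivers."""

import numpy as np
import pytest

import mepkit as mk
from mepkit.errors import InputError
from mepkit.string_method import path_from_trajectory, _tangents


class TestSteeredInitialPath:
    def test_flat_potential_reaches_target(self):
        sys1 = mk.ToySystem("linear_1d", parameters={"slope": 0.0},
                            temperature=0.1, timestep=1e-3)
        path = mk.steered_initial_path(sys1, [0.0], [4.0], n_steps=20000,
                                       pull_k=50.0, seed=1, n_images=5)
        assert abs(path.images[-1, 0] - 4.0) < 0.05
        assert np.all(np.diff(path.images[:, 0]) > 0)

    def test_double_well_path_crosses_barrier(self):
        h = 3.0
        sys1 = mk.ToySystem("double_well_1d", parameters={"h": h, "a": 1.0},
                            temperature=0.5, timestep=1e-3)
        path = mk.steered_initial_path(sys1, [-1.0], [1.0], n_steps=30000,
                                       pull_k=60.0, seed=2, n_images=15)
        from mepkit.toy_systems import potential_and_gradient
        u, _ = potential_and_gradient(sys1, path.images)
        # barrier height h at x=0; max along path must come within kT of it
        assert u.max() >= h - sys1.kt

    def test_straight_trajectory_resampling(self):
        frames = np.linspace([0.0], [4.0], 100)
        path = path_from_trajectory(frames, 3)
        assert np.allclose(path.images.ravel(), [0.0, 2.0, 4.0], atol=1e-12)

    def test_identical_endpoints_rejected(self):
        sys1 = mk.ToySystem("linear_1d", parameters={"slope": 0.0})
        with pytest.raises(InputError):
            mk.steered_initial_path(sys1, [1.0], [1.0], 100, 10.0)


class TestMeanForce:
    def test_symmetric_samples_give_zero_force(self, rng):
        frames = rng.normal(2.0, 0.1, (5000, 1))
        traj = mk.Trajectory(frames=frames, potential_energy=np.zeros(5000),
                             bias_energy=np.zeros(5000), seed=0)
        r = mk.RestraintSpec(center=[2.0], force_constant=10.0)
        f, se = mk.estimate_mean_force(traj, r)
        assert abs(f[0]) < 3 * se[0]

    def test_linear_potential_recovers_slope(self):
        sys1 = mk.ToySystem("linear_1d", parameters={"slope": 1.0},
                            temperature=1.0, timestep=5e-3)
        r = mk.RestraintSpec(center=[0.0], force_constant=10.0)
        traj = mk.sample_restrained(sys1, r, n_steps=40000, burn_in=1000, seed=3, stride=2)
        f, se = mk.estimate_mean_force(traj, r)
        # mean force equals minus the free-energy gradient: -g = -1
        assert f[0] == pytest.approx(-1.0, abs=3 * max(se[0], 0.01))

    def test_harmonic_window_gaussian_arithmetic(self):
        # K=2 at 0, window at c=1 with k_r=10: <x> = k_r c/(K+k_r) = 0.8333,
        # mean force = k_r(<x>-c) = -K<x> = -1.667
        sys1 = mk.ToySystem("harmonic_nd", dimension=1, parameters={"k": 2.0},
                            temperature=1.0, timestep=8e-3)
        r = mk.RestraintSpec(center=[1.0], force_constant=10.0)
        traj = mk.sample_restrained(sys1, r, n_steps=40000, burn_in=1000, seed=4, stride=2)
        f, se = mk.estimate_mean_force(traj, r)
        assert f[0] == pytest.approx(-10.0 / 6.0, abs=3 * max(se[0], 0.02))

    def test_short_window_rejected(self):
        traj = mk.Trajectory(frames=np.zeros((5, 1)), potential_energy=np.zeros(5),
                             bias_energy=np.zeros(5), seed=0)
        r = mk.RestraintSpec(center=[0.0], force_constant=1.0)
        with pytest.raises(InputError):
            mk.estimate_mean_force(traj, r, n_blocks=5)


class TestRemoveExternalComponents:
    def test_uniform_xy_translation_removed(self, rng):
        coords = rng.standard_normal((10, 3))
        force = np.tile([1.0, -2.0, 0.0], (10, 1))
        out = mk.remove_external_components(force, coords)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_z_rotation_field_removed(self, rng):
        coords = rng.standard_normal((10, 3))
        cen = coords[:, :2].mean(axis=0)
        force = np.zeros((10, 3))
        force[:, 0] = -(coords[:, 1] - cen[1])
        force[:, 1] = coords[:, 0] - cen[0]
        out = mk.remove_external_components(force, coords)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_z_translation_retained(self, rng):
        coords = rng.standard_normal((8, 3))
        force = np.tile([0.0, 0.0, 3.0], (8, 1))
        out = mk.remove_external_components(force, coords)
        assert np.allclose(out, force, atol=1e-12)

    def test_projection_idempotent(self, rng):
        coords = rng.standard_normal((12, 3))
        force = rng.standard_normal((12, 3))
        once = mk.remove_external_components(force, coords)
        twice = mk.remove_external_components(once, coords)
        assert np.allclose(twice, once, atol=1e-12)


class TestUpdateImages:
    def test_zero_forces_leave_equidistant_path_unchanged(self):
        path = mk.reparameterize(mk.ImagePath(np.linspace([0, 0], [3, 4], 10)))
        cfg = mk.StringConfig(n_images=10, smoothing_kappa=0.0)
        out = mk.update_images(path, np.zeros((10, 2)), cfg, cycle=1)
        assert np.allclose(out.images, path.images, atol=1e-12)

    def test_terminal_fixed_while_cycles_below_threshold(self):
        path = mk.reparameterize(mk.ImagePath(np.linspace([0, 0], [9, 0], 10)))
        forces = np.ones((10, 2))
        cfg = mk.StringConfig(n_images=10, fixed_terminal_cycles=9,
                              step_size=0.01, smoothing_kappa=0.0)
        out = mk.update_images(path, forces, cfg, cycle=5)
        assert np.array_equal(out.images[0], path.images[0])
        assert np.array_equal(out.images[-1], path.images[-1])

    def test_released_terminal_ignores_tangential_force(self):
        path = mk.reparameterize(mk.ImagePath(np.linspace([0, 0], [9, 0], 10)))
        forces = np.zeros((10, 2))
        forces[-1] = [5.0, 0.0]  # purely tangential at the last image
        cfg = mk.StringConfig(n_images=10, fixed_terminal_cycles=0,
                              step_size=0.01, smoothing_kappa=0.0)
        out = mk.update_images(path, forces, cfg, cycle=1)
        assert np.allclose(out.images[-1], path.images[-1], atol=1e-12)

    def test_quadratic_bowl_interior_converges_to_axis(self):
        # MEP of an isotropic bowl between two points through the minimum is
        # the straight line; an offset path must flatten onto it
        sys1 = mk.ToySystem("harmonic_nd", dimension=2, parameters={"k": 1.0})
        start = np.array([-2.0, 0.0])
        end = np.array([2.0, 0.0])
        t = np.linspace(0, 1, 15)
        bent = np.stack([start[0] + 4 * t, 1.5 * np.sin(np.pi * t)], axis=1)
        path = mk.reparameterize(mk.ImagePath(bent))
        cfg = mk.StringConfig(n_images=15, step_size=0.05, smoothing_kappa=0.0,
                              fixed_terminal_cycles=10**9, n_cycles=10**9)
        from mepkit.toy_systems import potential_and_gradient
        for cycle in range(400):
            _, g = potential_and_gradient(sys1, path.images)
            path = mk.update_images(path, -g, cfg, cycle=1)
        assert np.all(np.abs(path.images[1:-1, 1]) < 1e-2)


class TestRunString:
    def test_double_well_images_monotone(self):
        sys1 = mk.ToySystem("double_well_1d", parameters={"h": 2.0, "a": 1.0},
                            temperature=0.2, timestep=2e-3)
        init = mk.ImagePath(np.linspace([-1.0], [1.0], 12))
        cfg = mk.StringConfig(n_images=12, restraint_k=150.0, mean_force_batch=400,
                              burn_in=100, step_size=1e-3, n_cycles=30,
                              fixed_terminal_cycles=5, smoothing_kappa=0.05)
        conv, diag = mk.run_string(sys1, init, cfg, seed=1)
        assert np.all(np.diff(conv.images[:, 0]) > 0)
        assert diag.n_cycles_run >= 5
        assert np.all(diag.rmsd_to_initial >= 0)

    def test_deterministic_for_fixed_seed(self):
        sys1 = mk.ToySystem("double_well_1d", parameters={"h": 2.0, "a": 1.0},
                            temperature=0.2, timestep=2e-3)
        init = mk.ImagePath(np.linspace([-1.0], [1.0], 8))
        cfg = mk.StringConfig(n_images=8, restraint_k=150.0, mean_force_batch=200,
                              burn_in=50, step_size=1e-3, n_cycles=5,
                              fixed_terminal_cycles=2)
        c1, _ = mk.run_string(sys1, init, cfg, seed=3)
        c2, _ = mk.run_string(sys1, init, cfg, seed=3)
        assert np.array_equal(c1.images, c2.images)

    def test_endpoints_bitwise_constant_while_fixed(self):
        sys1 = mk.ToySystem("double_well_1d", parameters={"h": 2.0, "a": 1.0},
                            temperature=0.2, timestep=2e-3)
        init = mk.reparameterize(mk.ImagePath(np.linspace([-1.0], [1.0], 8)))
        cfg = mk.StringConfig(n_images=8, restraint_k=150.0, mean_force_batch=200,
                              burn_in=50, step_size=1e-3, n_cycles=4,
                              fixed_terminal_cycles=4)
        conv, _ = mk.run_string(sys1, init, cfg, seed=4)
        assert np.array_equal(conv.images[0], init.images[0])
        assert np.array_equal(conv.images[-1], init.images[-1])

    def test_equidistance_after_run(self):
        sys1 = mk.ToySystem("double_well_1d", parameters={"h": 2.0, "a": 1.0},
                            temperature=0.2, timestep=2e-3)
        init = mk.ImagePath(np.linspace([-1.0], [1.0], 8))
        cfg = mk.StringConfig(n_images=8, restraint_k=150.0, mean_force_batch=200,
                              burn_in=50, step_size=1e-3, n_cycles=4,
                              fixed_terminal_cycles=2)
        conv, _ = mk.run_string(sys1, init, cfg, seed=5)
        gaps = conv.segment_lengths()
        assert gaps.std() / gaps.mean() < 1e-9


class TestZeroTemperatureString:
    def test_reduces_perpendicular_gradient(self, muller_brown):
        init = mk.ImagePath(np.linspace([-0.558, 1.442], [0.623, 0.028], 31))
        out = mk.zero_temperature_string(muller_brown, init, max_iter=4000, tol=1e-8)
        from mepkit.toy_systems import potential_and_gradient
        _, g = potential_and_gradient(muller_brown, out.images)
        t = _tangents(out.images)
        g_perp = g - np.sum(g * t, axis=1, keepdims=True) * t
        # interior perpendicular gradients collapse relative to full gradients
        ratio = np.linalg.norm(g_perp[1:-1], axis=1) / (np.linalg.norm(g[1:-1], axis=1) + 1e-12)
        assert np.median(ratio) < 0.1
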