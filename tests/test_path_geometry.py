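"""Path primitives: fitting, symmetrization, reparameterization, projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import mepkit as mk
from mepkit.errors import ConfigError, InputError
from mepkit.path_geometry import project_points


def _rz(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestFitXYPlane:
    def test_identity_for_identical_sets(self, rng):
        pts = rng.standard_normal((12, 3))
        out, ang, t = mk.fit_xy_plane(pts, pts)
        assert ang == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)
        assert np.allclose(out, pts)

    def test_recovers_inverse_of_rotation_and_shift(self, rng):
        ref = rng.standard_normal((15, 3))
        mob = ref @ _rz(np.deg2rad(30)).T + np.array([1.0, 2.0, 0.0])
        out, ang, t = mk.fit_xy_plane(mob, ref)
        assert np.rad2deg(ang) == pytest.approx(-30.0, abs=1e-9)
        assert np.allclose(t, [-1.0, -2.0], atol=1e-9)
        assert np.allclose(out, ref, atol=1e-9)

    def test_z_coordinates_pass_through_exactly(self, rng):
        mob = rng.standard_normal((20, 3))
        ref = rng.standard_normal((20, 3))
        out, _, _ = mk.fit_xy_plane(mob, ref)
        assert np.array_equal(out[:, 2], mob[:, 2])

    def test_matches_golden_section_angle_scan(self, rng):
        # brute-force 1-D search over the rotation angle as independent oracle
        mob = rng.standard_normal((50, 3))
        ref = mob + 0.1 * rng.standard_normal((50, 3))
        out, ang, _ = mk.fit_xy_plane(mob, ref)
        obj_fit = np.sum((out[:, :2] - ref[:, :2]) ** 2)

        def objective(theta):
            rot = _rz(theta)[:2, :2]
            pm = mob[:, :2] - mob[:, :2].mean(axis=0)
            pr = ref[:, :2] - ref[:, :2].mean(axis=0)
            return np.sum((pm @ rot.T - pr) ** 2)

        from scipy.optimize import minimize_scalar

        best = minimize_scalar(objective, bounds=(-np.pi, np.pi), method="bounded",
                               options={"xatol": 1e-12})
        pm = mob[:, :2] - mob[:, :2].mean(axis=0)
        pr = ref[:, :2] - ref[:, :2].mean(axis=0)
        rot = _rz(best.x)[:2, :2]
        assert obj_fit == pytest.approx(np.sum((pm @ rot.T - pr) ** 2), abs=1e-8)

    def test_degenerate_projection_rejected(self):
        pts = np.array([[0.0, 0.0, z] for z in range(4)])
        with pytest.raises(InputError, match="degenerate"):
            mk.fit_xy_plane(pts, pts + [0.0, 0.0, 1.0])


class TestSymmetricReference:
    def _symmetric_structure(self, rng, n_per_unit=4):
        base = rng.standard_normal((n_per_unit, 3))
        r = _rz(2 * np.pi / 3)
        pts = np.concatenate([base, base @ r.T, base @ r.T @ r.T])
        n = 3 * n_per_unit
        sigma = (np.arange(n) + 2 * n_per_unit) % n
        return pts, sigma

    def test_symmetric_input_is_fixed_point(self, rng):
        pts, sigma = self._symmetric_structure(rng)
        # T(X)[i] = R120 X[sigma[i]] must equal X for this construction
        r = _rz(2 * np.pi / 3)
        assert np.allclose(pts[sigma] @ r.T, pts, atol=1e-12)
        out = mk.symmetric_reference([pts, pts, pts], sigma)
        assert np.allclose(out, pts, atol=1e-9)

    def test_output_invariant_under_rotation_and_permutation(self, rng):
        _, sigma = self._symmetric_structure(rng)
        states = [rng.standard_normal((12, 3)) for _ in range(3)]
        out = mk.symmetric_reference(states, sigma)
        r = _rz(2 * np.pi / 3)
        assert np.allclose(out[sigma] @ r.T, out, atol=1e-6)

    def test_missing_permutation_rejected(self, rng):
        states = [rng.standard_normal((6, 3)) for _ in range(3)]
        with pytest.raises(InputError, match="permutation"):
            mk.symmetric_reference(states)

    def test_two_point_toy_matches_hand_average(self):
        # one point per subunit on the unit circle, plus one shared apex on z
        r = _rz(2 * np.pi / 3)
        unit = np.array([1.0, 0.0, 0.0])
        pts = np.stack([unit, r @ unit, r @ r @ unit])
        sigma = np.array([2, 0, 1])
        out = mk.symmetric_reference([pts, pts, pts], sigma)
        assert np.allclose(out, pts, atol=1e-12)


class TestReparameterize:
    def test_simple_arithmetic_case(self):
        path = mk.ImagePath([[0.0], [1.0], [4.0]])
        out = mk.reparameterize(path)
        assert np.allclose(out.images.ravel(), [0.0, 2.0, 4.0])

    def test_idempotent(self, rng):
        path = mk.ImagePath(np.cumsum(rng.uniform(0.1, 1.0, (30, 2)), axis=0))
        once = mk.reparameterize(path)
        twice = mk.reparameterize(once)
        assert np.allclose(twice.images, once.images, atol=1e-12)

    def test_equidistance_and_endpoints(self, rng):
        path = mk.ImagePath(np.cumsum(rng.uniform(0.1, 1.0, (30, 2)), axis=0))
        out = mk.reparameterize(path)
        gaps = out.segment_lengths()
        assert gaps.std() / gaps.mean() < 1e-9
        assert np.allclose(out.images[0], path.images[0])
        assert np.allclose(out.images[-1], path.images[-1])

    def test_arc_length_preserved_on_smooth_path(self):
        # well-resolved smooth curve: corner-cutting is O(gap^2 curvature)
        t = np.linspace(0.0, 1.0, 50)
        path = mk.ImagePath(np.stack([t, np.sin(2 * t)], axis=1))
        out = mk.reparameterize(path)
        assert out.arc_length() == pytest.approx(path.arc_length(), rel=1e-3)

    def test_arc_length_exact_on_collinear_path(self):
        path = mk.ImagePath([[0.0], [0.3], [1.1], [4.0]])
        out = mk.reparameterize(path)
        assert out.arc_length() == pytest.approx(4.0, rel=1e-12)

    def test_duplicate_images_merged_with_warning(self):
        path = mk.ImagePath([[0.0], [1.0], [1.0], [3.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            out = mk.reparameterize(path)
        assert out.n_images == 4
        assert np.allclose(out.images.ravel(), [0.0, 1.0, 2.0, 3.0])


class TestSmoothPath:
    def test_kappa_zero_is_identity(self, zigzag_path):
        out = mk.smooth_path(zigzag_path, 0.0)
        assert np.array_equal(out.images, zigzag_path.images)

    def test_collinear_path_is_fixed_point(self):
        path = mk.ImagePath(np.linspace([0, 0], [4, 4], 5))
        out = mk.smooth_path(path, 0.7)
        assert np.allclose(out.images, path.images, atol=1e-12)

    def test_zigzag_arithmetic(self, zigzag_path):
        out = mk.smooth_path(zigzag_path, 0.2)
        assert np.allclose(out.images[1], [1.0, 0.8])
        assert np.array_equal(out.images[0], zigzag_path.images[0])
        assert np.array_equal(out.images[2], zigzag_path.images[2])

    def test_curvature_sum_strictly_decreases(self, rng):
        pts = np.cumsum(rng.uniform(0.1, 1.0, (12, 2)), axis=0)
        pts[:, 1] += rng.standard_normal(12)
        path = mk.ImagePath(pts)

        def curvature_sum(p):
            second = p.images[2:] - 2 * p.images[1:-1] + p.images[:-2]
            return np.sum(second**2)

        out = mk.smooth_path(path, 0.3)
        assert curvature_sum(out) < curvature_sum(path)

    def test_invalid_kappa_rejected(self, zigzag_path):
        with pytest.raises(ConfigError):
            mk.smooth_path(zigzag_path, 1.0)


class TestProjection:
    def test_sample_at_image_has_zero_distance(self):
        path = mk.ImagePath([[0.0, 0.0], [1.0, 0.0], [2.0, 1.0]])
        for i, img in enumerate(path.images):
            pr = mk.project_onto_path(img, path)
            assert pr.progress == pytest.approx(i)
            assert pr.orthogonal_sq_distance == pytest.approx(0.0, abs=1e-12)
            assert pr.image_coordinate == pytest.approx(i + 1)

    def test_straight_line_fraction(self):
        path = mk.ImagePath([[0.0], [10.0]])
        pr = mk.project_onto_path([2.5], path)
        assert pr.normalized == pytest.approx(0.25)
        assert pr.orthogonal_sq_distance == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_distance_pythagoras(self):
        path = mk.ImagePath([[0.0, 0.0], [10.0, 0.0]])
        pr = mk.project_onto_path([3.0, 4.0], path)
        assert pr.orthogonal_sq_distance == pytest.approx(16.0)
        assert pr.progress == pytest.approx(0.3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.float64, (2,), elements=st.floats(-5, 5)))
    def test_foot_point_reprojects_to_itself(self, sample):
        path = mk.ImagePath([[0.0, 0.0], [1.0, 0.5], [2.0, 0.0], [3.0, 1.0]])
        pr = mk.project_onto_path(sample, path)
        # reconstruct the foot point and reproject
        seg = min(int(pr.progress), path.n_images - 2)
        frac = pr.progress - seg
        foot = path.images[seg] + frac * (path.images[seg + 1] - path.images[seg])
        pr2 = mk.project_onto_path(foot, path)
        assert pr2.orthogonal_sq_distance == pytest.approx(0.0, abs=1e-20)
        assert pr2.progress == pytest.approx(pr.progress, abs=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        path = mk.ImagePath(np.cumsum(rng.uniform(0.1, 1.0, (8, 2)), axis=0))
        samples = rng.standard_normal((40, 2)) * 3
        prog, dsq = project_points(samples, path)
        for n in range(40):
            pr = mk.project_onto_path(samples[n], path)
            assert prog[n] == pytest.approx(pr.progress)
            assert dsq[n] == pytest.approx(pr.orthogonal_sq_distance)


class TestMonitors:
    def test_pair_distance_and_com_z(self):
        frames = np.array([[[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]],
                           [[0.0, 0.0, 1.0], [0.0, 0.0, 3.0]]])
        obs = mk.monitor_observables(frames, pairs=[(0, 1)], z_groups=[[0, 1]])
        assert obs["distances"][0, 0] == pytest.approx(5.0)
        assert obs["com_z"][1, 0] == pytest.approx(2.0)

    def test_matches_bruteforce_loop(self, rng):
        frames = rng.standard_normal((100, 6, 3))
        pairs = [(0, 3), (2, 5)]
        groups = [[0, 1], [2, 3, 4]]
        obs = mk.monitor_observables(frames, pairs=pairs, z_groups=groups)
        for f in range(100):
            for k, (i, j) in enumerate(pairs):
                d = np.sqrt(sum((frames[f, i, a] - frames[f, j, a]) ** 2 for a in range(3)))
                assert obs["distances"][f, k] == pytest.approx(d)
            for k, grp in enumerate(groups):
                z = sum(frames[f, i, 2] for i in grp) / len(grp)
                assert obs["com_z"][f, k] == pytest.approx(z)

    def test_empty_group_rejected(self, rng):
        frames = rng.standard_normal((2, 3, 3))
        with pytest.raises(InputError):
            mk.monitor_observables(frames, z_groups=[[]])


class TestImagePathIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        path = mk.ImagePath(rng.standard_normal((5, 3)), metadata={"cycle": 4})
        path.to_csv(tmp_path / "p.csv")
        back = mk.ImagePath.from_csv(tmp_path / "p.csv")
        assert np.array_equal(back.images, path.images)
        assert back.metadata["cycle"] == 4
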