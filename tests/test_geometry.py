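"""Superposition, RMSD, smoothing, and screw decomposition.

The Kabsch fit is checked against a brute-force quaternion-grid oracle that
knows nothing about the SVD solution; screw decomposition is checked by
reconstructing the rigid motion it claims to describe.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nbdtraj as nt
from nbdtraj.errors import DegenerateGeometryError
from nbdtraj.geometry import rotation_about_axis, screw_compose


def _quat_to_matrices(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q.T
    R = np.empty((len(q), 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def quaternion_grid_rmsd(mobile: np.ndarray, target: np.ndarray,
                         n_samples: int = 200_000, seed: int = 0) -> float:
    """Brute-force minimum RMSD over rotations: dense random unit quaternions
    followed by shrinking local refinement around the best one.

    Independent of the SVD route: centre both sets, apply every sampled
    rotation to the mobile set, take the best RMSD.
    """
    rng = np.random.default_rng(seed)
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)

    def best(q):
        q = q / np.linalg.norm(q, axis=1, keepdims=True)
        rotated = np.einsum("nij,kj->nki", _quat_to_matrices(q), P)
        sq = ((rotated - Q) ** 2).sum(axis=(1, 2)) / len(P)
        i = int(np.argmin(sq))
        return float(np.sqrt(sq[i])), q[i]

    value, q_best = best(rng.normal(size=(n_samples, 4)))
    for scale in (0.05, 0.01, 0.002, 0.0005):
        v, q = best(q_best + scale * rng.normal(size=(20_000, 4)))
        if v < value:
            value, q_best = v, q
    return value


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        fit = nt.kabsch_fit(pts, pts)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(fit.translation, 0, atol=1e-10)
        assert fit.rmsd <= 1e-12

    def test_recovers_forced_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3)) * 5
        R = rotation_about_axis([0, 0, 1], 30.0)
        target = pts @ R.T + np.array([1.0, 2.0, 3.0])
        fit = nt.kabsch_fit(pts, target)
        angle = np.degrees(np.arccos(np.clip((np.trace(fit.rotation) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(30.0, abs=1e-6)
        assert fit.rmsd <= 1e-9

    def test_noise_floor_matches_expected_scale(self):
        # fitted RMSD on sigma-noised copies concentrates near sigma*sqrt(3)
        sigma = 0.1
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(10, 3)) * 8
            noisy = pts + rng.normal(0, sigma, pts.shape)
            vals.append(nt.kabsch_fit(pts, noisy).rmsd)
        vals = np.array(vals)
        assert ((0.5 * sigma * np.sqrt(3) <= vals)
                & (vals <= 1.5 * sigma * np.sqrt(3))).mean() > 0.9

    def test_agrees_with_quaternion_grid_oracle(self):
        rng = np.random.default_rng(42)
        mobile = rng.normal(size=(4, 3)) * 4
        target = rng.normal(size=(4, 3)) * 4
        fit = nt.kabsch_fit(mobile, target)
        oracle = quaternion_grid_rmsd(mobile, target)
        assert fit.rmsd <= oracle + 1e-12   # never worse than brute force
        assert abs(fit.rmsd - oracle) <= 1e-3

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            nt.kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            nt.kabsch_fit(line, line)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), angle=st.floats(0, 180),
           tx=st.floats(-20, 20))
    def test_rmsd_invariant_under_common_rigid_transform(self, seed, angle, tx):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3)) * 3
        b = a + rng.normal(0, 0.5, a.shape)
        base = nt.kabsch_fit(a, b).rmsd
        R = rotation_about_axis([1, 1, 1], angle)
        t = np.array([tx, -tx, 2.0])
        moved = nt.kabsch_fit(a @ R.T + t, b @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)


class TestMovingAverage:
    def test_hand_computed_window(self):
        assert np.allclose(nt.moving_average([1, 2, 3, 4], 2), [1.5, 2.5, 3.5])

    def test_constant_series_unchanged(self):
        assert np.allclose(nt.moving_average(np.full(30, 2.5), 20), 2.5)

    def test_period_one_is_identity(self):
        x = np.arange(7.0)
        assert np.array_equal(nt.moving_average(x, 1), x)

    def test_period_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            nt.moving_average([1.0, 2.0], 5)


class TestScrewDecomposition:
    def test_identity_motion(self):
        coords = np.random.default_rng(0).normal(size=(6, 3))
        s = nt.screw_decomposition(np.eye(3), np.zeros(3), coords)
        assert s.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert not s.axis_defined
        assert s.centre_displacement == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_about_offset_axis(self):
        R, t = screw_compose(90.0, [0, 0, 1], [1.0, 0.0, 0.0])
        coords = np.random.default_rng(1).normal(size=(5, 3)) + [3, 0, 0]
        s = nt.screw_decomposition(R, t, coords)
        assert s.angle_deg == pytest.approx(90.0, abs=1e-9)
        assert np.allclose(np.abs(s.axis), [0, 0, 1], atol=1e-9)
        assert s.pivot[0] == pytest.approx(1.0, abs=1e-6)
        assert s.pivot[1] == pytest.approx(0.0, abs=1e-6)

    def test_random_screw_reconstruction(self):
        rng = np.random.default_rng(7)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        pivot = rng.normal(size=3) * 10
        R, t = screw_compose(25.0, axis, pivot, pitch=2.0)
        coords = rng.normal(size=(10, 3)) * 6
        s = nt.screw_decomposition(R, t, coords)
        R2, t2 = screw_compose(s.angle_deg, s.axis, s.pivot, s.pitch)
        moved = coords @ R.T + t
        rebuilt = coords @ R2.T + t2
        assert np.abs(moved - rebuilt).max() <= 1e-6

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(angle=st.floats(1.5, 179.0), pitch=st.floats(-5, 5),
           seed=st.integers(0, 10_000))
    def test_compose_decompose_round_trip(self, angle, pitch, seed):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        pivot = rng.normal(size=3) * 8
        R, t = screw_compose(angle, axis, pivot, pitch)
        coords = rng.normal(size=(6, 3)) * 5
        s = nt.screw_decomposition(R, t, coords)
        assert s.angle_deg == pytest.approx(angle, abs=1e-6)
        assert abs(np.dot(s.axis, axis)) == pytest.approx(1.0, abs=1e-9)
        sign = np.sign(np.dot(s.axis, axis))
        assert s.pitch * sign == pytest.approx(pitch, abs=1e-6)
        # recovered pivot lies on the planted axis line
        d = s.pivot - pivot
        assert np.linalg.norm(d - (d @ axis) * axis) <= 1e-6

    def test_near_identity_flags_axis_undefined(self):
        R, t = screw_compose(0.5, [0, 0, 1], [0, 0, 0])
        s = nt.screw_decomposition(R, t, np.eye(3) * 4)
        assert not s.axis_defined
        assert s.angle_deg == pytest.approx(0.5, abs=1e-6)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, dimer, dimer_ca_selection):
        frames = np.repeat(dimer.coords[None], 5, axis=0)
        traj = nt.Trajectory(dimer, frames, np.arange(5) * 7.5)
        series = nt.rmsd_series(traj, dimer_ca_selection, dimer_ca_selection, dimer)
        assert np.abs(series).max() <= 1e-9

    def test_rigid_rotations_give_zero(self, dimer, dimer_ca_selection):
        frames = np.stack([
            dimer.coords @ rotation_about_axis([0, 1, 0], a).T + [a, 0, -a]
            for a in (0.0, 35.0, 170.0)])
        traj = nt.Trajectory(dimer, frames, np.arange(3) * 7.5)
        series = nt.rmsd_series(traj, dimer_ca_selection, dimer_ca_selection, dimer)
        assert np.abs(series).max() <= 1e-8

    def test_opening_moves_dimer_but_not_subdomains(self, dimer, scheme,
                                                    dimer_ca_selection):
        traj, _ = nt.generate_opening_trajectory(dimer, theta_max=20.0,
                                                 n_frames=60, noise_sigma=0.0,
                                                 seed=0)
        dimer_series = nt.rmsd_series(traj, dimer_ca_selection,
                                      dimer_ca_selection, dimer)
        assert dimer_series[-1] > 1.0
        assert np.all(np.diff(dimer_series) >= -1e-9)
        for chain in scheme.chains:
            core = nt.select_calpha(dimer, chain, scheme.core)
            sub = nt.rmsd_series(traj, core, core, dimer)
            assert np.abs(sub).max() <= 1e-8  # rigid blocks fit back exactly
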