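"""Essential-dynamics PCA: eigendecomposition oracle, projections, overlap."""

import numpy as np
import pytest

import nbdtraj as nt
from nbdtraj.pca import _aligned_coordinates


def _static_traj(struct, n=10):
    return nt.Trajectory(struct, np.repeat(struct.coords[None], n, axis=0),
                         np.arange(n) * 7.5)


def _orthogonal_displacement(rng, sel, struct):
    """A 3N pattern with no net translation/rotation about the reference."""
    coords = sel.coords(struct.coords)
    n = len(coords)
    d = rng.normal(size=(n, 3))
    d -= d.mean(axis=0)                       # remove net translation
    centred = coords - coords.mean(axis=0)
    # remove infinitesimal rigid rotations r_k x x_i
    basis = []
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        basis.append(np.cross(np.broadcast_to(e, (n, 3)), centred).ravel())
    v = d.ravel()
    for b in basis:
        v -= (v @ b) / (b @ b) * b
    v /= np.linalg.norm(v)
    return v.reshape(n, 3)


class TestFitPca:
    def test_identical_frames_have_zero_eigenvalues(self, dimer, dimer_ca_selection):
        model = nt.fit_pca(_static_traj(dimer), dimer_ca_selection, dimer)
        assert np.abs(model.eigenvalues).max() <= 1e-12

    def test_rank_one_displacement_recovered(self, dimer, dimer_ca_selection):
        rng = np.random.default_rng(5)
        sel = dimer_ca_selection
        d = _orthogonal_displacement(rng, sel, dimer)
        s = 2.0 * np.sin(np.linspace(0, 4 * np.pi, 40))
        s -= s.mean()
        frames = np.repeat(dimer.coords[None], 40, axis=0)
        frames[:, sel.index_array, :] += s[:, None, None] * d[None]
        traj = nt.Trajectory(dimer, frames, np.arange(40) * 7.5)
        model = nt.fit_pca(traj, sel, dimer)
        assert model.fractions[0] == pytest.approx(1.0, abs=1e-6)
        overlap = abs(model.modes[0] @ d.ravel())
        assert overlap == pytest.approx(1.0, abs=1e-6)

    def test_matches_svd_oracle(self, opening_run, dimer, dimer_ca_selection):
        traj, _ = opening_run
        short = nt.Trajectory(dimer, traj.frames[:80], traj.times[:80])
        model = nt.fit_pca(short, dimer_ca_selection, dimer)
        X = _aligned_coordinates(short, dimer_ca_selection, dimer)
        Xc = X - X.mean(axis=0)
        svals = np.linalg.svd(Xc, compute_uv=False)
        expected = svals ** 2 / X.shape[0]
        k = len(expected)
        assert np.abs(model.eigenvalues[:k] - expected).max() <= 1e-8

    def test_planted_variance_ratio_recovered(self, dimer, dimer_ca_selection):
        rng = np.random.default_rng(17)
        sel = dimer_ca_selection
        d1 = _orthogonal_displacement(rng, sel, dimer)
        d2 = _orthogonal_displacement(rng, sel, dimer)
        v2 = d2.ravel() - (d2.ravel() @ d1.ravel()) * d1.ravel()
        d2 = (v2 / np.linalg.norm(v2)).reshape(d2.shape)
        n = 500
        # standardise the amplitude draws so the realised variances are
        # exactly 4 and 1 and the check isolates estimator error
        a1 = rng.normal(size=n)
        a1 = (a1 - a1.mean()) / a1.std() * 2.0
        a2 = rng.normal(size=n)
        a2 = (a2 - a2.mean()) / a2.std() * 1.0
        frames = np.repeat(dimer.coords[None], n, axis=0)
        frames[:, sel.index_array, :] += (a1[:, None, None] * d1[None]
                                          + a2[:, None, None] * d2[None])
        frames += rng.normal(0, 0.05, frames.shape)
        traj = nt.Trajectory(dimer, frames, np.arange(n) * 7.5)
        model = nt.fit_pca(traj, sel, dimer)
        ratio = model.eigenvalues[0] / model.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_fractions_sum_to_one(self, opening_model):
        f = opening_model.fractions
        assert np.all(f >= 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_frames_rejected(self, dimer, dimer_ca_selection):
        with pytest.raises(ValueError):
            nt.fit_pca(_static_traj(dimer, n=1), dimer_ca_selection, dimer)


class TestProjection:
    def test_mean_projects_to_zero(self, opening_model, dimer):
        mean_struct = dimer.subset(opening_model.selection.indices).with_coords(
            opening_model.mean.reshape(-1, 3))
        p = nt.project_structure(mean_struct, opening_model, 1, align=False)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_displaced_mean_projects_to_amplitude(self, opening_model, dimer):
        coords = (opening_model.mean + 2.5 * opening_model.modes[0]).reshape(-1, 3)
        struct = dimer.subset(opening_model.selection.indices).with_coords(coords)
        p = nt.project_structure(struct, opening_model, 1, align=False)
        assert p == pytest.approx(2.5, abs=1e-9)

    def test_self_projection_variance_equals_eigenvalue(self, opening_run,
                                                        opening_model):
        traj, _ = opening_run
        proj = nt.project(traj, opening_model, 1)
        var = np.mean((proj.values - proj.values.mean()) ** 2)
        assert var == pytest.approx(opening_model.eigenvalues[0], rel=1e-6)

    def test_mode_out_of_range(self, opening_run, opening_model):
        traj, _ = opening_run
        with pytest.raises(ValueError):
            nt.project(traj, opening_model, 10 ** 6)

    def test_flip_sign(self, opening_run, opening_model):
        traj, _ = opening_run
        a = nt.project(traj, opening_model, 1)
        b = nt.project(traj, opening_model, 1, flip_sign=True)
        assert np.allclose(a.values, -b.values)


class TestSubspaceOverlap:
    def test_own_mode_is_contained(self, opening_model):
        assert nt.subspace_overlap(opening_model.modes[0], opening_model, 2) \
            == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_vector_is_zero(self, opening_model):
        v = opening_model.modes[50]
        assert nt.subspace_overlap(v, opening_model, 2) == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_combination(self, opening_model):
        v = (opening_model.modes[0] + opening_model.modes[1]) / np.sqrt(2)
        assert nt.subspace_overlap(v, opening_model, 1) \
            == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_non_unit_vector_normalised_with_warning(self, opening_model):
        with pytest.warns(UserWarning, match="normalising"):
            val = nt.subspace_overlap(3.0 * opening_model.modes[0],
                                      opening_model, 1)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_full_mode_set_contains_configurational_vectors(self, opening_model):
        # any direction actually explored by the ensemble lies in the span of
        # all modes with nonzero eigenvalue (rigid-body motions are removed
        # by the alignment, up to residual)
        rng = np.random.default_rng(3)
        w = rng.normal(size=20)
        v = w @ opening_model.modes[:20]
        v /= np.linalg.norm(v)
        k = int(np.sum(opening_model.eigenvalues > 1e-12))
        assert nt.subspace_overlap(v, opening_model, k) == pytest.approx(1.0, abs=1e-6)


class TestPearson:
    def test_affine_relation_is_perfect(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        assert nt.pearson_correlation(a, 2 * a + 1) == pytest.approx(1.0)
        assert nt.pearson_correlation(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r = nt.pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nt.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestExtremeFrames:
    def test_monotone_projection_gives_first_and_last(self, dimer,
                                                      dimer_ca_selection, scheme):
        traj, _ = nt.generate_opening_trajectory(dimer, theta_max=15.0,
                                                 n_frames=60, noise_sigma=0.0,
                                                 seed=0)
        model = nt.fit_pca(traj, dimer_ca_selection, dimer)
        proj = nt.project(traj, model, 1)
        lo, hi, (t_lo, t_hi) = nt.extreme_frames(proj, traj, model)
        assert {t_lo, t_hi} == {traj.times[0], traj.times[-1]}

    def test_unique_extremum_location(self, dimer, dimer_ca_selection):
        from nbdtraj.pca import ProjectionSeries
        frames = np.repeat(dimer.coords[None], 10, axis=0)
        traj = nt.Trajectory(dimer, frames, np.arange(10) * 7.5)
        model = nt.fit_pca(traj, dimer_ca_selection, dimer)
        values = np.zeros(10)
        values[7] = 5.0
        proj = ProjectionSeries(traj.times, values, 1)
        _, hi, (_, t_hi) = nt.extreme_frames(proj, traj, model)
        assert t_hi == traj.times[7]

    def test_max_projection_frame_has_widest_apo_site(self, opening_run,
                                                      opening_model, scheme):
        traj, _ = opening_run
        proj = nt.project(traj, opening_model, 1)
        opening = nt.opening_distance_series(traj, scheme)["site_apo"].values
        r = nt.pearson_correlation(proj.values, opening)
        i_star = int(np.argmax(proj.values if r > 0 else -proj.values))
        # the frame at the projection extreme is among the widest-open frames
        assert opening[i_star] >= np.quantile(opening, 0.95)


class TestInterpolateMode:
    def test_endpoint_only(self, opening_model):
        traj = nt.interpolate_mode(opening_model, 1, -3.0, 3.0, n_inner=0)
        assert traj.n_frames == 2

    def test_eight_inner_structures(self, opening_model):
        traj = nt.interpolate_mode(opening_model, 1, -9.0, 9.0, n_inner=8)
        assert traj.n_frames == 10
        ps = [nt.project_structure(traj.frame_structure(i), opening_model, 1,
                                   align=False)
              for i in range(traj.n_frames)]
        assert np.allclose(np.diff(ps), 18.0 / 9.0, atol=1e-9)

    def test_reprojection_round_trip(self, opening_model):
        traj = nt.interpolate_mode(opening_model, 1, -2.0, 5.0, n_inner=3)
        targets = np.linspace(-2.0, 5.0, 5)
        for i, target in enumerate(targets):
            p = nt.project_structure(traj.frame_structure(i), opening_model, 1,
                                     align=False)
            assert p == pytest.approx(target, abs=1e-9)

    def test_invalid_bounds(self, opening_model):
        with pytest.raises(ValueError):
            nt.interpolate_mode(opening_model, 1, 2.0, -2.0)
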