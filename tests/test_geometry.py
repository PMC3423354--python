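import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindmode import (
    Frame,
    GeometryError,
    NoIntersectionError,
    ProjectionPlane,
    kabsch_fit,
    line_plane_intersection,
    projection_timeseries,
    rmsd,
    rmsd_timeseries,
    rmsf_per_atom,
)
from bindmode.synthetic import (
    default_ligand_centers,
    gen_harmonic_protein,
    gen_pocket_trajectory,
)

from conftest import make_trajectory, random_rigid_transform


class TestKabschFit:
    def test_identical_sets_give_zero_and_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        rt, value = kabsch_fit(pts, pts)
        assert value < 1e-12
        assert np.allclose(rt.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(8, 3)) * 5.0
        R, t = random_rigid_transform(rng)
        rt, value = kabsch_fit(ref, ref @ R.T + t)
        assert value < 1e-8

    def test_matches_rotation_grid_oracle(self):
        # brute-force search over a dense Euler-angle grid can do no better
        # than the closed-form fit, and approaches it to grid resolution
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(4, 3)) * 3.0
        mov = ref + rng.normal(size=(4, 3)) * 0.4
        _, fitted = kabsch_fit(ref, mov)
        c_ref, c_mov = ref.mean(axis=0), mov.mean(axis=0)
        step = np.radians(6.0)
        grid = np.arange(-np.pi, np.pi, step)
        half = np.arange(-np.pi / 2, np.pi / 2, step)
        best = np.inf
        for a in grid:
            for b in half:
                for c in grid:
                    R = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                    cand = (mov - c_mov) @ R.T + c_ref
                    best = min(best, rmsd(ref, cand))
        assert fitted <= best + 1e-12
        assert best - fitted < 0.05  # grid resolution slack

    def test_agrees_with_scipy_align_vectors(self, rng):
        ref = rng.normal(size=(10, 3))
        mov = ref + rng.normal(size=(10, 3)) * 0.3
        _, ours = kabsch_fit(ref, mov)
        rot, _ = Rotation.align_vectors(
            ref - ref.mean(axis=0), mov - mov.mean(axis=0)
        )
        aligned = rot.apply(mov - mov.mean(axis=0)) + ref.mean(axis=0)
        assert abs(ours - rmsd(ref, aligned)) < 1e-8

    def test_fitted_rmsd_never_exceeds_unfitted(self, rng):
        for _ in range(20):
            a = rng.normal(size=(5, 3)) * 4
            b = rng.normal(size=(5, 3)) * 4
            _, fitted = kabsch_fit(a, b)
            assert fitted <= rmsd(a, b) + 1e-10

    def test_collinear_points_raise(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(GeometryError):
            kabsch_fit(line, line)

    def test_too_few_points_raise(self):
        with pytest.raises(GeometryError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdTimeseries:
    def test_identical_frames_are_zero(self, static_trajectory):
        ref = static_trajectory.frames[0]
        sel = np.arange(static_trajectory.n_atoms)
        series = rmsd_timeseries(static_trajectory, ref, sel, sel)
        assert np.all(series.values < 1e-10)

    def test_rigidly_displaced_frames_are_zero(self, rng):
        base = rng.normal(size=(8, 3)) * 4
        frames = []
        for _ in range(10):
            R, t = random_rigid_transform(rng)
            frames.append(base @ R.T + t)
        traj = make_trajectory(np.stack(frames))
        sel = np.arange(8)
        series = rmsd_timeseries(traj, Frame(0.0, base), sel, sel)
        assert np.all(series.values < 1e-8)

    def test_gaussian_noise_matches_sigma_sqrt3(self, rng):
        # static anchor atoms carry the fit; noisy atoms carry the metric
        sigma = 0.4
        anchors = rng.normal(size=(4, 3)) * 6
        noisy_ref = rng.normal(size=(100, 3)) * 6
        base = np.vstack([anchors, noisy_ref])
        frames = [base]
        for _ in range(200):
            jitter = np.vstack(
                [np.zeros((4, 3)), rng.normal(0, sigma, (100, 3))]
            )
            frames.append(base + jitter)
        traj = make_trajectory(np.stack(frames))
        series = rmsd_timeseries(
            traj, Frame(0.0, base), np.arange(4), np.arange(4, 104)
        )
        mean_rmsd = series.values[1:].mean()
        assert abs(mean_rmsd - sigma * np.sqrt(3)) < 0.05 * sigma * np.sqrt(3)

    def test_out_of_range_selection_raises(self, static_trajectory):
        ref = static_trajectory.frames[0]
        with pytest.raises(GeometryError):
            rmsd_timeseries(static_trajectory, ref, [0, 99], [0])


class TestRmsfPerAtom:
    def test_static_trajectory_is_zero(self, static_trajectory):
        sel = np.arange(static_trajectory.n_atoms)
        values = rmsf_per_atom(
            static_trajectory, static_trajectory.frames[0], sel
        )
        assert np.all(values.values < 1e-10)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        sigmas = np.array([0.0] * 5 + [0.5] * 30)
        traj, ref = gen_harmonic_protein(sigmas, n_frames=1000, seed=11)
        values = rmsf_per_atom(
            traj, ref, np.arange(35), fit_sel=np.arange(5)
        )
        got = values.values[5:]
        expected = 0.5 * np.sqrt(3)
        assert np.all(np.abs(got - expected) < 0.05 * expected)

    def test_single_mobile_atom_detected(self, rng):
        base = rng.normal(size=(6, 3)) * 5
        frames = [base.copy() for _ in range(50)]
        for i, f in enumerate(frames):
            f[3] = base[3] + [0, 0, 0.1 * i]
        traj = make_trajectory(np.stack(frames))
        values = rmsf_per_atom(
            traj, Frame(0.0, base), np.arange(6), fit_sel=np.array([0, 1, 2, 4, 5])
        )
        assert values.values[3] > 0.5
        assert np.all(values.values[[0, 1, 2, 4, 5]] < 1e-8)

    def test_rmsf_ordering_follows_sigma_ordering(self):
        sigmas = np.array([0.1, 0.3, 0.6, 0.9, 0.0, 0.0, 0.0])
        traj, ref = gen_harmonic_protein(sigmas, n_frames=800, seed=5)
        values = rmsf_per_atom(traj, ref, np.arange(7), fit_sel=np.arange(4, 7))
        assert list(np.argsort(values.values[:4])) == [0, 1, 2, 3]

    def test_single_frame_warns(self, rng):
        traj = make_trajectory(rng.normal(size=(1, 5, 3)))
        with pytest.warns(UserWarning):
            rmsf_per_atom(traj, traj.frames[0], np.arange(5))

    def test_invariant_to_global_rigid_motion(self, rng):
        sigmas = np.full(12, 0.4)
        traj, ref = gen_harmonic_protein(sigmas, n_frames=100, seed=2)
        base = rmsf_per_atom(traj, ref, np.arange(12))
        moved_frames = []
        for fr in traj.frames:
            R, t = random_rigid_transform(rng)
            moved_frames.append(fr.coords @ R.T + t)
        moved = make_trajectory(np.stack(moved_frames))
        again = rmsf_per_atom(moved, ref, np.arange(12))
        assert np.allclose(base.values, again.values, atol=1e-8)


class TestLinePlaneIntersection:
    def test_axis_aligned_case(self):
        plane = ProjectionPlane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        res = line_plane_intersection((0.25, 0.5, 1.0), (0.25, 0.5, 2.0), plane)
        assert np.allclose([res.t, res.u, res.v], [-1.0, 0.25, 0.5])
        assert np.allclose(res.point, [0.25, 0.5, 0.0])

    def test_line_origin_on_plane_gives_t_zero(self):
        plane = ProjectionPlane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        res = line_plane_intersection((0.3, 0.4, 0.0), (0, 0, 1.0), plane)
        assert abs(res.t) < 1e-12

    def test_both_parametric_forms_agree_on_random_inputs(self, rng):
        n_done = 0
        while n_done < 300:
            p = rng.normal(size=(3, 3)) * 5
            la, lb = rng.normal(size=(2, 3)) * 5
            try:
                plane = ProjectionPlane(*p)
                res = line_plane_intersection(la, lb, plane)
            except (GeometryError, NoIntersectionError):
                continue
            line_pt = la + (lb - la) * res.t
            plane_pt = (
                plane.p0
                + (plane.p1 - plane.p0) * res.u
                + (plane.p2 - plane.p0) * res.v
            )
            assert np.allclose(line_pt, plane_pt, atol=1e-8)
            assert np.allclose(res.point, line_pt, atol=1e-8)
            n_done += 1

    def test_parallel_line_raises_not_nan(self):
        plane = ProjectionPlane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        with pytest.raises(NoIntersectionError):
            line_plane_intersection((0, 0, 1.0), (1.0, 1.0, 1.0), plane)

    def test_collinear_plane_anchors_raise(self):
        with pytest.raises(GeometryError):
            ProjectionPlane((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_coincident_line_points_raise(self):
        plane = ProjectionPlane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        with pytest.raises(GeometryError):
            line_plane_intersection((1, 1, 1), (1, 1, 1), plane)


class TestProjectionTimeseries:
    def test_fixed_probe_gives_constant_uv(self, rng):
        anchors = np.array([[6.0, 0, 0], [-3.0, 5.2, 0], [-3.0, -5.2, 0]])
        probe = np.array([[1.0, 0.5, 3.0]])
        base = np.vstack([anchors, probe])
        traj = make_trajectory(np.repeat(base[None], 15, axis=0))
        df, excluded = projection_timeseries(traj, [3], [0, 1, 2])
        assert excluded == 0
        assert df["u"].std() < 1e-12 and df["v"].std() < 1e-12

    def test_planted_two_mode_scatter_separates(self):
        seq = np.array([0] * 400 + [1] * 400)
        result = gen_pocket_trajectory(
            default_ligand_centers(separation=4.0),
            noise_sigma=0.3,
            n_frames=800,
            seed=9,
            state_sequence=seq,
        )
        traj = result.trajectory
        probe = [int(result.ligand_indices[2])]
        df, _ = projection_timeseries(traj, probe, list(result.plane_indices))
        u = df["u"].to_numpy()
        mid = 0.5 * (u[seq == 0].mean() + u[seq == 1].mean())
        calls = (u > mid).astype(int) if u[seq == 1].mean() > mid else (u < mid)
        agreement = max(np.mean(calls == seq), np.mean(calls == 1 - seq))
        assert agreement >= 0.95

    def test_wrong_anchor_count_raises(self, static_trajectory):
        with pytest.raises(GeometryError):
            projection_timeseries(static_trajectory, [0], [1, 2])
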