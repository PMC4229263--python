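"""Triangulation, labeling/tracking and gap filling."""

import numpy as np
import pytest
from scipy.optimize import least_squares, linear_sum_assignment

from facemocap import (
    FrameCloud,
    NoiseSpec,
    fill_gaps,
    label_and_track,
    linear_rod,
    load_face_template,
    project,
    reconstruct_dataset,
    simulate_rod_session,
    triangulate,
    triangulate_table,
)
from facemocap.reconstruct import LabelingError
from facemocap.trajectories import CaptureClock, Trajectory3D


def _obs_for_point(rig, X, cams=None):
    cams = cams if cams is not None else range(len(rig.cameras))
    return {
        rig.cameras[i].camera_id: project(rig.cameras[i], np.asarray(X, float))
        for i in cams
    }


class TestTriangulate:
    def test_two_view_exact(self, rig, noiseless_calibration):
        X = np.array([10.0, 20.0, 40.0])
        obs = _obs_for_point(rig, X, cams=[0, 5])   # horizontal + vertical arm
        Xh, res = triangulate(obs, noiseless_calibration.projections)
        np.testing.assert_allclose(Xh, X, atol=1e-9)
        assert res < 1e-9

    def test_six_view_matches_nonlinear_oracle(self, rig, noiseless_calibration):
        """Linear DLT point equals an independent reprojection-minimizing
        refinement on noiseless data."""
        X = np.array([-25.0, 35.0, 15.0])
        obs = _obs_for_point(rig, X)
        Ps = noiseless_calibration.projections
        X_lin, _ = triangulate(obs, Ps)

        def resid(p):
            out = []
            for c, uv in obs.items():
                xh = Ps[c] @ np.append(p, 1.0)
                out.append(xh[:2] / xh[2] - uv)
            return np.concatenate(out)

        X0 = X_lin + np.array([0.5, -0.5, 0.5])
        sol = least_squares(resid, X0, method="lm")
        np.testing.assert_allclose(X_lin, sol.x, atol=1e-9)

    def test_single_camera_rejected(self, rig, noiseless_calibration):
        obs = _obs_for_point(rig, [0, 0, 0], cams=[1])
        with pytest.raises(ValueError):
            triangulate(obs, noiseless_calibration.projections)

    def test_noiseless_linear_rod_distance(self, rig, noiseless_calibration):
        ds = simulate_rod_session(rig, linear_rod(), "static", 1.0, NoiseSpec(0.0), seed=4)
        trajs = reconstruct_dataset(ds, noiseless_calibration)
        d = np.linalg.norm(trajs["rodA"].positions - trajs["rodB"].positions, axis=1)
        np.testing.assert_allclose(d, 176.84, atol=1e-6)

    def test_rigid_pair_distance_spread_shrinks_with_noise(self, rig, noiseless_calibration):
        sds = []
        for sigma in (1.0, 0.25, 0.0):
            ds = simulate_rod_session(rig, linear_rod(), "static", 1.0,
                                      NoiseSpec(sigma), seed=11)
            trajs = reconstruct_dataset(ds, noiseless_calibration)
            d = np.linalg.norm(trajs["rodA"].positions - trajs["rodB"].positions, axis=1)
            sds.append(d.std())
        assert sds[0] > sds[1] > sds[2]
        assert sds[2] < 1e-9

    def test_table_agrees_with_per_point_solver(self, rig, wand, noisy_calibration):
        from facemocap import simulate_wand_sweep

        ds = simulate_wand_sweep(rig, wand, 10, NoiseSpec(0.5), seed=12)
        table = triangulate_table(ds.observations, noisy_calibration.projections)
        for r in table.itertuples():
            g = ds.observations[
                (ds.observations["frame"] == r.frame)
                & (ds.observations["marker_id"] == r.marker_id)
            ]
            obs = {t.camera_id: np.array([t.u_px, t.v_px]) for t in g.itertuples()}
            X, res = triangulate(obs, noisy_calibration.projections)
            np.testing.assert_allclose([r.x_mm, r.y_mm, r.z_mm], X, atol=1e-9)
            assert r.residual_px == pytest.approx(res, abs=1e-9)


def _clouds_from_positions(positions, seed=None):
    """positions: (n_frames, n_markers, 3) -> FrameClouds, optionally shuffled."""
    rng = np.random.default_rng(seed) if seed is not None else None
    clouds = []
    for f, pts in enumerate(positions):
        order = np.arange(len(pts))
        if rng is not None:
            rng.shuffle(order)
        clouds.append(FrameCloud(f, pts[order], np.full(len(pts), 6)))
    return clouds


class TestLabelAndTrack:
    def test_static_rod_gives_complete_trajectories(self):
        p = np.tile(np.array([[0.0, 0, 0], [176.84, 0, 0]]), (500, 1, 1))
        trajs = label_and_track(_clouds_from_positions(p),
                                {"rodA": p[0, 0], "rodB": p[0, 1]})
        assert set(trajs) == {"rodA", "rodB"}
        for t in trajs.values():
            assert not t.gap_mask.any()

    def test_dropped_frame_becomes_gap_then_reacquires(self):
        pos = np.cumsum(np.full((20, 1, 3), 0.5), axis=0)   # steady 50 mm/s drift
        clouds = _clouds_from_positions(pos)
        clouds[7] = FrameCloud(7, np.empty((0, 3)), np.empty(0, dtype=int))
        trajs = label_and_track(clouds, {"m": pos[0, 0]})
        gap = trajs["m"].gap_mask
        assert gap[7] and not gap[6] and not gap[8]
        np.testing.assert_allclose(trajs["m"].positions[8], pos[8, 0])

    def test_matches_optimal_assignment_on_face_template(self):
        """Frame-wise labels equal the globally optimal minimum-total-distance
        matching (Hungarian oracle) on the 24-marker template."""
        tpl = load_face_template()
        codes = list(tpl.positions)
        rest = np.stack([tpl.positions[c] for c in codes])
        rng = np.random.default_rng(21)
        n_frames = 40
        pos = rest[None] + np.cumsum(rng.normal(0, 0.3, (n_frames, len(codes), 3)), axis=0)
        clouds = _clouds_from_positions(pos, seed=22)
        trajs = label_and_track(clouds, dict(zip(codes, rest)))
        for f in range(n_frames):
            cloud = clouds[f]
            cost = np.linalg.norm(
                np.stack([trajs[c].positions[max(f - 1, 0)] for c in codes])[:, None]
                - cloud.points[None], axis=2,
            ) if f else np.linalg.norm(rest[:, None] - cloud.points[None], axis=2)
            ri, ci = linear_sum_assignment(cost)
            for i, c in enumerate(codes):
                np.testing.assert_allclose(
                    trajs[c].positions[f], cloud.points[ci[ri == i][0]], atol=1e-12
                )

    def test_permutation_safety(self):
        tpl = load_face_template()
        codes = list(tpl.positions)
        rest = np.stack([tpl.positions[c] for c in codes])
        rng = np.random.default_rng(31)
        pos = rest[None] + rng.normal(0, 0.2, (30, len(codes), 3)).cumsum(axis=0)
        t1 = label_and_track(_clouds_from_positions(pos), dict(zip(codes, rest)))
        t2 = label_and_track(_clouds_from_positions(pos, seed=5), dict(zip(codes, rest)))
        for c in codes:
            np.testing.assert_allclose(t1[c].positions, t2[c].positions, atol=1e-12)

    def test_ambiguous_first_frame_raises(self):
        template = {"a": np.zeros(3), "b": np.array([0.1, 0, 0])}
        cloud = FrameCloud(0, np.array([[0.05, 0, 0], [50.0, 0, 0]]), np.array([6, 6]))
        with pytest.raises(LabelingError):
            label_and_track([cloud], template)


class TestFillGaps:
    def _traj(self, pos, gaps=()):
        p = np.array(pos, dtype=float)   # copy: gaps must not alias the input
        for g in gaps:
            p[g] = np.nan
        return Trajectory3D("m", p, CaptureClock())

    def test_no_gaps_is_identity(self):
        t = self._traj(np.random.default_rng(0).normal(size=(20, 3)))
        out = fill_gaps(t)
        np.testing.assert_array_equal(out.positions, t.positions)

    def test_linear_motion_gap_filled_on_the_line(self):
        pos = np.linspace(0, 19, 20)[:, None] * np.array([1.0, 2.0, -0.5])
        t = self._traj(pos, gaps=[8, 9, 10])
        out = fill_gaps(t, max_gap_frames=10)
        np.testing.assert_allclose(out.positions, pos, atol=1e-9)
        assert not out.gap_mask.any()

    def test_long_gap_left_flagged(self):
        pos = np.linspace(0, 29, 30)[:, None] * np.ones(3)
        t = self._traj(pos, gaps=range(5, 20))
        out = fill_gaps(t, max_gap_frames=10)
        assert out.gap_mask[5:20].all()

    def test_edge_gap_never_extrapolated(self):
        pos = np.linspace(0, 9, 10)[:, None] * np.ones(3)
        t = self._traj(pos, gaps=[0, 1, 9])
        out = fill_gaps(t, max_gap_frames=5)
        assert out.gap_mask[0] and out.gap_mask[1] and out.gap_mask[9]


class TestParameterRecovery:
    def test_face_session_rms_below_half_mm(self, rig, noisy_calibration):
        """Seeded default-noise expression session: reconstructed landmark
        positions match simulator ground truth within 0.5 mm RMS."""
        from facemocap import load_expressions, simulate_expression_session

        ds = simulate_expression_session(
            load_face_template(), rig, load_expressions(),
            noise=NoiseSpec(0.5), seed=41,
        )
        trajs = reconstruct_dataset(ds, noisy_calibration)
        sq = []
        for mk in ds.marker_ids:
            truth = ds.truth_trajectory(mk)
            ok = ~trajs[mk].gap_mask
            sq.append(np.sum((trajs[mk].positions[ok] - truth.positions[ok]) ** 2, axis=1))
        rms = np.sqrt(np.mean(np.concatenate(sq)))
        assert rms < 0.5
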