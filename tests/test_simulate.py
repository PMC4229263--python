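"""Camera projection and the synthetic capture generator."""

import numpy as np
import pandas as pd
import pytest

from facemocap import (
    HeadMotionSpec,
    NoiseSpec,
    default_rig,
    l_rod,
    linear_rod,
    load_expressions,
    load_face_template,
    project,
    simulate_expression_session,
    simulate_rod_session,
    simulate_wand_sweep,
    t_rod,
)
from facemocap.camera import ProjectionError
from facemocap.simulate import ExpressionEvent


@pytest.fixture(scope="module")
def cam(rig):
    return rig.cameras[2]


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self, cam):
        p = cam.center + 500.0 * cam.rotation[2]   # 500 mm along the optical axis
        uv = project(cam, p)
        np.testing.assert_allclose(uv, cam.principal_px, atol=1e-9)

    def test_doubling_depth_halves_offset(self, cam):
        off = 30.0 * cam.rotation[0] + 10.0 * cam.rotation[1]
        near = cam.center + 400.0 * cam.rotation[2] + off
        far = cam.center + 800.0 * cam.rotation[2] + 2 * off  # same ray direction scaled
        d_near = project(cam, near) - cam.principal_px
        d_far = project(cam, far) - cam.principal_px
        np.testing.assert_allclose(d_far, d_near, atol=1e-9)

    def test_matches_homogeneous_matrix_oracle(self, cam):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-100, 100, size=(50, 3))
        uv = project(cam, pts)
        P = cam.projection_matrix
        xh = np.hstack([pts, np.ones((50, 1))]) @ P.T
        oracle = xh[:, :2] / xh[:, [2]]
        np.testing.assert_allclose(uv, oracle, atol=1e-9)

    def test_behind_camera_raises(self, cam):
        behind = cam.center - 100.0 * cam.rotation[2]
        with pytest.raises(ProjectionError):
            project(cam, behind)


class TestRigLayout:
    def test_six_cameras_at_working_distance(self, rig):
        assert len(rig) == 6
        # all camera centres sit in the plane z = working distance
        for c in rig.cameras:
            assert c.center[2] == pytest.approx(rig.working_distance_mm, abs=1e-9)

    def test_l_shape_has_horizontal_and_vertical_arms(self, rig):
        centers = np.stack([c.center for c in rig.cameras])
        assert (centers[:3, 1] == 0).all() and (centers[:3, 0] < 0).all()
        assert (centers[3:, 0] == 0).all() and (centers[3:, 1] > 0).all()


class TestWandSweep:
    def test_frame_count_and_collinearity(self, rig, wand):
        ds = simulate_wand_sweep(rig, wand, 100, NoiseSpec(0.0), seed=5)
        assert ds.n_frames == 100
        # true wand markers stay collinear with the manufactured spacings
        t = ds.truth.pivot_table(index="frame", columns="marker_id",
                                 values=["x_mm", "y_mm", "z_mm"])
        for f in range(0, 100, 17):
            p = np.array([[t[("x_mm", m)][f], t[("y_mm", m)][f], t[("z_mm", m)][f]]
                          for m in wand.marker_ids])
            d01 = np.linalg.norm(p[1] - p[0])
            d12 = np.linalg.norm(p[2] - p[1])
            d02 = np.linalg.norm(p[2] - p[0])
            assert d01 == pytest.approx(100.0, abs=1e-9)
            assert d12 == pytest.approx(150.0, abs=1e-9)
            assert d02 == pytest.approx(d01 + d12, abs=1e-9)  # collinear

    def test_noiseless_observations_are_exact_reprojections(self, rig, wand):
        ds = simulate_wand_sweep(rig, wand, 20, NoiseSpec(0.0), seed=6)
        truth = ds.truth.set_index(["frame", "marker_id"])
        cams = {c.camera_id: c for c in rig.cameras}
        for r in ds.observations.head(200).itertuples():
            X = truth.loc[(r.frame, r.marker_id)][["x_mm", "y_mm", "z_mm"]].to_numpy()
            uv = project(cams[r.camera_id], X.astype(float))
            np.testing.assert_allclose([r.u_px, r.v_px], uv, atol=1e-9)

    def test_seed_determinism(self, rig, wand):
        a = simulate_wand_sweep(rig, wand, 50, NoiseSpec(0.5), seed=7)
        b = simulate_wand_sweep(rig, wand, 50, NoiseSpec(0.5), seed=7)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self, rig, wand):
        a = simulate_wand_sweep(rig, wand, 50, NoiseSpec(0.5), seed=7)
        c = simulate_wand_sweep(rig, wand, 50, NoiseSpec(0.5), seed=8)
        assert not a.truth.equals(c.truth)


class TestRodSessions:
    def test_static_session_length_and_rigidity(self, rig):
        ds = simulate_rod_session(rig, linear_rod(), "static", 5.0, NoiseSpec(0.0), seed=1)
        assert ds.n_frames == 500   # 5 s at 100 frames/s
        t = ds.truth.pivot_table(index="frame", columns="marker_id",
                                 values=["x_mm", "y_mm", "z_mm"])
        pa = t.xs("rodA", axis=1, level=1).to_numpy()
        pb = t.xs("rodB", axis=1, level=1).to_numpy()
        d = np.linalg.norm(pa - pb, axis=1)
        np.testing.assert_allclose(d, 176.84, atol=1e-9)

    def test_dynamic_session_length(self, rig):
        ds = simulate_rod_session(rig, l_rod(), "dynamic", 60.0, NoiseSpec(0.0), seed=2)
        assert ds.n_frames == 6000  # about 1 minute

    def test_bad_mode_rejected(self, rig):
        with pytest.raises(ValueError):
            simulate_rod_session(rig, linear_rod(), "wobbly", 1.0)


class TestExpressionSession:
    def test_null_schedule_and_no_head_motion_is_static(self, rig):
        ds = simulate_expression_session(
            load_face_template(), rig, load_expressions(), schedule=[],
            head_motion=HeadMotionSpec(0.0, 0.0), noise=NoiseSpec(0.0), seed=3,
        )
        for mk in ("B", "h", "HM1"):
            tr = ds.truth_trajectory(mk)
            assert np.ptp(tr.positions, axis=0).max() == pytest.approx(0.0, abs=1e-12)

    def test_helmet_markers_follow_head_only(self, rig):
        tpl = load_face_template()
        reg = load_expressions()
        ds = simulate_expression_session(
            tpl, rig, reg, head_motion=HeadMotionSpec(0.0, 0.0),
            noise=NoiseSpec(0.0), seed=4,
        )
        for hm in ("HM1", "HM2", "HM3"):
            tr = ds.truth_trajectory(hm)
            assert np.ptp(tr.positions, axis=0).max() == pytest.approx(0.0, abs=1e-12)
        # while active face landmarks do move
        assert np.ptp(ds.truth_trajectory("B").positions, axis=0).max() > 5

    def test_peak_deviation_equals_configured_amplitude(self, rig):
        """The raised-cosine profile reaches exactly the registered peak."""
        tpl = load_face_template()
        reg = load_expressions()
        ev = ExpressionEvent(1, start_s=0.5)   # maximal brow lift
        ds = simulate_expression_session(
            tpl, rig, reg, schedule=[ev], head_motion=HeadMotionSpec(0.0, 0.0),
            noise=NoiseSpec(0.0), seed=5,
        )
        tr = ds.truth_trajectory("B")
        dev = np.linalg.norm(tr.positions - tpl.positions["B"], axis=1)
        amp = np.linalg.norm(reg[1].displacements["B"])
        assert dev.max() == pytest.approx(amp, abs=1e-9)
        assert amp == pytest.approx(8.0)

    def test_unknown_expression_rejected(self, rig):
        with pytest.raises(KeyError):
            simulate_expression_session(
                load_face_template(), rig, load_expressions(),
                schedule=[ExpressionEvent(99, 1.0)], seed=6,
            )

    def test_visibility_report_full_coverage_at_default_rig(self, rig):
        ds = simulate_expression_session(
            load_face_template(), rig, load_expressions(), noise=NoiseSpec(0.5), seed=7,
        )
        counts = ds.camera_counts()
        assert not counts["qc_under_three"].any()
        assert ds.visibility_ok()


class TestRaisedCosineProfile:
    def test_profile_shape(self):
        ev = ExpressionEvent(1, start_s=1.0, onset_s=0.5, hold_s=1.0, offset_s=0.5)
        t = np.array([0.0, 1.0, 1.25, 1.5, 2.0, 2.5, 2.75, 3.0, 4.0])
        act = ev.activation(t)
        np.testing.assert_allclose(act, [0, 0, 0.5, 1, 1, 1, 0.5, 0, 0], atol=1e-12)
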