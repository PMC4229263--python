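"""Helmet and anatomical reference frames."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from facemocap import (
    HeadMotionSpec,
    NoiseSpec,
    anatomical_frame,
    helmet_frame,
    load_expressions,
    load_face_template,
    reconstruct_dataset,
    simulate_expression_session,
    to_anatomical,
    to_helmet,
)
from facemocap.geometry import GeometryError
from facemocap.registries import HELMET_MARKERS
from facemocap.trajectories import CaptureClock, Trajectory3D

coord = st.floats(-200, 200, allow_nan=False, allow_infinity=False)
vec3 = arrays(np.float64, (3,), elements=coord)


def _template_frames():
    tpl = load_face_template()
    rest = {c: p for c, p in tpl.positions.items()}
    return tpl, rest


class TestHelmetFrame:
    def test_origin_is_centroid(self):
        fr = helmet_frame((1, 0, 0), (-1, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(fr.origin, [0, 1 / 3, 0], atol=1e-12)

    def test_collinear_markers_rejected(self):
        with pytest.raises(GeometryError):
            helmet_frame((0, 0, 0), (1, 0, 0), (2, 0, 0))

    @given(vec3, vec3, vec3)
    @settings(max_examples=100, derandomize=True)
    def test_axes_orthonormal_and_match_gram_schmidt(self, m1, m2, m3):
        if 0.5 * np.linalg.norm(np.cross(m2 - m1, m3 - m1)) < 1.0:
            return
        fr = helmet_frame(m1, m2, m3)
        A = fr.axes
        np.testing.assert_allclose(A @ A.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(A) == pytest.approx(1.0, abs=1e-12)
        # independent Gram-Schmidt oracle for the in-plane axis
        o = (m1 + m2 + m3) / 3
        n = np.cross(m2 - m1, m3 - m1)
        n = n / np.linalg.norm(n)
        v = (m1 - o) - np.dot(m1 - o, n) * n
        v = v / np.linalg.norm(v)
        np.testing.assert_allclose(fr.axes[0], v, atol=1e-12)

    def test_rigid_motion_covariance(self):
        """Re-expressed landmark coordinates are pose-invariant."""
        tpl, rest = _template_frames()
        m = [rest[h] for h in HELMET_MARKERS]
        p = rest["H"]
        local_before = helmet_frame(*m, face_point=p).to_local(p)[0]
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        shift = np.array([30.0, -12.0, 44.0])
        moved = [R @ x + shift for x in m]
        local_after = helmet_frame(*moved, face_point=R @ p + shift).to_local(R @ p + shift)[0]
        np.testing.assert_allclose(local_after, local_before, atol=1e-9)


class TestToHelmet:
    def _session_trajs(self, rig, calibration, seed, head_motion, sigma):
        ds = simulate_expression_session(
            load_face_template(), rig, load_expressions(), schedule=[],
            head_motion=head_motion, noise=NoiseSpec(sigma), seed=seed,
        )
        return reconstruct_dataset(ds, calibration)

    def test_head_motion_only_is_constant_in_helmet_frame(self, rig, noiseless_calibration):
        trajs = self._session_trajs(rig, noiseless_calibration, 13, HeadMotionSpec(), 0.0)
        local = to_helmet(trajs)
        for c, t in local.items():
            if c in HELMET_MARKERS:
                continue
            spread = np.ptp(t.positions[~t.gap_mask], axis=0).max()
            assert spread < 1e-6

    def test_missing_helmet_marker_rejected(self):
        t = Trajectory3D("B", np.zeros((10, 3)), CaptureClock())
        with pytest.raises(KeyError):
            to_helmet({"B": t})

    def test_reexpression_is_isometric(self, rig, noiseless_calibration):
        trajs = self._session_trajs(rig, noiseless_calibration, 14, HeadMotionSpec(), 0.0)
        local = to_helmet(trajs)
        f = 37
        for a, b in (("A", "h"), ("G", "III"), ("E", "F")):
            d_world = np.linalg.norm(trajs[a].positions[f] - trajs[b].positions[f])
            d_local = np.linalg.norm(local[a].positions[f] - local[b].positions[f])
            assert d_local == pytest.approx(d_world, abs=1e-9)


class TestAnatomicalFrame:
    def test_axes_orthonormal_right_handed(self):
        _, rest = _template_frames()
        fr = anatomical_frame(rest)
        np.testing.assert_allclose(fr.axes @ fr.axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(fr.axes) == pytest.approx(1.0, abs=1e-12)

    def test_sign_conventions_on_template(self):
        """Left landmarks get positive X; the right mouth corner is negative;
        brow landmarks sit above (positive Y of) the tragus plane."""
        _, rest = _template_frames()
        fr = anatomical_frame(rest)
        local = {c: fr.to_local(p)[0] for c, p in rest.items() if c not in HELMET_MARKERS}
        assert local["H"][0] > 0 and local["h"][0] < 0
        assert local["B"][1] > 0 and local["J"][1] > 0
        assert local["I"][2] > local["A"][2]   # nasal point forward of the tragus

    def test_horizontal_plane_contains_tragi_and_nasal_point(self):
        _, rest = _template_frames()
        fr = anatomical_frame(rest)
        for c in ("A", "a", "I"):
            assert fr.to_local(rest[c])[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_origin_on_coronal_plane_through_left_tragus(self):
        _, rest = _template_frames()
        fr = anatomical_frame(rest)
        # left tragus has zero Z (coronal) and zero Y (horizontal) coordinate
        local_A = fr.to_local(rest["A"])[0]
        assert local_A[1] == pytest.approx(0.0, abs=1e-9)
        assert local_A[2] == pytest.approx(0.0, abs=1e-9)
        # and the sagittal plane passes through the nasal point
        assert fr.to_local(rest["I"])[0][0] == pytest.approx(0.0, abs=1e-9)

    def test_tragus_midpoint_on_sagittal_plane_for_symmetric_template(self):
        _, rest = _template_frames()
        fr = anatomical_frame(rest)
        mid = (rest["A"] + rest["a"]) / 2
        assert fr.to_local(mid)[0][0] == pytest.approx(0.0, abs=1e-9)

    def test_missing_landmark_rejected(self):
        _, rest = _template_frames()
        rest.pop("A")
        with pytest.raises(KeyError):
            anatomical_frame(rest)

    def test_nasal_landmark_configurable(self):
        _, rest = _template_frames()
        fr = anatomical_frame(rest, nasal_landmark="K")
        assert fr.to_local(rest["K"])[0][0] == pytest.approx(0.0, abs=1e-9)


class TestBrowLiftDirection:
    def test_brow_lift_moves_positive_y(self, rig, noiseless_calibration):
        """A simulated brow lift displaces landmark B upward (+Y) in the
        anatomical frame."""
        from facemocap.simulate import ExpressionEvent

        ds = simulate_expression_session(
            load_face_template(), rig, load_expressions(),
            schedule=[ExpressionEvent(1, 1.0)],
            head_motion=HeadMotionSpec(0.0, 0.0), noise=NoiseSpec(0.0), seed=15,
        )
        trajs = reconstruct_dataset(ds, noiseless_calibration)
        local = to_helmet(trajs)
        rest = {c: t.positions[0] for c, t in local.items() if c not in HELMET_MARKERS}
        fr = anatomical_frame(rest)
        anat = to_anatomical({c: t for c, t in local.items() if c not in HELMET_MARKERS}, fr)
        disp = anat["B"].positions - anat["B"].positions[0]
        peak = disp[np.argmax(np.linalg.norm(disp, axis=1))]
        assert peak[1] > 0.9 * np.linalg.norm(peak)
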