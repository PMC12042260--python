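"""Helix axes, inter-helix angles, distances, RMSD/RMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import nrtraj as nt
from nrtraj.errors import GeometryError

from conftest import random_rigid_transform, transform_trajectory


class TestHelixAxis:
    def test_ideal_helix_axis_matches_generating_axis(self, ideal_helix):
        top, frame = ideal_helix
        axis = nt.helix_axis(frame, top, nt.ResidueSpan("A", 1, 20))
        v = axis.vector / axis.length
        assert np.degrees(np.arccos(abs(v[2]))) < 2.0

    def test_axis_equivariant_under_rotation(self, ideal_helix):
        top, frame = ideal_helix
        span = nt.ResidueSpan("A", 1, 20)
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        rotated = nt.Frame(index=0, time=0.0, coordinates=frame.coordinates @ R.T)
        a = nt.helix_axis(frame, top, span)
        b = nt.helix_axis(rotated, top, span)
        assert np.allclose(R @ a.vector, b.vector, atol=1e-9)

    def test_short_span_rejected(self, ideal_helix):
        top, frame = ideal_helix
        with pytest.raises(GeometryError):
            nt.helix_axis(frame, top, nt.ResidueSpan("A", 1, 5))


class TestAxisAngle:
    @pytest.mark.parametrize("vec,expected", [
        ((0, 0, 1), 0.0), ((0, 0, -1), 180.0), ((1, 0, 0), 90.0)])
    def test_canonical_directions(self, vec, expected):
        z = nt.HelixAxis(np.zeros(3), np.array([0.0, 0.0, 5.0]))
        other = nt.HelixAxis(np.zeros(3), 5.0 * np.asarray(vec, dtype=float))
        assert nt.axis_angle(z, other) == pytest.approx(expected, abs=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a = nt.HelixAxis(rng.normal(size=3), rng.normal(size=3) + 3)
        b = nt.HelixAxis(rng.normal(size=3), rng.normal(size=3) - 3)
        assert nt.axis_angle(a, b) == nt.axis_angle(b, a)

    def test_rotation_matrix_oracle(self):
        """axis_angle equals the angle of the rotation aligning one axis to the other."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            va = rng.normal(size=3) * 5
            vb = rng.normal(size=3) * 5
            while min(np.linalg.norm(va), np.linalg.norm(vb)) < 0.5:
                va, vb = rng.normal(size=3) * 5, rng.normal(size=3) * 5
            a = nt.HelixAxis(np.zeros(3), va)
            b = nt.HelixAxis(np.zeros(3), vb)
            ua, ub = va / np.linalg.norm(va), vb / np.linalg.norm(vb)
            # brute-force oracle: rotation about ua x ub taking ua onto ub
            axis = np.cross(ua, ub)
            s, c = np.linalg.norm(axis), float(np.dot(ua, ub))
            oracle = np.degrees(np.arctan2(s, c))
            assert nt.axis_angle(a, b) == pytest.approx(oracle, abs=1e-6)

    def test_degenerate_axis_rejected(self):
        good = nt.HelixAxis(np.zeros(3), np.array([0.0, 0.0, 5.0]))
        bad = nt.HelixAxis(np.zeros(3), np.array([0.0, 0.0, 0.05]))
        with pytest.raises(GeometryError):
            nt.axis_angle(good, bad)


class TestVertexAngle:
    def test_right_triangle_3_4_5(self):
        assert nt.vertex_angle((3, 0, 0), (0, 0, 0), (0, 4, 0)) == pytest.approx(90.0)

    def test_equilateral(self):
        p = (1, 0, 0)
        q = (0.5, np.sqrt(3) / 2, 0)
        assert nt.vertex_angle(p, (0, 0, 0), q) == pytest.approx(60.0)

    def test_collinear_through_vertex(self):
        assert nt.vertex_angle((-2, 0, 0), (0, 0, 0), (5, 0, 0)) == pytest.approx(180.0)

    def test_zero_arm_rejected(self):
        with pytest.raises(GeometryError):
            nt.vertex_angle((0, 0, 0), (0, 0, 0), (1, 1, 1))

    def test_triangle_inequality_on_random_points(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p, v, q = rng.normal(size=(3, 3)) * 5
            a = np.linalg.norm(p - v)
            b = np.linalg.norm(q - v)
            c = np.linalg.norm(p - q)
            assert c <= a + b + 1e-9
            assert 0.0 <= nt.vertex_angle(p, v, q) <= 180.0


class TestAngleSeries:
    def test_agonist_parameter_recovery(self, agonist_bundle, anchors):
        series = nt.angle_series(agonist_bundle, anchors)
        n = agonist_bundle.n_frames
        assert abs(series.ang2.mean() - 55.0) < 3 * 4.0 / np.sqrt(n)
        assert abs(series.ang1.mean() - 70.0) < 3 * 3.0 / np.sqrt(n)

    def test_angles_bounded(self, antagonist_bundle, anchors):
        series = nt.angle_series(antagonist_bundle, anchors)
        assert np.all((series.ang1 >= 0) & (series.ang1 <= 180))
        assert np.all((series.ang2 >= 0) & (series.ang2 <= 180))


class TestComDistance:
    def test_translation_invariance(self, agonist_bundle, anchors):
        d0 = nt.com_distance_series(agonist_bundle, anchors.h12, anchors.h10)
        shifted = transform_trajectory(agonist_bundle, np.eye(3), np.array([3.0, -1.0, 7.0]))
        d1 = nt.com_distance_series(shifted, anchors.h12, anchors.h10)
        assert np.allclose(d0.values, d1.values, atol=1e-9)

    def test_span_against_itself_is_zero(self, agonist_bundle, anchors):
        d = nt.com_distance_series(agonist_bundle, anchors.h10, anchors.h10)
        assert np.allclose(d.values, 0.0)

    def test_distance_recovery(self, agonist_bundle, anchors):
        d = nt.com_distance_series(agonist_bundle, anchors.h12, anchors.h10)
        n = agonist_bundle.n_frames
        assert abs(d.values.mean() - 12.0) < 3 * 0.5 / np.sqrt(n)

    def test_empty_span_rejected(self, agonist_bundle):
        with pytest.raises(GeometryError):
            nt.com_distance_series(agonist_bundle, nt.ResidueSpan("A", 900, 910),
                                   nt.ResidueSpan("A", 1, 24))


class TestRmsd:
    def test_identical_frames_zero(self, ideal_helix):
        top, frame = ideal_helix
        sel = [int(a) for a in top.atom_id]
        assert nt.rmsd(frame, frame, sel, top) == pytest.approx(0.0, abs=1e-9)

    def test_translation_removed_by_superposition(self, ideal_helix):
        top, frame = ideal_helix
        sel = [int(a) for a in top.atom_id]
        moved = nt.Frame(index=1, time=0.0, coordinates=frame.coordinates + [1.0, 0, 0])
        assert nt.rmsd(frame, moved, sel, top, superpose_first=True) == pytest.approx(0.0, abs=1e-9)
        assert nt.rmsd(frame, moved, sel, top, superpose_first=False) == pytest.approx(1.0)

    def test_hand_computed_displacements(self):
        top = nt.Topology(atom_id=range(1, 6), name=["CA"] * 5, element=["C"] * 5,
                          residue_number=range(1, 6), residue_name=["ALA"] * 5,
                          chain=["A"] * 5)
        ref = nt.Frame(index=0, time=0.0, coordinates=np.zeros((5, 3)) + np.arange(5)[:, None] * 10)
        xyz = ref.coordinates.copy()
        xyz[0, 0] += 1.0
        xyz[1, 0] += 2.0
        moved = nt.Frame(index=1, time=0.0, coordinates=xyz)
        expected = np.sqrt((1 + 4) / 5)
        assert nt.rmsd(ref, moved, [1, 2, 3, 4, 5], top,
                       superpose_first=False) == pytest.approx(expected)

    def test_empty_selection_rejected(self, ideal_helix):
        top, frame = ideal_helix
        with pytest.raises(GeometryError):
            nt.rmsd(frame, frame, [], top)


class TestRmsf:
    def _static_traj(self, top, frame, n=5):
        frames = [nt.Frame(index=i, time=float(i), coordinates=frame.coordinates.copy())
                  for i in range(n)]
        return nt.Trajectory(topology=top, frames=frames)

    def test_static_trajectory_zero(self, ideal_helix):
        top, frame = ideal_helix
        traj = self._static_traj(top, frame)
        ca = nt.select_atoms(top, role="c_alpha")
        assert np.allclose(nt.rmsf(traj, ca).to_numpy(), 0.0)

    def test_two_point_oscillation_closed_form(self, ideal_helix):
        top, frame = ideal_helix
        frames = []
        for i in range(4):
            xyz = frame.coordinates.copy()
            xyz[1, 0] += 1.0 if i % 2 == 0 else -1.0  # CA of residue 1
            frames.append(nt.Frame(index=i, time=float(i), coordinates=xyz))
        traj = nt.Trajectory(topology=top, frames=frames)
        ca = nt.select_atoms(top, role="c_alpha")
        prof = nt.rmsf(traj, ca)
        assert prof.loc[1] == pytest.approx(1.0)
        assert prof.loc[5] == pytest.approx(0.0, abs=1e-12)

    def test_frame_order_invariance(self, agonist_bundle):
        ca = nt.select_atoms(agonist_bundle.topology, role="c_alpha")
        fwd = nt.rmsf(agonist_bundle, ca)
        rev_frames = [nt.Frame(index=i, time=float(i), coordinates=f.coordinates)
                      for i, f in enumerate(reversed(agonist_bundle.frames))]
        rev = nt.rmsf(nt.Trajectory(topology=agonist_bundle.topology, frames=rev_frames), ca)
        assert np.allclose(fwd.to_numpy(), rev.to_numpy(), atol=1e-9)

    def test_single_frame_rejected(self, ideal_helix):
        top, frame = ideal_helix
        traj = nt.Trajectory(topology=top, frames=[frame])
        with pytest.raises(GeometryError):
            nt.rmsf(traj, nt.select_atoms(top, role="c_alpha"))


class TestRigidMotionEquivariance:
    def test_descriptors_invariant_under_rigid_transforms(self, agonist_bundle, anchors):
        sub = nt.Trajectory(topology=agonist_bundle.topology,
                            frames=agonist_bundle.frames[:10])
        base_angles = nt.angle_series(sub, anchors)
        base_dist = nt.com_distance_series(sub, anchors.h12, anchors.h10)
        ca = nt.select_atoms(sub.topology, role="c_alpha")
        base_rmsf = nt.rmsf(nt.superpose_trajectory(sub, ca), ca).to_numpy()
        rng = np.random.default_rng(8)
        for _ in range(10):
            R, t = random_rigid_transform(rng)
            moved = transform_trajectory(sub, R, t)
            ang = nt.angle_series(moved, anchors)
            assert np.allclose(ang.ang1, base_angles.ang1, atol=1e-6)
            assert np.allclose(ang.ang2, base_angles.ang2, atol=1e-6)
            dist = nt.com_distance_series(moved, anchors.h12, anchors.h10)
            assert np.allclose(dist.values, base_dist.values, atol=1e-6)
            assert nt.rmsd(sub.frames[0], moved.frames[0], ca, sub.topology,
                           superpose_first=True) == pytest.approx(0.0, abs=1e-6)
            moved_rmsf = nt.rmsf(nt.superpose_trajectory(moved, ca), ca).to_numpy()
            assert np.allclose(moved_rmsf, base_rmsf, atol=1e-6)
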