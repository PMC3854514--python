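"""Observed rotational angles: axis fit, top-view frame, planted recovery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmexpo.fixtures import (
    HelixSpec,
    bundle_helices,
    helix_bundle,
    ideal_helix_calphas,
    periodic_rasa,
    PlantedProfile,
)
from tmexpo.geometry import (
    GeometryError,
    build_frame,
    inplane_angle,
    lipid_facing_direction,
    observed_rotations,
    principal_axis,
    topview_project,
)
from tmexpo.metrics import angular_error
from tmexpo.moment import predict_rotation
from tmexpo.structure_io import tm_calpha_coords


class TestPrincipalAxis:
    def test_straight_line_recovered(self):
        pts = np.column_stack((np.zeros(10), np.zeros(10), np.arange(10.0)))
        assert np.allclose(principal_axis(pts), [0, 0, 1], atol=1e-12)

    def test_reversing_order_negates_axis(self):
        pts = ideal_helix_calphas(HelixSpec(n_residues=20))
        assert np.allclose(principal_axis(pts), -principal_axis(pts[::-1]), atol=1e-9)

    @pytest.mark.parametrize("n", [14, 18, 26])
    def test_ideal_helix_axis_within_half_degree(self, n):
        axis = principal_axis(ideal_helix_calphas(HelixSpec(n_residues=n)))
        dev = np.degrees(np.arccos(np.clip(abs(axis[2]), 0, 1)))
        assert dev < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            principal_axis(np.zeros((2, 3)))

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            principal_axis(np.ones((5, 3)))


class TestTopView:
    def test_axis_point_projects_to_origin(self):
        frame = build_frame(np.array([0.0, 0.0, 1.0]))
        assert np.allclose(topview_project(np.array([0, 0, 7.5]), frame), [[0, 0]])

    def test_frame_is_right_handed_about_axis(self):
        frame = build_frame(np.array([0.3, -0.5, 0.81]))
        assert np.allclose(np.cross(frame.basis_u, frame.basis_v), frame.axis,
                           atol=1e-12)

    def test_successive_residues_advance_plus_hundred(self):
        """The handedness contract: an ideal right-handed helix steps +100°
        per residue in the frame's positive (clockwise-from-N) sense."""
        cas = ideal_helix_calphas(HelixSpec(n_residues=18))
        frame = build_frame(np.array([0.0, 0.0, 1.0]))
        proj = topview_project(cas, frame)
        angles = [inplane_angle(p) for p in proj]
        steps = [(b - a) % 360.0 for a, b in zip(angles, angles[1:])]
        assert np.allclose(steps, 100.0, atol=1e-9)

    def test_projection_is_isometric_in_plane(self, rng):
        frame = build_frame(np.array([0.2, 0.4, 0.89]))
        p = rng.normal(size=3)
        q = p + 2.5 * frame.basis_u - 1.2 * frame.basis_v  # in-plane displacement
        pu, qu = topview_project(np.vstack((p, q)), frame)
        assert np.linalg.norm(qu - pu) == pytest.approx(np.linalg.norm(q - p),
                                                        abs=1e-9)


class TestLipidFacing:
    def test_points_outward(self):
        assert np.allclose(lipid_facing_direction(np.array([1.0, 0.0]),
                                                  np.array([0.0, 0.0])), [1, 0])
        assert np.allclose(lipid_facing_direction(np.array([0.0, -2.0]),
                                                  np.array([0.0, 0.0])), [0, -1])

    def test_coincident_centers_rejected(self):
        with pytest.raises(GeometryError):
            lipid_facing_direction(np.zeros(2), np.zeros(2))

    def test_symmetric_bundle_vectors_point_radially(self):
        n = 4
        specs = [
            HelixSpec(n_residues=18,
                      position=(10 * np.cos(2 * np.pi * j / n),
                                10 * np.sin(2 * np.pi * j / n)))
            for j in range(n)
        ]
        _, _, truths = helix_bundle(specs)
        # identical helices (first residue at world 0°) around a ring: the
        # lipid vector of helix j points radially outward at azimuth 90°·j,
        # so the planted angle equals that azimuth
        expected = [(90.0 * j) % 360.0 for j in range(n)]
        assert all(abs(t - e) % 360.0 < 1e-9 or abs(abs(t - e) - 360.0) < 1e-9
                   for t, e in zip(truths, expected))


class TestObservedRotation:
    def test_planted_rotations_recovered_within_one_degree(self, bundle4):
        structure, _, helices, truths = bundle4
        cas = tm_calpha_coords(structure, helices)
        angles = observed_rotations(helices, cas)
        for truth, got in zip(truths, angles):
            assert angular_error(truth, got.angle) < 1.0

    def test_offset_shift_moves_angle_by_delta(self):
        base = [HelixSpec(n_residues=36, position=(8.0, 0.0), offset=0.0),
                HelixSpec(n_residues=36, position=(-8.0, 0.0), offset=0.0)]
        _, _, t0 = helix_bundle(base)
        delta = 37.0
        shifted = [HelixSpec(n_residues=36, position=(8.0, 0.0), offset=delta),
                   base[1]]
        _, _, t1 = helix_bundle(shifted)
        # rotating the helix by +delta in the positive sense moves the
        # first-residue vector with it, so the measured angle drops by delta
        assert angular_error((t0[0] - delta) % 360.0, t1[0]) < 1e-9

    def test_global_rigid_motion_leaves_angles(self, bundle4):
        structure, _, helices, _ = bundle4
        cas = tm_calpha_coords(structure, helices)
        before = observed_rotations(helices, cas)
        rot = Rotation.from_euler("xyz", [33, -61, 104], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 8.0])
        moved = {k: rot @ v + shift for k, v in cas.items()}
        after = observed_rotations(helices, moved)
        for a, b in zip(before, after):
            assert angular_error(a.angle, b.angle) < 1e-6

    def test_angles_always_in_range(self, bundle4):
        structure, _, helices, _ = bundle4
        cas = tm_calpha_coords(structure, helices)
        for res in observed_rotations(helices, cas):
            assert 0.0 <= res.angle < 360.0


class TestHandednessCrossModule:
    """One sign convention for geometry and moment.

    A helix whose residue i faces the lipid must have observed angle
    (i-1)*100 mod 360; a delta exposure profile at residue i must give the
    same moment direction.
    """

    @pytest.mark.parametrize("i", [1, 4, 9, 14])
    def test_observed_equals_moment_for_planted_exposure(self, i):
        target = ((i - 1) * 100.0) % 360.0
        # n=36 (full wheel): helix centers coincide with positions, so the
        # lipid direction of helix 1 at (8, 0) is exactly +x; planting
        # residue i's wheel position at +x means offset = -target
        specs = [
            HelixSpec(n_residues=36, position=(8.0, 0.0), offset=-target % 360.0),
            HelixSpec(n_residues=36, position=(-8.0, 0.0), offset=0.0),
        ]
        structure, annotations, truths = helix_bundle(specs)
        assert angular_error(truths[0], target) < 1e-9  # construction check
        helices = bundle_helices(structure, annotations)
        cas = tm_calpha_coords(structure, helices)
        observed = observed_rotations(helices, cas)[0].angle
        assert angular_error(observed, target) < 1.0

        scores = np.zeros(36)
        scores[i - 1] = 1.0
        assert angular_error(predict_rotation(scores).theta, target) < 1e-9

    def test_periodic_profile_phase_recovered(self):
        prof = periodic_rasa(PlantedProfile(n=18, phase=222.5))
        assert predict_rotation(prof).theta == pytest.approx(222.5, abs=1e-6)
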