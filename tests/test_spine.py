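"""Spine assembly: composition, lordosis, stacking, rigid-motion invariance."""

import numpy as np
import pytest
import trimesh

from pedispine import solid_kernel as sk
from pedispine.disc import disc_height
from pedispine.osteometry import get_dimensions
from pedispine.spine import assemble_spine, spine_report
from pedispine.validation import check_facet_gap


class TestComposition:
    def test_eleven_elements_in_craniocaudal_order(self, newborn_spine):
        names = [e.name for e in newborn_spine.elements]
        assert names == [
            "L1", "L1/2", "L2", "L2/3", "L3", "L3/4", "L4", "L4/5", "L5", "L5/S1", "S1",
        ]
        assert len(newborn_spine.vertebrae()) == 5
        assert len(newborn_spine.discs()) == 5
        assert sum(e.kind == "endplate" for e in newborn_spine.elements) == 1

    def test_newborn_spine_is_straight(self, newborn_spine):
        assert newborn_spine.lordosis_angle == 0.0
        assert sum(newborn_spine.relative_rotations) == 0.0

    def test_toddler_spine_has_visible_lordosis(self):
        m = assemble_spine(3)
        assert m.lordosis_angle > 0
        assert sum(m.relative_rotations) == pytest.approx(m.lordosis_angle, abs=0.1)

    def test_lordosis_override_passthrough(self):
        m = assemble_spine(1, lordosis=20.0)
        assert sum(m.relative_rotations) == pytest.approx(20.0, abs=0.1)


class TestStacking:
    def test_straight_stack_height_matches_table_arithmetic(self, newborn_spine):
        rep = spine_report(newborn_spine, full=False)
        expected = sum(
            get_dimensions(1, f"L{k}").PVBH for k in range(1, 6)
        ) + sum(disc_height(1, p) for p in ["L1/2", "L2/3", "L3/4", "L4/5", "L5/S1"])
        assert abs(rep["stack_height"] - expected) < 0.5

    def test_volume_conservation_in_report(self, newborn_spine):
        rep = spine_report(newborn_spine, full=False)
        total = sum(e["volume"] for e in rep["elements"])
        assert rep["total_volume"] == pytest.approx(total, rel=1e-9)

    def test_contacts_and_no_interpenetration(self, newborn_spine):
        rep = spine_report(newborn_spine)
        for gap in rep["contact_gaps"]:
            assert 0.0 <= gap["gap"] < 0.1, gap
        for pen in rep["interpenetration"]:
            assert pen["fraction"] < 1e-3, pen

    def test_facet_gaps_stay_within_joint_bound(self, preadolescent_spine):
        ordered = preadolescent_spine.elements[::-1]
        verts = [e for e in ordered if e.kind == "vertebra"]
        for lower, upper in zip(verts[:-1], verts[1:]):
            pose = np.linalg.inv(lower.pose) @ upper.pose
            gap = check_facet_gap(upper.payload, lower.payload, pose)
            assert not gap.overlapping
            assert gap.distance <= 0.5, (lower.name, upper.name)


class TestRigidMotionInvariance:
    def test_volumes_and_distances_survive_rigid_motion(self, newborn_spine):
        move = trimesh.transformations.rotation_matrix(0.8, (0.2, 1, 0.5), point=(5, -3, 10))
        move[:3, 3] += (4.0, -7.0, 2.0)
        moved = newborn_spine.transformed(move)
        v0 = [c.solid.volume for c in newborn_spine.world_components()]
        v1 = [c.solid.volume for c in moved.world_components()]
        assert np.allclose(v0, v1, rtol=1e-6)
        a0 = newborn_spine.elements[0].contact_solid().transformed(newborn_spine.elements[0].pose)
        b0 = newborn_spine.elements[1].contact_solid().transformed(newborn_spine.elements[1].pose)
        a1 = moved.elements[0].contact_solid().transformed(moved.elements[0].pose)
        b1 = moved.elements[1].contact_solid().transformed(moved.elements[1].pose)
        d0 = sk.min_distance(a0, b0).distance
        d1 = sk.min_distance(a1, b1).distance
        assert d1 == pytest.approx(d0, abs=1e-6)
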