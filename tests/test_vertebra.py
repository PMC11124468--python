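"""Vertebra construction: dimensions, architecture, styling, integrity."""

import math

import numpy as np
import pytest

from pedispine import solid_kernel as sk
from pedispine.config import default_config
from pedispine.osteometry import (
    VertebralDimensions,
    derive_arch_parameters,
    get_age_group,
    get_dimensions,
)
from pedispine.validation import measure_body_dimensions, measure_foramen
from pedispine.vertebra import (
    BodyGeometry,
    build_body,
    build_posterior_elements,
    build_vertebra,
    facet_spec,
    _arch_for,
)


def _spinous_angle(solids):
    sp = [s for s in solids if s.name == "spinous process"]
    assert sp, "spinous process expected for this group"
    v = sp[0].vertices - sp[0].vertices.mean(axis=0)
    _, vec = np.linalg.eigh(np.cov(v.T))
    axis = vec[:, -1] / np.linalg.norm(vec[:, -1])
    return math.degrees(math.asin(abs(axis[2])))


class TestBody:
    @pytest.mark.parametrize("group, level", [(1, "L3"), (3, "L1"), (4, "L5")])
    def test_dimension_round_trip(self, group, level):
        dims = get_dimensions(group, level)
        body = build_body(dims, group)
        measured = measure_body_dimensions(body, dims.PVBH)
        for name, value in measured.items():
            expected = getattr(dims, name)
            assert abs(value - expected) <= max(0.2, 0.02 * expected), name

    def test_equal_heights_give_parallel_endplates(self):
        dims = get_dimensions(1, "L3").model_copy(update={"AVBH": 7.2, "PVBH": 7.2})
        body = build_body(dims, 1)
        m = body.mesh
        fn, fa, fc = m.face_normals, m.area_faces, m.triangles_center
        cfg = default_config()
        grp = get_age_group(1)
        geom = BodyGeometry(dims, grp, _arch_for(dims, grp, cfg), cfg)
        top = fn[:, 2] > math.cos(math.radians(35))
        # plane outside the central fossa
        r = np.hypot(fc[top, 0] - geom.centroid[0], fc[top, 1] - geom.centroid[1])
        sel = r > geom.fossa_radius + 0.2
        n = (fn[top][sel] * fa[top][sel, None]).sum(axis=0)
        n /= np.linalg.norm(n)
        assert math.degrees(math.acos(min(1.0, n[2]))) < 0.5

    def test_waist_when_mid_width_is_smallest(self):
        dims = get_dimensions(5, "L3")  # MVBW < SVBW and MVBW < IVBW... L3: IVBW 36.5 < MVBW
        dims = dims.model_copy(update={"IVBW": 37.0})
        body = build_body(dims, 5)
        widths = []
        for frac in (0.25, 0.5, 0.75):
            sec = body.mesh.section(plane_origin=(0, 0, frac * dims.PVBH), plane_normal=(0, 0, 1))
            pts = np.vstack([np.asarray(d) for d in sec.discrete])
            widths.append(pts[:, 0].max() - pts[:, 0].min())
        assert widths[1] < widths[0] and widths[1] < widths[2]

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(Exception):
            VertebralDimensions(
                AVBH=0, PVBH=7.2, SVBL=7.7, IVBL=7.7, SVBW=14.6, MVBW=15.2, IVBW=14.6
            )


class TestPosteriorElements:
    def test_oversized_foramen_rejected(self):
        dims = get_dimensions(1, "L3")
        arch = derive_arch_parameters(
            dims, 1, overrides={"foramen_frontal_diameter": 2 * dims.MVBW}
        )
        with pytest.raises(sk.GeometryError):
            build_posterior_elements(dims, arch, 1)

    def test_group4_spinous_slants_down_group5_horizontal(self):
        for group, lo, hi in ((4, 13.0, 17.0), (5, 0.0, 2.0)):
            dims = get_dimensions(group, "L3")
            arch = derive_arch_parameters(dims, group)
            solids = build_posterior_elements(dims, arch, group)
            angle = _spinous_angle(solids)
            assert lo <= angle <= hi

    def test_facet_cutout_solved_to_target_gap(self, config):
        for g in (1, 5):
            spec = facet_spec(g, config)
            assert spec.cutout_radius > spec.pin_radius
            assert spec.measured_gap <= 0.5
            assert abs(spec.measured_gap - config.arch.facet_gap_target) <= 3 * config.arch.facet_gap_tolerance


class TestArchitecture:
    def test_component_counts_by_group(self, vertebra_l3):
        expected = {1: 6, 2: 4, 3: 4, 4: 1, 5: 1}
        for g, model in vertebra_l3.items():
            assert len(model.components) == expected[g], f"group {g}"

    def test_newborn_tissue_split(self, newborn_vertebra):
        assert len(newborn_vertebra.bone_components) == 3
        assert len(newborn_vertebra.cartilage_components) == 3

    def test_fused_groups_are_single_bone(self, vertebra_l3):
        for g in (4, 5):
            comps = vertebra_l3[g].components
            assert len(comps) == 1
            assert comps[0].tissue.tissue == "cortical bone"
            assert comps[0].solid.body_count == 1

    def test_all_components_watertight(self, vertebra_l3):
        for model in vertebra_l3.values():
            for c in model.components:
                assert c.solid.is_watertight, c.anatomical_name

    def test_infant_l5_midline_cartilage_flag(self, config):
        special = config.model_copy(
            update={"arch": config.arch.model_copy(update={"group2_l5_midline_cartilage": True})}
        )
        model = build_vertebra(2, "L5", special)
        # retaining the midline synchondrosis splits the arch into two
        # semi-arches: the L5 exception reproduces the newborn architecture
        assert len(model.components) == 6
        assert len(model.cartilage_components) == 3
        assert len(model.bone_components) == 3

    def test_cartilage_contacts_both_bone_neighbours(self, newborn_vertebra):
        comps = {c.anatomical_name: c.solid for c in newborn_vertebra.components}
        pairs = [
            ("right pedicle cartilage", "body"),
            ("right pedicle cartilage", "right semi-arch"),
            ("left pedicle cartilage", "body"),
            ("left pedicle cartilage", "left semi-arch"),
            ("midline cartilage", "right semi-arch"),
            ("midline cartilage", "left semi-arch"),
        ]
        for a, b in pairs:
            r = sk.min_distance(comps[a], comps[b])
            assert not r.overlapping
            assert r.distance < 0.05, (a, b)

    def test_no_component_pair_overlaps(self, newborn_vertebra):
        import itertools

        comps = newborn_vertebra.components
        for ca, cb in itertools.combinations(comps, 2):
            try:
                inter = sk.intersection(ca.solid, cb.solid, pitch=0.08)
                vol = inter.volume
            except sk.GeometryError:
                vol = 0.0
            smaller = min(ca.solid.volume, cb.solid.volume)
            assert vol < 1e-3 * smaller, (ca.anatomical_name, cb.anatomical_name)

    def test_foramen_shape_by_age(self, vertebra_l3):
        circ1 = measure_foramen(vertebra_l3[1]).measured
        circ4 = measure_foramen(vertebra_l3[4]).measured
        assert circ1 > 0.9  # newborn foramen is circular
        assert circ4 < circ1  # middle childhood trends triangular

    def test_total_volume_grows_with_age(self, vertebra_l3):
        totals = [
            sum(c.solid.volume for c in vertebra_l3[g].components) for g in range(1, 6)
        ]
        assert all(b > a for a, b in zip(totals, totals[1:]))


class TestDeterminism:
    def test_repeat_build_is_byte_identical(self):
        dims = get_dimensions(2, "L4")
        cfg = default_config()
        grp = get_age_group(2)
        g1 = BodyGeometry(dims, grp, _arch_for(dims, grp, cfg), cfg).mesh()
        g2 = BodyGeometry(dims, grp, _arch_for(dims, grp, cfg), cfg).mesh()
        assert g1.vertices.tobytes() == g2.vertices.tobytes()
        assert g1.faces.tobytes() == g2.faces.tobytes()
        p1 = build_posterior_elements(dims, _arch_for(dims, grp, cfg), grp, cfg)
        p2 = build_posterior_elements(dims, _arch_for(dims, grp, cfg), grp, cfg)
        for a, b in zip(p1, p2):
            assert a.vertices.tobytes() == b.vertices.tobytes()
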