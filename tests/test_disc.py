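"""Disc construction: heights, wedge, cavity fraction, nucleus fit."""

import numpy as np
import pytest

from pedispine import solid_kernel as sk
from pedispine.config import default_config
from pedispine.disc import (
    DISC_PAIRS,
    build_disc,
    disc_height,
    disc_solids,
    parse_pair,
)
from pedispine.osteometry import get_dimensions
from pedispine.validation import check_disc


class TestDiscHeight:
    def test_newborn_discs_match_body_heights(self):
        # ratio 1.0 x mean(PVBH of L3, L4) = mean(7.2, 7.3)
        assert disc_height(1, "L3/4") == pytest.approx(7.25)

    def test_height_is_linear_in_the_ratio(self, config):
        half = config.model_copy(
            update={"disc": config.disc.model_copy(update={"height_ratio": {1: 0.5, 2: 0.8, 3: 0.6, 4: 0.4, 5: 0.3}})}
        )
        assert disc_height(1, "L3/4", half) == pytest.approx(3.625)

    def test_preadolescent_discs_shorter_than_bodies(self):
        mean_pvbh = 0.5 * (get_dimensions(5, "L3").PVBH + get_dimensions(5, "L4").PVBH)
        assert disc_height(5, "L3/4") < mean_pvbh

    def test_pair_parsing(self):
        assert parse_pair("l3/4")[0].value == "L3"
        assert parse_pair("L5/S1")[1] is None
        with pytest.raises(ValueError):
            parse_pair("L6/7")


class TestDiscGeometry:
    def test_wedge_angle_and_cavity(self, newborn_disc):
        rep = check_disc(newborn_disc)
        assert rep["wedge angle"].measured == pytest.approx(7.0, abs=0.5)
        assert rep["cavity volume fraction"].measured == pytest.approx(0.50, abs=0.05)
        assert rep["superior face planarity"].measured < 0.05
        assert rep.overall_pass

    def test_zero_wedge_gives_parallel_faces(self):
        flat = build_disc(1, "L3/4", wedge_angle=0.0)
        rep = check_disc(flat)
        assert rep["wedge angle"].measured < 0.2

    def test_annulus_and_nucleus_watertight_disjoint(self, newborn_disc):
        ann, nuc = newborn_disc.annulus.solid, newborn_disc.nucleus.solid
        assert ann.is_watertight and nuc.is_watertight
        r = sk.min_distance(nuc, ann)
        assert not r.overlapping
        assert 0.0 < r.distance <= 0.1  # uniform clearance stays below 0.1 mm

    def test_no_volume_lost_between_annulus_and_nucleus(self, newborn_disc):
        # cavity volume = envelope - annulus; the nucleus must fit inside it
        env = newborn_disc.envelope.volume
        ann = newborn_disc.annulus.solid.volume
        nuc = newborn_disc.nucleus.solid.volume
        assert nuc < env - ann
        # union of disjoint parts adds volumes (checked on the fields)
        lo, hi = newborn_disc.nucleus.solid.bounds
        rng = np.random.default_rng(3)
        pts = rng.uniform(lo, hi, size=(20000, 3))
        both = (newborn_disc.annulus.solid.sdf(pts) < 0) & (newborn_disc.nucleus.solid.sdf(pts) < 0)
        assert both.sum() == 0

    def test_nucleus_contained_for_all_groups_at_l34(self):
        for g in (2, 4):
            rep = check_disc(build_disc(g, "L3/4"))
            assert rep["nucleus outside cavity (fraction)"].measured <= 0.001
            assert rep.overall_pass

    def test_translated_nucleus_fails_containment(self, newborn_disc):
        import copy

        broken = copy.copy(newborn_disc)
        broken.nucleus = copy.copy(newborn_disc.nucleus)
        broken.nucleus.solid = newborn_disc.nucleus.solid.translated((0, 5.0, 0))
        rep = check_disc(broken)
        assert not rep["nucleus outside cavity (fraction)"].passed

    def test_prism_scaling_quadruples_volume(self):
        """Doubling the footprint at fixed height scales volume by 4 within 1%."""
        ang = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        outline = np.column_stack([12 * np.cos(ang), 9 * np.sin(ang)])
        env1, *_ = disc_solids(outline, 6.0, 0.0, default_config())
        env2, *_ = disc_solids(2 * outline, 6.0, 0.0, default_config())
        assert env2.volume / env1.volume == pytest.approx(4.0, rel=0.01)


class TestAllPairs:
    @pytest.mark.parametrize("pair", DISC_PAIRS)
    def test_newborn_pairs_build_and_validate(self, pair):
        rep = check_disc(build_disc(1, pair))
        assert rep.overall_pass, rep.to_text()
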