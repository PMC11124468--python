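"""Dimension table integrity, material registry and derived parameters."""

import pytest

from pedispine.osteometry import (
    ARCH_FRACTIONS,
    LEVELS,
    OsteometryLookupError,
    age_groups,
    derive_arch_parameters,
    get_age_group,
    get_dimensions,
    get_material,
    material_registry,
)

DIM_NAMES = ("AVBH", "PVBH", "SVBL", "IVBL", "SVBW", "MVBW", "IVBW")


class TestDimensionTable:
    def test_every_pair_resolves_and_is_positive(self):
        count = 0
        for group in age_groups():
            for level in LEVELS:
                rec = get_dimensions(group, level)
                for name in DIM_NAMES:
                    assert 0 < getattr(rec, name) < 50
                count += 1
        assert count == 25

    def test_five_groups_with_specimen_counts(self):
        groups = age_groups()
        assert [g.index for g in groups] == [1, 2, 3, 4, 5]
        assert [g.specimen_count for g in groups] == [23, 12, 9, 7, 6]

    @pytest.mark.parametrize("level", LEVELS)
    def test_growth_from_newborn_to_infant_in_every_dimension(self, level):
        a, b = get_dimensions(1, level), get_dimensions(2, level)
        for name in DIM_NAMES:
            assert getattr(b, name) >= getattr(a, name)

    @pytest.mark.parametrize("level", LEVELS)
    @pytest.mark.parametrize("name", ["AVBH", "SVBL", "SVBW"])
    def test_monotone_growth_across_all_groups(self, level, name):
        values = [getattr(get_dimensions(g, level), name) for g in range(1, 6)]
        assert values == sorted(values)

    def test_widths_exceed_lengths_in_every_record(self):
        for g in range(1, 6):
            for level in LEVELS:
                rec = get_dimensions(g, level)
                assert min(rec.SVBW, rec.MVBW, rec.IVBW) > max(rec.SVBL, rec.IVBL)

    @pytest.mark.parametrize(
        "group, level, name, value",
        [
            (1, "L3", "MVBW", 15.2),
            (1, "L3", "AVBH", 7.2),
            (5, "L2", "SVBW", 34.7),
            (5, "L3", "AVBH", 23.0),
            (4, "L1", "PVBH", 16.3),
        ],
    )
    def test_spot_values(self, group, level, name, value):
        assert getattr(get_dimensions(group, level), name) == value

    def test_unknown_level_and_group_raise_lookup_errors(self):
        with pytest.raises(OsteometryLookupError):
            get_dimensions(1, "L6")
        with pytest.raises(OsteometryLookupError):
            get_dimensions(9, "L1")
        with pytest.raises(OsteometryLookupError):
            get_age_group(0)


class TestMaterials:
    EXPECTED = {
        "cortical bone": (12000, 0.30),
        "trabecular bone": (100, 0.20),
        "cartilage": (10, 0.40),
        "nucleus pulposus": (1, 0.49),
        "annulus fibrosus": (4.2, 0.45),
    }

    def test_registry_has_exactly_five_matching_entries(self):
        reg = material_registry()
        assert set(reg) == set(self.EXPECTED)
        for tissue, (E, nu) in self.EXPECTED.items():
            assert reg[tissue].youngs_modulus_E == E
            assert reg[tissue].poisson_ratio_nu == nu

    def test_lookup_is_case_insensitive(self):
        assert get_material("Cortical Bone").youngs_modulus_E == 12000
        assert get_material("  NUCLEUS PULPOSUS ").poisson_ratio_nu == 0.49

    def test_unknown_tissue_lists_valid_names(self):
        with pytest.raises(OsteometryLookupError, match="annulus fibrosus"):
            get_material("enamel")


class TestDerivedArchParameters:
    def test_defaults_are_documented_fractions(self):
        dims = get_dimensions(1, "L3")
        arch = derive_arch_parameters(dims, 1)
        assert arch.pedicle_width == pytest.approx(0.20 * 15.2)  # 3.04 mm
        for field, (fraction, source) in ARCH_FRACTIONS.items():
            assert getattr(arch, field) == pytest.approx(fraction * getattr(dims, source))

    def test_override_passthrough_and_validation(self):
        dims = get_dimensions(1, "L3")
        arch = derive_arch_parameters(dims, 1, overrides={"pedicle_width": 4.0})
        assert arch.pedicle_width == 4.0
        with pytest.raises(ValueError):
            derive_arch_parameters(dims, 1, overrides={"pedicle_width": -1.0})
        with pytest.raises(ValueError):
            derive_arch_parameters(dims, 1, overrides={"no_such_field": 1.0})

    def test_deterministic(self):
        dims = get_dimensions(3, "L2")
        assert derive_arch_parameters(dims, 3) == derive_arch_parameters(dims, 3)

    def test_foramen_smaller_than_body_widths(self):
        for g in range(1, 6):
            for level in LEVELS:
                dims = get_dimensions(g, level)
                arch = derive_arch_parameters(dims, g)
                assert arch.foramen_frontal_diameter < min(dims.SVBW, dims.MVBW, dims.IVBW)
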