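"""Unit and property tests for per-cell isotope arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diazosym as dz
from diazosym.isotopes import (
    PG_C_TO_FMOL,
    atom_fraction_to_ratio,
    biomass_from_volume,
    biovolume,
    fixation_rate,
    growth_rate,
    growth_to_new_fraction,
    ratio_to_atom_fraction,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


class TestRatioConversion:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.0, 0.0),
            (1.0, 0.5),
            (0.0111802, 0.011056585),  # natural 13C ratio -> atom fraction
        ],
    )
    def test_known_values(self, r, expected):
        assert ratio_to_atom_fraction(r) == pytest.approx(expected, abs=1e-6)

    def test_negative_ratio_rejected(self):
        with pytest.raises(dz.DomainError):
            ratio_to_atom_fraction(-0.1)

    @given(st.floats(0.0, 0.999))
    def test_round_trip_identity(self, a):
        assert ratio_to_atom_fraction(atom_fraction_to_ratio(a)) == pytest.approx(
            a, abs=1e-12
        )

    @given(st.floats(0.0, 100.0), st.floats(1e-6, 100.0))
    def test_strictly_increasing(self, r, dr):
        assert ratio_to_atom_fraction(r + dr) > ratio_to_atom_fraction(r)


class TestBiovolume:
    def test_host_elliptic_cylinder(self):
        m = dz.IsotopeMeasurement("r", "s", "host", 0, 0, length_um=40, width_um=5)
        assert biovolume(m) == pytest.approx(785.398, abs=1e-3)

    def test_symbiont_sphere(self):
        m = dz.IsotopeMeasurement("r", "s", "symbiont", 0, 0, diameter_um=1.5)
        assert biovolume(m) == pytest.approx(1.767, abs=1e-3)

    def test_degenerate_host_dimensions_rejected(self):
        with pytest.raises(dz.DomainError):
            dz.IsotopeMeasurement("r", "s", "host", 0, 0, length_um=0, width_um=5)

    def test_missing_dimension_rejected(self):
        m = dz.IsotopeMeasurement("r", "s", "host", 0, 0, length_um=40)
        with pytest.raises(dz.DomainError):
            biovolume(m)


class TestBiomass:
    def test_host_allometry(self):
        b = biomass_from_volume(785.398, "host")
        assert b.c_content_fmol * 12 / 1000 == pytest.approx(64.14, rel=1e-3)
        assert b.c_content_fmol == pytest.approx(5345, rel=1e-3)
        assert b.n_content_fmol == pytest.approx(806.8, rel=1e-3)

    def test_symbiont_constant_density(self):
        p = dz.BiomassParams(symbiont_c_density_fg_um3=112.0)
        b = biomass_from_volume(1.767, "symbiont", p)
        assert b.c_content_fmol * 12 == pytest.approx(197.9, rel=1e-3)
        assert b.c_content_fmol == pytest.approx(16.49, rel=1e-3)
        assert b.n_content_fmol == pytest.approx(3.30, rel=1e-2)

    def test_unit_cn_ratio_means_equal_contents(self):
        p = dz.BiomassParams(cn_host=1.0)
        b = biomass_from_volume(100.0, "host", p)
        assert b.c_content_fmol == b.n_content_fmol

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(dz.DomainError):
            biomass_from_volume(0.0, "host")


class TestFixationRate:
    def test_no_incorporation_gives_zero(self):
        assert fixation_rate(0.003663, 0.003663, 0.05, 800, 1) == 0.0

    def test_worked_example(self):
        rate = fixation_rate(0.0268, 0.003663, 0.05, 800, 1)
        assert rate == pytest.approx(399.456, abs=1e-2)

    def test_linear_in_content(self):
        r1 = fixation_rate(0.0268, 0.003663, 0.05, 800, 1)
        r2 = fixation_rate(0.0268, 0.003663, 0.05, 1600, 1)
        assert r2 == pytest.approx(2 * r1)

    def test_source_below_initial_rejected(self):
        with pytest.raises(dz.ConfigurationError):
            fixation_rate(0.02, 0.05, 0.01, 800, 1)

    def test_negative_enrichment_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert fixation_rate(0.003, 0.003663, 0.05, 800, 1) == 0.0

    @given(
        st.floats(0.01, 0.04),
        st.floats(1e-4, 2.0),
        st.floats(0.1, 10.0),
    )
    def test_affine_rescaling_invariance(self, a_meas, scale, shift):
        """Simultaneously rescaling all atom fractions leaves the rate fixed."""
        a_init, a_source = 0.003663, 0.05
        base = fixation_rate(a_meas, a_init, a_source, 100.0, 1.0)
        scaled = fixation_rate(
            (a_meas + shift) * scale,
            (a_init + shift) * scale,
            (a_source + shift) * scale,
            100.0,
            1.0,
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(st.floats(0.004, 0.0499), st.floats(1e-6, 0.0001))
    def test_monotone_in_enrichment(self, a, da):
        lo = fixation_rate(a, 0.003663, 0.0501, 100, 1)
        hi = fixation_rate(a + da, 0.003663, 0.0501, 100, 1)
        assert hi > lo


class TestGrowthRate:
    def _a_from_x(self, x, a_nat=0.011056, a_source=0.05):
        return a_nat + x * (a_source - a_nat)

    @pytest.mark.parametrize(
        "x, expected_g",
        [(0.0, 0.0), (0.5, 1.0), (0.75, 2.0)],
    )
    def test_doubling_arithmetic(self, x, expected_g):
        g = growth_rate(self._a_from_x(x), 0.011056, 0.05, 1.0)
        assert g == pytest.approx(expected_g, abs=1e-12)

    def test_saturation_rejected(self):
        with pytest.raises(dz.SaturationError):
            growth_rate(0.05, 0.011056, 0.05, 1.0)

    def test_below_natural_clamped_to_zero(self):
        with pytest.warns(UserWarning):
            assert growth_rate(0.010, 0.011056, 0.05, 1.0) == 0.0

    @given(st.floats(0.0, 5.0), st.floats(0.1, 3.0))
    def test_forward_inverse_round_trip(self, g, t):
        """growth_rate is the exact inverse of the exponential forward model."""
        x = growth_to_new_fraction(g, t)
        a = self._a_from_x(x)
        assert growth_rate(a, 0.011056, 0.05, t) == pytest.approx(
            g, rel=1e-9, abs=1e-9
        )

    @given(st.floats(0.012, 0.0499), st.floats(1e-6, 1e-4))
    def test_monotone_in_enrichment(self, a, da):
        if a + da >= 0.05:
            return
        assert growth_rate(a + da, 0.011056, 0.05, 1.0) > growth_rate(
            a, 0.011056, 0.05, 1.0
        )


def test_labeling_config_rejects_inverted_source():
    with pytest.raises(dz.ConfigurationError):
        dz.LabelingConfig(a_source_n=0.001)


def test_menden_deuer_lessard_units():
    """Host allometry: 1 um^3 cell -> 0.288 pg C."""
    b = biomass_from_volume(1.0, "host")
    assert b.c_content_fmol == pytest.approx(0.288 * PG_C_TO_FMOL)
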