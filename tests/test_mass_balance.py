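"""Nitrogen/carbon partitioning between host and symbionts."""

import math

import pytest

import diazosym as dz
from diazosym.isotopes import atom_fraction_to_ratio, growth_to_new_fraction
from diazosym.mass_balance import (
    partition_carbon,
    partition_nitrogen,
    symbiosis_growth,
)


def _measurement(roi, sid, compartment, a_c, a_n, **dims):
    return dz.IsotopeMeasurement(
        roi, sid, compartment,
        ratio_c=atom_fraction_to_ratio(a_c),
        ratio_n=atom_fraction_to_ratio(a_n),
        **dims,
    )


def _cell(a_c, a_n, c_fmol, n_fmol, compartment, roi="r", sid="s"):
    m = _measurement(roi, sid, compartment, a_c, a_n)
    b = dz.CellBiomass(biovolume_um3=1.0, c_content_fmol=c_fmol, n_content_fmol=n_fmol)
    return m, b


def _a_n(rate, n_fmol, lab, t=1.0):
    """Nitrogen atom fraction produced by a given fixation rate."""
    x = rate * t / n_fmol
    return lab.a_nat_n + x * (lab.a_source_n - lab.a_nat_n)


def _a_c(x, lab):
    return lab.a_nat_c + x * (lab.a_source_c - lab.a_nat_c)


@pytest.fixture
def lab():
    return dz.LabelingConfig()


def _symbiosis(host_n_rate, sym_n_rates, lab, host_n=807.0, sym_n=3.3,
               host_c_x=0.0, sym_c_x=0.0, host_c=5345.0, sym_c=16.5):
    host = _cell(_a_c(host_c_x, lab), _a_n(host_n_rate, host_n, lab),
                 host_c, host_n, "host", roi="h")
    syms = tuple(
        _cell(_a_c(sym_c_x, lab), _a_n(r, sym_n, lab), sym_c, sym_n,
              "symbiont", roi=f"y{i}")
        for i, r in enumerate(sym_n_rates)
    )
    return dz.SymbiosisRecord(symbiosis_id="s", host=host, symbionts=syms)


class TestPartitionNitrogen:
    def test_transfer_regime(self, lab):
        """Host recovers 643.5, symbionts retain 6.5: phi=0.99, 100-fold."""
        s = _symbiosis(643.5, [6.5 / 4] * 4, lab)
        f_total, f_sym, phi, amp = partition_nitrogen(s, lab)
        assert f_total == pytest.approx(650.0, rel=1e-9)
        assert f_sym == pytest.approx(6.5, rel=1e-9)
        assert phi == pytest.approx(0.99, rel=1e-9)
        assert amp == pytest.approx(100.0, rel=1e-9)

    def test_complete_transfer(self, lab):
        s = _symbiosis(100.0, [0.0, 0.0], lab)
        f_total, f_sym, phi, amp = partition_nitrogen(s, lab)
        assert phi == 1.0
        assert math.isinf(amp)

    def test_no_transfer(self, lab):
        s = _symbiosis(0.0, [5.0, 5.0], lab)
        _, _, phi, amp = partition_nitrogen(s, lab)
        assert phi == 0.0
        assert amp == pytest.approx(1.0)

    def test_no_fixation_gives_missing(self, lab):
        s = _symbiosis(0.0, [0.0], lab)
        f_total, _, phi, amp = partition_nitrogen(s, lab)
        assert f_total == 0.0
        assert math.isnan(phi) and math.isnan(amp)

    def test_amplification_identity(self, lab):
        """amplification = 1/(1-phi) exactly, for phi < 1."""
        for host_rate, sym_rate in [(90.0, 10.0), (50.0, 50.0), (643.5, 6.5)]:
            s = _symbiosis(host_rate, [sym_rate / 2] * 2, lab)
            _, _, phi, amp = partition_nitrogen(s, lab)
            assert amp * (1 - phi) == pytest.approx(1.0, rel=1e-12)

    def test_additivity_vs_pooled_estimator(self, lab):
        """Summed member rates equal the rate of the pooled N pool at its
        content-weighted mean enrichment (linearity of the estimator)."""
        s = _symbiosis(600.0, [2.0, 1.0, 0.5, 3.0], lab)
        f_total, _, _, _ = partition_nitrogen(s, lab)
        members = [s.host, *s.symbionts]
        n_tot = sum(b.n_content_fmol for _, b in members)
        a_bar = sum(
            dz.ratio_to_atom_fraction(m.ratio_n) * b.n_content_fmol
            for m, b in members
        ) / n_tot
        pooled = dz.fixation_rate(a_bar, lab.a_nat_n, lab.a_source_n, n_tot, lab.t_days)
        assert pooled == pytest.approx(f_total, rel=1e-9)


class TestPartitionCarbon:
    def test_one_percent_regime(self, lab):
        """Host fixes 2256, symbionts jointly 22.79: psi ~ 1%."""
        host = _cell(_a_c(2256.0 / 5345.0, lab), lab.a_nat_n, 5345.0, 807.0, "host", "h")
        syms = tuple(
            _cell(_a_c((22.79 / 4) / 16.5, lab), lab.a_nat_n, 16.5, 3.3,
                  "symbiont", f"y{i}")
            for i in range(4)
        )
        s = dz.SymbiosisRecord("s", host, syms)
        f_total, psi = partition_carbon(s, lab)
        assert f_total == pytest.approx(2278.79, rel=1e-6)
        assert psi == pytest.approx(22.79 / 2278.79, rel=1e-9)
        assert psi == pytest.approx(0.0100, abs=2e-4)

    def test_no_symbiont_uptake(self, lab):
        s = _symbiosis(1.0, [0.0], lab, host_c_x=0.4, sym_c_x=0.0)
        _, psi = partition_carbon(s, lab)
        assert psi == 0.0

    def test_host_dark(self, lab):
        s = _symbiosis(1.0, [0.0], lab, host_c_x=0.0, sym_c_x=0.3)
        _, psi = partition_carbon(s, lab)
        assert psi == 1.0


class TestSymbiosisGrowth:
    def test_equal_enrichment_collapses_to_single_rate(self, lab):
        x = growth_to_new_fraction(0.7, 1.0)
        s = _symbiosis(1.0, [0.1] * 4, lab, host_c_x=x, sym_c_x=x)
        g = symbiosis_growth(s, lab)
        assert g == pytest.approx(0.7, rel=1e-9)

    def test_weighted_mean_worked_example(self, lab):
        """Host at x=0.4257 (g=0.8) with 2.9% symbiont carbon at x=0.3402
        gives a combined growth just under the host's."""
        s = _symbiosis(
            1.0, [0.1], lab,
            host_c_x=0.4257, sym_c_x=0.3402,
            host_c=0.971, sym_c=0.029,
        )
        assert symbiosis_growth(s, lab) == pytest.approx(0.7939, abs=1e-3)

    def test_negligible_symbiont_carbon_limit(self, lab):
        x_h = growth_to_new_fraction(0.8, 1.0)
        s = _symbiosis(1.0, [0.1], lab, host_c_x=x_h, sym_c_x=0.0,
                       host_c=5345.0, sym_c=1e-9)
        g_host_only = dz.growth_rate(_a_c(x_h, lab), lab.a_nat_c, lab.a_source_c, 1.0)
        assert symbiosis_growth(s, lab) == pytest.approx(g_host_only, rel=1e-6)


class TestSymbiosisRecordValidation:
    def test_requires_symbionts(self, lab):
        host = _cell(0.02, 0.01, 100, 10, "host")
        with pytest.raises(dz.ValidationError):
            dz.SymbiosisRecord("s", host, ())

    def test_rejects_mismatched_symbiosis_id(self, lab):
        host = _cell(0.02, 0.01, 100, 10, "host", sid="s")
        stray = _cell(0.02, 0.01, 10, 2, "symbiont", sid="other")
        with pytest.raises(dz.ValidationError):
            dz.SymbiosisRecord("s", host, (stray,))

    def test_rejects_symbiont_in_host_slot(self, lab):
        imposter = _cell(0.02, 0.01, 100, 10, "symbiont")
        sym = _cell(0.02, 0.01, 10, 2, "symbiont")
        with pytest.raises(dz.ValidationError):
            dz.SymbiosisRecord("s", imposter, (sym,))
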