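"""Reaction rate laws: glycolysis, lactate transport, the malate-aspartate
shuttle, proton buffering and the oxygen balance."""

import math

import numpy as np
import pytest

from hibrain import (DomainError, ParameterSet, effective_proton_volume,
                     glycolysis_rate, integrate_shuttle_to_equilibrium,
                     lactate_transport_rate, ma_shuttle_rate,
                     mitochondrial_oxygen_derivative,
                     shuttle_mass_action_ratio)

P = ParameterSet()


def _glycolysis_reference(ADP, Pi, gluc, NAD, ATP, kA, kP, kG, kN, vmax):
    """Independent direct transcription of the rate law, kept separate
    from the implementation."""
    return (vmax * ADP ** 2 * Pi ** 2 * gluc * NAD ** 2
            / ((kA ** 2 + ATP ** 2) * (kP ** 2 + Pi ** 2)
               * (kG + gluc) * (kN ** 2 + NAD ** 2)))


class TestGlycolysis:
    def test_zero_when_nad_absent(self):
        assert glycolysis_rate(0.03, 1.0, 1.2, 0.0, 2.2, P) == 0.0

    def test_glucose_saturation(self):
        lo = glycolysis_rate(0.03, 1.0, 50.0, 359.0, 2.2, P)
        hi = glycolysis_rate(0.03, 1.0, 5000.0, 359.0, 2.2, P)
        # the glucose factor approaches 1: large increases barely matter
        assert hi / lo < 1.02
        assert hi > lo

    @pytest.mark.parametrize("args", [
        (0.05, 0.9, 1.1, 300.0, 2.0),
        (0.5, 2.0, 0.3, 50.0, 0.5),
        (1.0, 1.0, 1.0, 1.0, 1.0),
    ])
    def test_matches_independent_evaluation(self, args):
        ADP, Pi, gluc, NAD, ATP = args
        got = glycolysis_rate(ADP, Pi, gluc, NAD, ATP, P, v_glyc=0.37)
        want = _glycolysis_reference(ADP, Pi, gluc, NAD, ATP,
                                     P.k_m_glycA, P.k_m_glycP,
                                     P.k_m_glycG, P.k_m_glycN, 0.37)
        assert got == pytest.approx(want, rel=1e-13)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            glycolysis_rate(-0.1, 1.0, 1.0, 1.0, 1.0, P)


class TestLactateTransport:
    def test_zero_at_capillary_concentration(self):
        assert lactate_transport_rate(P.lac_cap, P) == pytest.approx(0.0)

    def test_maximal_influx_at_zero_lactate(self):
        expected = P.v_MCT * P.lac_cap / (P.k_MCT + P.lac_cap)
        assert lactate_transport_rate(0.0, P) == pytest.approx(expected)

    def test_full_form_symmetry(self):
        p = P.replace(k_MCT_H=1e-7)
        assert lactate_transport_rate(p.lac_cap, p, H_cyt=p.H_cap) == \
            pytest.approx(0.0, abs=1e-18)

    def test_full_form_requires_protons(self):
        p = P.replace(k_MCT_H=1e-7)
        with pytest.raises(DomainError):
            lactate_transport_rate(1.0, p)

    def test_efflux_above_capillary(self):
        assert lactate_transport_rate(5.0, P) < 0.0


class TestMAShuttle:
    def test_zero_at_equilibrium_ratio(self):
        # choose concentrations whose mass-action ratio equals K_eq = 10
        rate = ma_shuttle_rate(1.0, 1.0, 1e-7, 2.0, 5.0, 1e-7, P, k_r=3.0)
        assert shuttle_mass_action_ratio(1.0, 1.0, 1e-7, 2.0, 5.0, 1e-7) \
            == pytest.approx(10.0)
        assert rate == pytest.approx(0.0, abs=1e-20)

    def test_forward_only_without_products(self):
        rate = ma_shuttle_rate(1.0, 1.0, 1e-7, 0.0, 0.0, 1e-7, P, k_r=1.0)
        assert rate == pytest.approx(10.0 * 1.0 * 1.0 * 1e-7)

    def test_isolated_integration_reaches_keq(self):
        out = integrate_shuttle_to_equilibrium(
            dict(NADH_cyt=3.0, NAD_mit=0.7, H_cyt=2e-7,
                 NADH_mit=0.9, NAD_cyt=1.1, H_mit=5e-8))
        assert out["ratio"] == pytest.approx(10.0, rel=1e-3)

    def test_equilibrium_independent_of_start(self):
        a = integrate_shuttle_to_equilibrium(
            dict(NADH_cyt=0.2, NAD_mit=4.0, H_cyt=1e-6,
                 NADH_mit=0.01, NAD_cyt=0.5, H_mit=1e-8))
        assert a["ratio"] == pytest.approx(10.0, rel=1e-3)


class TestProtonBuffering:
    def test_monotone_decreasing_in_pH(self):
        vols = [effective_proton_volume(ph, P)
                for ph in np.linspace(6.0, 8.0, 21)]
        assert all(a > b for a, b in zip(vols, vols[1:]))
        assert all(v > 0 for v in vols)

    def test_small_dpH_limit(self):
        # analytic limit: C * ln(10) * 10^-pH * Vol_cyt
        p = P.replace(dpH=1e-7)
        ph = 7.2
        expected = P.C_buffi_c * math.log(10) * 10 ** (-ph) * P.Vol_cyt
        assert effective_proton_volume(ph, p) == \
            pytest.approx(expected, rel=1e-6)

    def test_volume_divisor_switch(self):
        p = P.replace(buffer_vol_divides=True)
        ratio = effective_proton_volume(7.0, p) / \
            effective_proton_volume(7.0, P)
        assert ratio == pytest.approx(1.0 / P.Vol_cyt ** 2)

    def test_nonpositive_dpH_rejected(self):
        from hibrain.errors import ConfigError
        bad = ParameterSet()
        bad.dpH = 0.0
        with pytest.raises(ConfigError):
            effective_proton_volume(7.0, bad)

    def test_out_of_range_pH_rejected(self):
        with pytest.raises(DomainError):
            effective_proton_volume(4.9, P)


class TestOxygenBalance:
    def test_no_cell_death_reduces_to_base(self):
        d0 = mitochondrial_oxygen_derivative(0.02, 0.02, 0.1, P)
        assert d0 == pytest.approx(0.02 / P.V_mit - 0.1)

    def test_half_dead_doubles_transfer_term(self):
        p = P.replace(d_f=0.5)
        base = mitochondrial_oxygen_derivative(0.02, 0.02, 0.0, P)
        halved = mitochondrial_oxygen_derivative(0.02, 0.02, 0.0, p)
        assert halved == pytest.approx(2.0 * base)

    def test_consumption_only_is_negative(self):
        assert mitochondrial_oxygen_derivative(0.02, 0.0, 0.3, P) < 0.0

    def test_singular_dead_fraction_rejected(self):
        from hibrain.errors import ConfigError
        with pytest.raises(ConfigError):
            P.replace(d_f=1.0)
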