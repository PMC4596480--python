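"""Time-course integration, insult protocol machinery and conservation."""

import numpy as np
import pytest

from hibrain import Model, ParameterSet
from hibrain.errors import ConfigError
from hibrain.model import STATE_NAMES
from hibrain.simulate import (InputTraces, Protocol, apply_protocol,
                              simulate)

_I = {n: i for i, n in enumerate(STATE_NAMES)}


class TestInputTraces:
    def test_rejects_non_monotone_time(self):
        with pytest.raises(ConfigError):
            InputTraces(time=[0, 2, 1], SaO2=[0.9] * 3, Pa=[50] * 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            InputTraces(time=[0, 1], SaO2=[0.9, 1.2], Pa=[50, 50])
        with pytest.raises(ConfigError):
            InputTraces(time=[0, 1], SaO2=[0.9, 0.9], Pa=[50, -3])

    def test_linear_interpolation(self):
        tr = InputTraces(time=[0, 100], SaO2=[0.9, 0.5], Pa=[50, 40])
        assert tr.sao2_at(50.0) == pytest.approx(0.7)
        assert tr.pa_at(25.0) == pytest.approx(47.5)


class TestProtocol:
    def test_base_ramp_shape(self):
        prot = Protocol()
        assert prot.base_k_occ(0.0) == 0.0
        assert prot.base_k_occ(prot.t_occlude + 30.0) == pytest.approx(0.5)
        assert prot.base_k_occ(prot.t_occlude + 60.0) == 1.0
        assert prot.base_k_occ(prot.t_release - 1.0) == 1.0
        assert prot.base_k_occ(prot.t_release + 30.0) == pytest.approx(0.5)
        assert prot.base_k_occ(prot.duration) == 0.0

    def test_scenario_none_keeps_parameters(self):
        prot, p = Protocol(), ParameterSet()
        eff = apply_protocol(prot, prot.duration - 1.0, p)
        assert eff == {"k_occ": 0.0, "k_unc": p.k_unc, "d_f": p.d_f}

    def test_cell_death_ramps_in_after_release(self):
        prot = Protocol(scenario="cell_death", post_d_f=0.45)
        p = ParameterSet()
        before = apply_protocol(prot, prot.t_change - 1.0, p)
        after = apply_protocol(prot, prot.t_change + prot.d_f_ramp_s, p)
        assert before["d_f"] == pytest.approx(0.0, abs=1e-6)
        assert after["d_f"] == pytest.approx(0.45)

    def test_persistent_occlusion_never_releases(self):
        prot = Protocol(scenario="occlusion", post_k_occ=1.0)
        p = ParameterSet()
        for t in np.linspace(prot.t_release, prot.duration, 20):
            assert apply_protocol(prot, float(t), p)["k_occ"] == \
                pytest.approx(1.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigError):
            Protocol(scenario="zombie")


class TestSimulation:
    def test_constant_baseline_stays_flat(self, model):
        t = np.array([0.0, 1800.0, 3600.0])
        tr = InputTraces(time=t,
                         SaO2=np.full(3, model.params.SaO2_n),
                         Pa=np.full(3, model.params.P_a_n))
        res = simulate(model, tr, output_dt=300.0)
        for name in ("dHbO2", "dHHb", "dOxCCO"):
            assert np.max(np.abs(res.signals[name])) < 1e-3
        assert np.max(np.abs(res.signals["pH"] - 7.0)) < 1e-4
        assert np.max(np.abs(res.signals["CBF"] - 1.0)) < 1e-5

    def test_insult_signature(self, insult_run):
        """During the insult: HbO2 and oxCCO fall, HHb rises, NTP and PCr
        fractions fall, Pi fraction rises, pH drops, CBF and CMRO2 fall."""
        s = insult_run.signals
        mid = np.argmin(np.abs(s.time - 1200.0))
        assert s["dHbO2"][mid] < -5.0
        assert s["dHHb"][mid] > 5.0
        assert s["dOxCCO"][mid] < -0.2
        assert s["NTP_EPP"][mid] < s["NTP_EPP"][0] - 0.05
        assert s["PCr_EPP"][mid] < s["PCr_EPP"][0] - 0.05
        assert s["Pi_EPP"][mid] > s["Pi_EPP"][0] + 0.1
        assert s["pH"][mid] < 6.9
        assert s["CBF"][mid] < 0.95
        assert s["CMRO2"][mid] < 0.8

    def test_return_to_baseline_without_state_change(self, insult_run):
        s = insult_run.signals
        for name in ("dHbO2", "dHHb", "dOxCCO"):
            assert abs(s[name][-1]) < 0.1
        assert s["NTP_EPP"][-1] == pytest.approx(s["NTP_EPP"][0], abs=5e-3)
        assert s["Pi_EPP"][-1] == pytest.approx(s["Pi_EPP"][0], abs=5e-3)
        assert s["pH"][-1] == pytest.approx(7.0, abs=0.01)
        assert s["CBF"][-1] == pytest.approx(1.0, abs=0.01)

    def test_conservation_along_insult(self, insult_run):
        """NAD pools and the exchangeable phosphate pool drift < 1e-6
        relative over a full simulated insult."""
        st = insult_run.states
        for pool in (st[_I["NAD_cyt"]] + st[_I["NADH_cyt"]],
                     st[_I["NAD_mit"]] + st[_I["NADH_mit"]],
                     st[_I["PCr"]] + st[_I["Pi"]] + 2 * st[_I["ATP"]],
                     st[_I["ATP"]] + st[_I["ADP"]],
                     st[_I["PCr"]] + st[_I["Cr"]]):
            assert np.ptp(pool) / pool[0] < 1e-6

    def test_phosphate_identity_along_trajectory(self, insult_run):
        s = insult_run.signals
        total = 2 * s["NTP_EPP"] + s["PCr_EPP"] + s["Pi_EPP"]
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_tolerance_robustness(self, model):
        """Tightening solver tolerances tenfold changes signals < 0.1%."""
        prot = Protocol(insult_s=600.0, recovery_s=600.0)
        t = np.arange(0.0, prot.duration + 60.0, 60.0)
        sao2 = np.full_like(t, model.params.SaO2_n)
        during = (t >= prot.t_occlude) & (t <= prot.t_release)
        sao2[during] = 0.35
        tr = InputTraces(time=t, SaO2=sao2,
                         Pa=np.full_like(t, model.params.P_a_n))
        a = simulate(model, tr, prot, output_dt=60.0, rtol=1e-6)
        b = simulate(model, tr, prot, output_dt=60.0, rtol=1e-7)
        for name in ("NTP_EPP", "Pi_EPP", "pH", "CBF"):
            scale = max(np.max(np.abs(a.signals[name])), 1.0)
            assert np.max(np.abs(a.signals[name] - b.signals[name])) \
                / scale < 1e-3

    def test_cell_death_scenario_shifts_pi_asymptote(self, model):
        """Post-insult Pi/EPP settles at (1-d_f) * living ratio + d_f."""
        d_f = 0.45
        prot = Protocol(scenario="cell_death", post_d_f=d_f,
                        insult_s=600.0, recovery_s=2400.0)
        t = np.arange(0.0, prot.duration + 60.0, 60.0)
        sao2 = np.full_like(t, model.params.SaO2_n)
        during = (t >= prot.t_occlude) & (t <= prot.t_release)
        sao2[during] = 0.35
        tr = InputTraces(time=t, SaO2=sao2,
                         Pa=np.full_like(t, model.params.P_a_n))
        res = simulate(model, tr, prot, output_dt=60.0, rtol=1e-6)
        s = res.signals
        base_pi = s["Pi_EPP"][0]
        # living ratios relax back towards baseline; the observable keeps
        # the dead-fraction offset
        expected = (1 - d_f) * base_pi + d_f
        assert s["Pi_EPP"][-1] == pytest.approx(expected, abs=0.03)
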