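"""Synthetic-study generation: protocol shape, determinism, noise model."""

import numpy as np
import pytest

from hibrain import ParameterSet
from hibrain.errors import ConfigError
from hibrain.synth import (default_noise_sd, make_insult_protocol,
                           make_pseudo_measurements)


class TestInsultProtocol:
    def test_occlusion_ramp_shape(self):
        _, prot = make_insult_protocol(seed=0)
        assert prot.base_k_occ(prot.t_occlude - 1.0) == 0.0
        assert prot.base_k_occ(prot.t_occlude + 60.0) == 1.0
        assert prot.base_k_occ(prot.t_release - 1.0) == 1.0
        assert prot.base_k_occ(prot.t_release + 60.0) == 0.0

    def test_zero_jitter_floor_at_normal_is_constant(self):
        tr, _ = make_insult_protocol(sao2_floor=0.96, sao2_n=0.96,
                                     jitter_sd=0.0, seed=1)
        assert np.allclose(tr.SaO2, 0.96)
        assert np.allclose(tr.Pa, 50.0)

    def test_desaturation_reaches_floor(self):
        tr, prot = make_insult_protocol(sao2_floor=0.3, jitter_sd=0.0,
                                        seed=1)
        during = (tr.time > prot.t_occlude + 600) & \
            (tr.time < prot.t_release)
        assert np.all(tr.SaO2[during] < 0.35)
        assert tr.SaO2[0] == pytest.approx(0.96)

    def test_seed_determinism(self):
        a, _ = make_insult_protocol(seed=5)
        b, _ = make_insult_protocol(seed=5)
        c, _ = make_insult_protocol(seed=6)
        assert np.array_equal(a.SaO2, b.SaO2)
        assert not np.array_equal(a.SaO2, c.SaO2)

    def test_sampling_interval_is_one_minute(self):
        tr, _ = make_insult_protocol(seed=0)
        assert np.allclose(np.diff(tr.time), 60.0)

    def test_invalid_durations_rejected(self):
        with pytest.raises(ConfigError):
            make_insult_protocol(baseline_min=-1.0)
        with pytest.raises(ConfigError):
            make_insult_protocol(sao2_floor=0.0)


@pytest.fixture(scope="module")
def study():
    traces, prot = make_insult_protocol(seed=21, jitter_sd=0.0,
                                        insult_min=10.0,
                                        recovery_min=15.0)
    return make_pseudo_measurements(ParameterSet(), traces, prot,
                                    noise_fraction=0.05, seed=21)


class TestPseudoMeasurements:
    def test_zero_noise_equals_model_output(self):
        traces, prot = make_insult_protocol(seed=2, jitter_sd=0.0,
                                            insult_min=5.0,
                                            recovery_min=5.0)
        study = make_pseudo_measurements(ParameterSet(), traces, prot,
                                         noise_sd={}, seed=2)
        for name in study.clean.data:
            assert np.array_equal(study.measurements[name],
                                  study.clean[name])

    def test_measurement_reproducibility(self, study):
        traces, prot = make_insult_protocol(seed=21, jitter_sd=0.0,
                                            insult_min=10.0,
                                            recovery_min=15.0)
        again = make_pseudo_measurements(ParameterSet(), traces, prot,
                                         noise_fraction=0.05, seed=21)
        for name in study.measurements.data:
            assert np.array_equal(study.measurements[name],
                                  again.measurements[name])

    def test_noise_sd_recoverable_from_baseline_residuals(self, study):
        """The SD of baseline-phase residuals matches the configured noise
        within 20% at >= 10 baseline samples (pooled across signals)."""
        base = study.measurements.time <= study.protocol.t_occlude
        assert base.sum() >= 10
        ratios = []
        for name, sd in study.noise_sd.items():
            if sd <= 0:
                continue
            resid = (study.measurements[name] - study.clean[name])[base]
            ratios.append(np.std(resid) / sd)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_recovery_truth_returns_to_baseline(self, study):
        s = study.clean
        assert s["NTP_EPP"][-1] == pytest.approx(s["NTP_EPP"][0], abs=0.01)

    def test_nonrecovery_truth_shifts_pi_fraction(self):
        """With 40% cell death the post-insult Pi/EPP stays elevated by the
        dead-fraction offset."""
        d_f = 0.40
        traces, prot = make_insult_protocol(seed=4, jitter_sd=0.0,
                                            insult_min=10.0,
                                            recovery_min=25.0,
                                            scenario="cell_death",
                                            post_d_f=d_f)
        study = make_pseudo_measurements(ParameterSet(), traces, prot,
                                         noise_sd={}, seed=4)
        s = study.clean
        expected = (1 - d_f) * s["Pi_EPP"][0] + d_f
        assert s["Pi_EPP"][-1] == pytest.approx(expected, abs=0.03)
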