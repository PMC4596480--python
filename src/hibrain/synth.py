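"""Synthetic insult studies: input protocols and model-based noisy
pseudo-measurements.

No experimental piglet recordings are distributed with this package, so
screening, fitting and the scenario comparison are exercised against
synthetic studies: a generator :class:`~hibrain.parameters.ParameterSet`
(the truth), input traces emulating the experimental insult protocol
(10 min of baseline, desaturation plus bilateral carotid occlusion with
one-minute ramps, release, recovery), and model outputs sampled at the
experimental 1-minute acquisition interval with seeded Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .model import Model
from .observables import SignalSet
from .parameters import ParameterSet
from .simulate import InputTraces, Protocol, SimulationResult, simulate

__all__ = ["SyntheticStudy", "make_insult_protocol",
           "make_pseudo_measurements", "default_noise_sd"]

#: experimental acquisition interval (s)
SAMPLE_INTERVAL = 60.0


@dataclass
class SyntheticStudy:
    """A complete reproducible pseudo-experiment."""
    truth: ParameterSet
    traces: InputTraces
    protocol: Protocol
    noise_sd: dict[str, float]
    seed: int
    measurements: SignalSet
    clean: SignalSet = field(repr=False, default=None)
    simulation: SimulationResult = field(repr=False, default=None)


def make_insult_protocol(baseline_min: float = 10.0,
                         insult_min: float = 20.0,
                         recovery_min: float = 30.0,
                         sao2_floor: float = 0.30,
                         sao2_n: float = 0.96,
                         pa_n: float = 50.0,
                         jitter_sd: float = 0.01,
                         jitter_rho: float = 0.9,
                         desat_tau_s: float = 120.0,
                         scenario: str = "none",
                         seed: int = 0,
                         **protocol_kw) -> tuple[InputTraces, Protocol]:
    """Fig-4-style driving inputs plus the matching protocol.

    SaO2 descends from normal towards the floor with an exponential
    approach (time constant ``desat_tau_s``) during the insult and
    recovers the same way; Pa stays near-constant.  Both carry first-order
    autocorrelated jitter (lag-1 correlation ``jitter_rho``, marginal SD
    ``jitter_sd`` as a fraction of the normal value); the occlusion
    control ramps 0 -> 1 over a minute at insult start and back at
    release.  Identical seeds give identical traces.
    """
    if min(baseline_min, insult_min, recovery_min) <= 0:
        raise ConfigError("phase durations must be strictly positive")
    if not 0.0 < sao2_floor <= sao2_n:
        raise ConfigError("sao2_floor must lie in (0, normal SaO2]")
    protocol = Protocol(baseline_s=baseline_min * 60.0,
                        insult_s=insult_min * 60.0,
                        recovery_s=recovery_min * 60.0,
                        scenario=scenario, **protocol_kw)
    t = np.arange(0.0, protocol.duration + SAMPLE_INTERVAL, SAMPLE_INTERVAL)
    rng = np.random.default_rng(seed)

    sao2 = np.full_like(t, sao2_n)
    t_on, t_off = protocol.t_occlude, protocol.t_release
    during = (t >= t_on) & (t < t_off)
    sao2[during] = sao2_floor + (sao2_n - sao2_floor) * np.exp(
        -(t[during] - t_on) / desat_tau_s)
    after = t >= t_off
    sao2_at_off = sao2_floor + (sao2_n - sao2_floor) * float(
        np.exp(-(t_off - t_on) / desat_tau_s))
    sao2[after] = sao2_n - (sao2_n - sao2_at_off) * np.exp(
        -(t[after] - t_off) / desat_tau_s)

    def ar1(n: int, sd: float) -> np.ndarray:
        if sd <= 0:
            return np.zeros(n)
        innov = rng.normal(0.0, sd * np.sqrt(1 - jitter_rho ** 2), n)
        x = np.empty(n)
        x[0] = rng.normal(0.0, sd)
        for i in range(1, n):
            x[i] = jitter_rho * x[i - 1] + innov[i]
        return x

    sao2 = np.clip(sao2 * (1.0 + ar1(len(t), jitter_sd)), 0.0, 1.0)
    pa = pa_n * (1.0 + ar1(len(t), jitter_sd))
    traces = InputTraces(time=t, SaO2=sao2, Pa=pa)
    return traces, protocol


def default_noise_sd(clean: SignalSet,
                     fraction: float = 0.05) -> dict[str, float]:
    """Per-signal noise SD as a fraction of the insult-phase dynamic range
    (no measurement-noise model is available for the original recordings)."""
    out = {}
    for name in clean.data:
        rng_ = float(np.ptp(clean.data[name]))
        out[name] = fraction * rng_ if rng_ > 0 else fraction
    return out


def make_pseudo_measurements(truth: ParameterSet,
                             traces: InputTraces,
                             protocol: Protocol,
                             noise_sd: dict[str, float] | None = None,
                             noise_fraction: float = 0.05,
                             seed: int = 0,
                             rtol: float = 1e-7) -> SyntheticStudy:
    """Simulate at the truth parameters, sample at the 1-minute acquisition
    grid and add seeded Gaussian noise per signal."""
    model = Model(truth)
    result = simulate(model, traces, protocol,
                      output_dt=SAMPLE_INTERVAL / 2.0, rtol=rtol)
    t_sample = np.arange(traces.t_span[0],
                         traces.t_span[1] + SAMPLE_INTERVAL / 2.0,
                         SAMPLE_INTERVAL)
    clean = result.signals.interpolate_to(t_sample)
    if noise_sd is None:
        noise_sd = default_noise_sd(clean, fraction=noise_fraction)
    rng = np.random.default_rng(seed + 104729)
    noisy = {name: clean.data[name]
             + rng.normal(0.0, noise_sd.get(name, 0.0), len(t_sample))
             for name in clean.data}
    measurements = SignalSet(time=t_sample, data=noisy)
    return SyntheticStudy(truth=truth, traces=traces, protocol=protocol,
                          noise_sd=dict(noise_sd), seed=seed,
                          measurements=measurements, clean=clean,
                          simulation=result)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, str]:
    """One-command fixture emission: inputs, measurements and a truth
    manifest in the same delimited formats the simulator and fitting
    modules consume."""
    from . import io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": str(outdir / "inputs.csv"),
        "measurements": str(outdir / "measurements.csv"),
        "truth": str(outdir / "truth.yaml"),
        "noise": str(outdir / "noise_sd.yaml"),
    }
    io.write_traces(study.traces, paths["traces"])
    io.write_signals(study.measurements, paths["measurements"])
    study.truth.to_yaml(paths["truth"])
    import yaml
    with open(paths["noise"], "w") as fh:
        yaml.safe_dump({"seed": study.seed,
                        "scenario": study.protocol.scenario,
                        "noise_sd": {k: float(v)
                                     for k, v in study.noise_sd.items()}}, fh)
    return paths
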