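"""Steady-state solving, time-course integration and the insult protocol.

The model is driven by measured (or synthetic) time series of arterial
oxygen saturation and arterial pressure, plus a carotid-occlusion control
``k_occ`` which either comes from an input trace or is generated by a
:class:`Protocol` (baseline, one-minute occlusion ramp on, insult, one-minute
release ramp, recovery).  A protocol can additionally apply a post-insult
state change -- persistent occlusion, mitochondrial uncoupling, or the death
of a cell fraction -- which is how non-recovery is represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import ConfigError, ConvergenceError
from .model import Model, Inputs, STATE_NAMES
from .observables import SignalSet, signals_from_trajectory
from .parameters import ParameterSet

__all__ = ["InputTraces", "Protocol", "SCENARIOS", "apply_protocol",
           "solve_steady_state", "simulate", "SimulationResult"]

SCENARIOS = ("none", "occlusion", "uncoupling", "cell_death",
             "occlusion_death", "all")

#: overrides activated by each non-recovery scenario
_SCENARIO_OVERRIDES = {
    "none": (),
    "occlusion": ("k_occ",),
    "uncoupling": ("k_unc",),
    "cell_death": ("d_f",),
    "occlusion_death": ("k_occ", "d_f"),
    "all": ("k_occ", "k_unc", "d_f"),
}


@dataclass
class InputTraces:
    """Piecewise-linear driving signals on a strictly increasing time grid."""
    time: np.ndarray
    SaO2: np.ndarray
    Pa: np.ndarray
    k_occ: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.SaO2 = np.asarray(self.SaO2, dtype=float)
        self.Pa = np.asarray(self.Pa, dtype=float)
        if self.k_occ is not None:
            self.k_occ = np.asarray(self.k_occ, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ConfigError("input traces need at least two time points")
        if np.any(np.diff(self.time) <= 0):
            raise ConfigError("input trace time must be strictly increasing")
        for name, arr in (("SaO2", self.SaO2), ("Pa", self.Pa),
                          ("k_occ", self.k_occ)):
            if arr is None:
                continue
            if arr.shape != self.time.shape:
                raise ConfigError(f"{name} trace length mismatch")
        if np.any((self.SaO2 < 0) | (self.SaO2 > 1)):
            raise ConfigError("SaO2 must lie in [0, 1]")
        if np.any(self.Pa <= 0):
            raise ConfigError("Pa must be strictly positive")
        if self.k_occ is not None and np.any((self.k_occ < 0) |
                                             (self.k_occ > 1)):
            raise ConfigError("k_occ must lie in [0, 1]")

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def sao2_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.SaO2))

    def pa_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.Pa))

    def k_occ_at(self, t: float) -> float | None:
        if self.k_occ is None:
            return None
        return float(np.interp(t, self.time, self.k_occ))


def _ramp(t: float, t_start: float, duration: float,
          v0: float, v1: float) -> float:
    """Linear ramp from v0 to v1 over [t_start, t_start + duration]."""
    if t <= t_start:
        return v0
    if t >= t_start + duration:
        return v1
    return v0 + (v1 - v0) * (t - t_start) / duration


@dataclass
class Protocol:
    """Insult phase timing and post-insult state-change scenario.

    Occlusion ramps from 0 to 1 over ``occlusion_ramp_s`` at the end of the
    baseline phase and back down over ``release_ramp_s`` after the insult.
    A non-``none`` scenario applies the corresponding post-insult override;
    ``d_f`` and ``k_unc`` transition over ``d_f_ramp_s`` starting at
    ``change_time_s`` (default: end of the release ramp), while a persistent
    ``k_occ`` ramps in during the release so that the occlusion never
    actually releases.
    """
    baseline_s: float = 600.0
    occlusion_ramp_s: float = 60.0
    insult_s: float = 1200.0
    release_ramp_s: float = 60.0
    recovery_s: float = 1800.0
    scenario: str = "none"
    post_k_occ: float = 1.0
    post_k_unc: float = 0.33
    post_d_f: float = 0.45
    change_time_s: float | None = None
    d_f_ramp_s: float = 60.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"expected one of {SCENARIOS}")
        for name in ("baseline_s", "occlusion_ramp_s", "insult_s",
                     "release_ramp_s", "recovery_s", "d_f_ramp_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 0.0 <= self.post_k_occ <= 1.0:
            raise ConfigError("post_k_occ must lie in [0, 1]")
        if self.post_k_unc <= 0:
            raise ConfigError("post_k_unc must be strictly positive")
        if not 0.0 <= self.post_d_f <= ParameterSet.D_F_MAX:
            raise ConfigError("post_d_f must lie in "
                              f"[0, {ParameterSet.D_F_MAX}]")

    @property
    def t_occlude(self) -> float:
        return self.baseline_s

    @property
    def t_release(self) -> float:
        return self.baseline_s + self.occlusion_ramp_s + self.insult_s

    @property
    def t_change(self) -> float:
        if self.change_time_s is not None:
            return self.change_time_s
        return self.t_release + self.release_ramp_s

    @property
    def duration(self) -> float:
        return self.t_release + self.release_ramp_s + self.recovery_s

    def base_k_occ(self, t: float) -> float:
        """The occlude/hold/release ramp without scenario overrides."""
        up = _ramp(t, self.t_occlude, self.occlusion_ramp_s, 0.0, 1.0)
        if t < self.t_release:
            return up
        return _ramp(t, self.t_release, self.release_ramp_s, 1.0, 0.0)


def apply_protocol(protocol: Protocol, t: float, params: ParameterSet,
                   k_occ_trace: float | None = None) -> dict[str, float]:
    """Effective control parameters at time ``t``.

    Returns a dict with ``k_occ``, ``k_unc`` and ``d_f``.  The base
    occlusion comes from the trace when supplied, otherwise from the
    protocol ramps; scenario overrides are then applied.
    """
    base = k_occ_trace if k_occ_trace is not None \
        else protocol.base_k_occ(t)
    k_occ, k_unc, d_f = base, params.k_unc, params.d_f

    active = _SCENARIO_OVERRIDES[protocol.scenario]
    if "k_occ" in active:
        # persistent occlusion: ramp in over the release so flow never
        # actually recovers
        override = _ramp(t, protocol.t_release, protocol.release_ramp_s,
                         0.0, protocol.post_k_occ)
        k_occ = max(k_occ, override)
    if "k_unc" in active:
        k_unc = _ramp(t, protocol.t_change, protocol.d_f_ramp_s,
                      params.k_unc, protocol.post_k_unc)
    if "d_f" in active:
        d_f = _ramp(t, protocol.t_change, protocol.d_f_ramp_s,
                    params.d_f, protocol.post_d_f)
    return {"k_occ": k_occ, "k_unc": k_unc, "d_f": d_f}


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

_I = {name: i for i, name in enumerate(STATE_NAMES)}
#: rows whose derivatives are exact combinations of others (conserved pools);
#: replaced by pool constraints in the Newton solve so the Jacobian is regular
_CONSERVED_ROWS = ("NAD_cyt", "NAD_mit", "ADP", "Cr", "Pi")


def _pool_constraints(y: np.ndarray, y_ref: np.ndarray) -> dict[str, float]:
    def pool(v, *names):
        return sum(v[_I[n]] for n in names)
    return {
        "NAD_cyt": pool(y, "NAD_cyt", "NADH_cyt")
                   - pool(y_ref, "NAD_cyt", "NADH_cyt"),
        "NAD_mit": pool(y, "NAD_mit", "NADH_mit")
                   - pool(y_ref, "NAD_mit", "NADH_mit"),
        "ADP": pool(y, "ATP", "ADP") - pool(y_ref, "ATP", "ADP"),
        "Cr": pool(y, "PCr", "Cr") - pool(y_ref, "PCr", "Cr"),
        "Pi": (y[_I["PCr"]] + y[_I["Pi"]] + 2 * y[_I["ATP"]])
              - (y_ref[_I["PCr"]] + y_ref[_I["Pi"]] + 2 * y_ref[_I["ATP"]]),
    }


def solve_steady_state(model: Model, inputs: Inputs | None = None,
                       tol: float = 1e-6, t_settle: float = 4000.0,
                       max_rounds: int = 3) -> np.ndarray:
    """Steady state of the model under constant inputs.

    Alternates settling integration from the calibrated baseline with a
    trust-region least-squares polish in which the five exactly conserved
    pools (cytosolic and mitochondrial NAD, adenine, creatine and
    exchangeable phosphate) replace their redundant derivative rows --
    the conservation laws make the raw Jacobian singular.

    ``tol`` bounds the maximum residual drift rate relative to each
    variable's normal value (1/s); the default 1e-6 corresponds to a
    worst-case drift below 0.4% of a variable's normal value per hour,
    which is the practical limit of finite-difference polishing for a
    system whose timescales span from milliseconds (CCO redox) to days
    (the bulk cytosolic NAD pool).  Raises
    :class:`~hibrain.errors.ConvergenceError` naming the worst-residual
    state variable on failure.
    """
    u = inputs or model.baseline_inputs
    scale = np.maximum(np.abs(model.y0), 1e-3)

    def residual(z: np.ndarray) -> np.ndarray:
        y = z * scale
        f = model.rhs(0.0, y, u) / scale
        cons = _pool_constraints(y, model.y0)
        for name, val in cons.items():
            f[_I[name]] = val / scale[_I[name]]
        return f

    y_guess = model.y0
    settle = t_settle
    for _ in range(max_rounds):
        sol = solve_ivp(lambda t, y: model.rhs(t, y, u),
                        (0.0, settle), y_guess, method="LSODA",
                        rtol=1e-9, atol=scale * 1e-10)
        if not sol.success:
            raise ConvergenceError(
                f"settling integration failed: {sol.message}")
        y_guess = sol.y[:, -1]
        res = least_squares(residual, y_guess / scale, method="trf",
                            xtol=3e-16, ftol=3e-16, gtol=3e-16,
                            x_scale="jac", max_nfev=2000)
        y_ss = res.x * scale
        resid = np.abs(model.rhs(0.0, y_ss, u)) / scale
        if np.max(resid) <= tol:
            return y_ss
        y_guess = y_ss
        settle *= 30.0   # escalate for slowly-relaxing redox pools
    worst = STATE_NAMES[int(np.argmax(resid))]
    raise ConvergenceError(
        "steady state did not converge; worst residual on "
        f"{worst!r} ({np.max(resid):.2e})")


# ---------------------------------------------------------------------------
# Time-course simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    time: np.ndarray
    states: np.ndarray            # (n_states, n_times)
    signals: SignalSet
    inputs_at: "callable" = field(repr=False, default=None)


def simulate(model: Model, traces: InputTraces,
             protocol: Protocol | None = None,
             output_dt: float = 10.0,
             rtol: float = 1e-7,
             max_step: float = 15.0,
             y0: np.ndarray | None = None) -> SimulationResult:
    """Integrate the model under driving traces and map to observables.

    The initial state defaults to the calibrated baseline steady state.
    Delta-signals (dHbO2, dHHb, dOxCCO) are zeroed at the first output
    sample.  Integration uses a stiff solver with per-variable absolute
    tolerances scaled by normal values.
    """
    params = model.params
    t0, t1 = traces.t_span

    def inputs_at(t: float) -> Inputs:
        k_trace = traces.k_occ_at(t)
        if protocol is not None:
            eff = apply_protocol(protocol, t, params, k_occ_trace=k_trace)
        else:
            eff = {"k_occ": k_trace if k_trace is not None else params.k_occ,
                   "k_unc": params.k_unc, "d_f": params.d_f}
        return Inputs(SaO2=traces.sao2_at(t), Pa=traces.pa_at(t), **eff)

    y_init = model.y0 if y0 is None else np.asarray(y0, dtype=float)
    scale = np.maximum(np.abs(model.y0), 1e-3)
    t_eval = np.arange(t0, t1 + 0.5 * output_dt, output_dt)
    t_eval = t_eval[t_eval <= t1]

    sol = solve_ivp(lambda t, y: model.rhs(t, y, inputs_at(t)),
                    (t0, t1), y_init, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=scale * rtol * 1e-2, max_step=max_step)
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else t0
        raise ConvergenceError(
            f"integration failed at t={t_fail:.1f} s: {sol.message}; "
            f"last state={dict(zip(STATE_NAMES, sol.y[:, -1]))}"
            if len(sol.t) else f"integration failed: {sol.message}")

    signals = signals_from_trajectory(model, sol.t, sol.y, inputs_at)
    for name in ("dHbO2", "dHHb", "dOxCCO"):
        signals.data[name] = signals.data[name] - signals.data[name][0]
    return SimulationResult(time=sol.t, states=sol.y, signals=signals,
                            inputs_at=inputs_at)
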