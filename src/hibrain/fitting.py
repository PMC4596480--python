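"""Ensemble particle-swarm fitting of screened parameters to measured
(or pseudo-measured) signals, and the non-recovery scenario comparison.

Optimisation is bound-constrained particle-swarm (global-best topology,
constriction coefficients) minimising a weighted sum of per-signal RMS
errors, each signal divided by its measured standard deviation so that
signals with different units contribute comparably.  Parameters are fitted
in groups ordered by the signals they influence (haemoglobin, pH, CCO,
phosphates), later groups seeing earlier groups' fitted values; repeated
runs with different seeds form an ensemble whose spread and pairwise
correlations expose the non-identifiability typical of sloppy models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, ConvergenceError, HibrainError
from .model import Model
from .observables import SignalSet
from .parameters import ParameterSet, default_ranges
from .sensitivity import rms_objective
from .simulate import InputTraces, Protocol, SCENARIOS, simulate

__all__ = ["SwarmConfig", "FitTask", "FitResult", "pswarm_minimise",
           "make_signal_objective", "grouped_fit", "scenario_fit",
           "DEFAULT_GROUPS", "ensemble_fit", "nadir_window"]

def nadir_window(measured: SignalSet,
                 signal: str = "NTP_EPP") -> tuple[float, float]:
    """Time window from the start of the measurements to the nadir of the
    insult, defined as the time of the minimum measured NTP/EPP (the
    reference signal is configurable).  Used to fit only the pre-change
    portion of a non-recovering dataset."""
    if signal not in measured.data:
        raise ConfigError(f"signal {signal!r} missing from measurements")
    i = int(np.argmin(measured.data[signal]))
    return float(measured.time[0]), float(measured.time[i])


#: Fit groups in the canonical order: parameters optimised against the
#: signals they influence, reducing the dimensionality of each search.
DEFAULT_GROUPS: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("Hbtot_n", "r_0", "V_blood_n"), ("dHbO2", "dHHb")),
    (("pH_o_n",), ("pH",)),
    (("CCO_tis", "CuA_frac_n"), ("dOxCCO",)),
    (("ATP_n", "PCr_n", "PCr_Pi_ratio_n"),
     ("NTP_EPP", "PCr_EPP", "Pi_EPP")),
)


@dataclass
class SwarmConfig:
    n_particles: int = 40
    n_iter: int = 200
    w: float = 0.729          # inertia (constriction form)
    c1: float = 1.49445       # cognitive acceleration
    c2: float = 1.49445       # social acceleration
    tol_rel: float = 1e-6     # relative objective change declaring convergence
    patience: int = 20        # iterations below tol_rel before stopping


@dataclass
class FitTask:
    """One bound-constrained fit: parameter subset, target signals and an
    optional time window ('up to the nadir of the insult' truncation)."""
    param_names: list[str]
    bounds: dict[str, tuple[float, float]]
    signals: list[str]
    t_window: tuple[float, float] | None = None
    scenario: str = "none"
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    seed: int = 0

    def __post_init__(self):
        if not self.signals:
            raise ConfigError("fit task needs at least one target signal")
        missing = [p for p in self.param_names if p not in self.bounds]
        if missing:
            raise ConfigError(f"no bounds for parameter(s) {missing}")


@dataclass
class FitResult:
    param_names: list[str]
    x_best: np.ndarray
    objective: float
    per_signal_rms: dict[str, float]
    seed: int
    n_iter: int
    converged: bool
    history: np.ndarray                 # best objective per iteration
    ensemble: "list[FitResult] | None" = None

    def as_dict(self) -> dict:
        out = {
            "parameters": dict(zip(self.param_names,
                                   map(float, self.x_best))),
            "objective": float(self.objective),
            "per_signal_rms": {k: float(v)
                               for k, v in self.per_signal_rms.items()},
            "seed": int(self.seed),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }
        if self.ensemble:
            mat = np.array([r.x_best for r in self.ensemble])
            out["ensemble"] = {
                "n": len(self.ensemble),
                "mean": dict(zip(self.param_names, map(float, mat.mean(0)))),
                "sd": dict(zip(self.param_names,
                               map(float, mat.std(0, ddof=1)
                                   if len(mat) > 1 else np.zeros(mat.shape[1])))),
                "correlations": np.corrcoef(mat.T).tolist()
                                if len(mat) > 2 and mat.shape[1] > 1 else None,
                "objectives": [float(r.objective) for r in self.ensemble],
            }
        return out


def pswarm_minimise(objective: Callable[[np.ndarray], float],
                    bounds: Sequence[tuple[float, float]],
                    seed: int = 0,
                    swarm: SwarmConfig | None = None) -> FitResult:
    """Bound-constrained global-best particle-swarm minimisation.

    Positions are clamped to the bounds (velocity zeroed at the wall);
    identical seeds give identical results.  Non-finite objective values
    are treated as infeasible; if no particle ever finds a finite value
    the search fails with diagnostics.
    """
    cfg = swarm or SwarmConfig()
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ConfigError("each bound must satisfy lo < hi")
    dim = len(bounds)
    rng = np.random.default_rng(seed)

    def f(x: np.ndarray) -> float:
        try:
            v = float(objective(x))
        except (HibrainError, FloatingPointError, OverflowError):
            return math.inf
        return v if math.isfinite(v) else math.inf

    x = lo + rng.random((cfg.n_particles, dim)) * (hi - lo)
    v = (rng.random((cfg.n_particles, dim)) - 0.5) * (hi - lo) * 0.2
    pbest = x.copy()
    pval = np.array([f(xi) for xi in x])
    g = int(np.argmin(pval))
    gval, gx = pval[g], pbest[g].copy()
    history = [gval]
    stall = 0
    it = 0
    for it in range(1, cfg.n_iter + 1):
        r1 = rng.random((cfg.n_particles, dim))
        r2 = rng.random((cfg.n_particles, dim))
        v = (cfg.w * v + cfg.c1 * r1 * (pbest - x)
             + cfg.c2 * r2 * (gx[None, :] - x))
        x = x + v
        under, over = x < lo, x > hi
        x = np.clip(x, lo, hi)
        v[under | over] = 0.0
        vals = np.array([f(xi) for xi in x])
        better = vals < pval
        pbest[better] = x[better]
        pval[better] = vals[better]
        g = int(np.argmin(pval))
        prev = gval
        if pval[g] < gval:
            gval, gx = pval[g], pbest[g].copy()
        history.append(gval)
        if math.isfinite(gval) and math.isfinite(prev):
            rel = abs(prev - gval) / max(abs(prev), 1e-12)
            stall = stall + 1 if rel < cfg.tol_rel else 0
            if stall >= cfg.patience:
                break
    if not math.isfinite(gval):
        raise ConvergenceError(
            "particle swarm found no finite objective value in "
            f"{cfg.n_particles}x{it} evaluations over bounds {list(bounds)}")
    return FitResult(param_names=[f"x{i}" for i in range(dim)],
                     x_best=gx, objective=float(gval),
                     per_signal_rms={}, seed=seed, n_iter=it,
                     converged=stall >= cfg.patience,
                     history=np.asarray(history))


# ---------------------------------------------------------------------------
# Signal-space objectives
# ---------------------------------------------------------------------------

def make_signal_objective(base_params: ParameterSet,
                          traces: InputTraces,
                          protocol: Protocol,
                          measured: SignalSet,
                          param_names: Sequence[str],
                          signals: Sequence[str],
                          t_window: tuple[float, float] | None = None,
                          fixed: dict[str, float] | None = None,
                          output_dt: float = 60.0,
                          rtol: float = 1e-5
                          ) -> Callable[[np.ndarray], float]:
    """Objective: simulate at the candidate parameters and sum per-signal
    RMS errors, each divided by the measured signal's standard deviation
    (equal-weight combination across unit systems)."""
    weights = {}
    for s in signals:
        sd = float(np.std(measured.data[s]))
        weights[s] = 1.0 / sd if sd > 0 else 1.0

    def objective(x: np.ndarray) -> float:
        overrides = dict(fixed or {})
        overrides.update({n: float(v) for n, v in zip(param_names, x)})
        params = base_params.replace(**overrides)
        model = Model(params)
        result = simulate(model, traces, protocol,
                          output_dt=output_dt, rtol=rtol, max_step=30.0)
        total = 0.0
        for s in signals:
            total += weights[s] * rms_objective(result.signals, measured, s,
                                                t_window=t_window)
        return total

    return objective


def _finalise(fit: FitResult, names: Sequence[str], objective,
              measured: SignalSet, signals: Sequence[str],
              base_params, traces, protocol, fixed,
              t_window, output_dt, rtol) -> FitResult:
    """Recompute per-signal RMS at the best point (the reported objective
    is exactly reproducible by re-simulation)."""
    overrides = dict(fixed or {})
    overrides.update({n: float(v) for n, v in zip(names, fit.x_best)})
    model = Model(base_params.replace(**overrides))
    result = simulate(model, traces, protocol, output_dt=output_dt,
                      rtol=rtol, max_step=30.0)
    fit.per_signal_rms = {
        s: rms_objective(result.signals, measured, s, t_window=t_window)
        for s in signals}
    fit.param_names = list(names)
    return fit


def ensemble_fit(task: FitTask, objective, n_repeats: int = 10,
                 **finalise_kw) -> FitResult:
    """Repeat a swarm fit with distinct seeds; the best run is returned
    with the full ensemble attached (per-parameter mean +/- SD and
    pairwise correlations via ``FitResult.as_dict``)."""
    runs = []
    for i in range(n_repeats):
        fit = pswarm_minimise(objective,
                              [task.bounds[p] for p in task.param_names],
                              seed=task.seed + 1000 * i, swarm=task.swarm)
        fit.param_names = list(task.param_names)
        runs.append(fit)
    best = min(runs, key=lambda r: r.objective)
    best.ensemble = runs
    if finalise_kw:
        best = _finalise(best, task.param_names, objective, **finalise_kw)
    return best


# ---------------------------------------------------------------------------
# High-level strategies
# ---------------------------------------------------------------------------

def grouped_fit(base_params: ParameterSet,
                traces: InputTraces,
                protocol: Protocol,
                measured: SignalSet,
                groups: Sequence[tuple[Sequence[str], Sequence[str]]]
                = DEFAULT_GROUPS,
                bounds: dict[str, tuple[float, float]] | None = None,
                t_window: tuple[float, float] | None = None,
                swarm: SwarmConfig | None = None,
                seed: int = 0,
                n_repeats: int = 1,
                output_dt: float = 60.0,
                rtol: float = 1e-5) -> dict[str, FitResult]:
    """Sequential group fits: each group's parameters are optimised against
    the signals they influence, with earlier groups' fitted values fixed
    for later groups.  Returns one FitResult per group keyed by the first
    target signal."""
    bounds = bounds or default_ranges(base_params)
    fixed: dict[str, float] = {}
    out: dict[str, FitResult] = {}
    for gi, (pnames, signals) in enumerate(groups):
        pnames, signals = list(pnames), list(signals)
        task = FitTask(param_names=pnames,
                       bounds={p: bounds[p] for p in pnames},
                       signals=signals, t_window=t_window,
                       swarm=swarm or SwarmConfig(), seed=seed + 17 * gi)
        objective = make_signal_objective(
            base_params, traces, protocol, measured, pnames, signals,
            t_window=t_window, fixed=fixed, output_dt=output_dt, rtol=rtol)
        if n_repeats > 1:
            fit = ensemble_fit(task, objective, n_repeats=n_repeats,
                               measured=measured, signals=signals,
                               base_params=base_params, traces=traces,
                               protocol=protocol, fixed=dict(fixed),
                               t_window=t_window, output_dt=output_dt,
                               rtol=rtol)
        else:
            fit = pswarm_minimise(objective,
                                  [task.bounds[p] for p in pnames],
                                  seed=task.seed, swarm=task.swarm)
            fit = _finalise(fit, pnames, objective, measured, signals,
                            base_params, traces, protocol, dict(fixed),
                            t_window, output_dt, rtol)
        out[signals[0]] = fit
        fixed.update(dict(zip(pnames, map(float, fit.x_best))))
    return out


#: post-insult control parameter(s) freed per non-recovery scenario,
#: with their search bounds
_SCENARIO_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "none": {},
    "occlusion": {"post_k_occ": (0.0, 1.0)},
    "uncoupling": {"post_k_unc": (0.2, 3.0)},
    "cell_death": {"post_d_f": (0.0, 0.8)},
    "occlusion_death": {"post_k_occ": (0.0, 1.0), "post_d_f": (0.0, 0.8)},
    "all": {"post_k_occ": (0.0, 1.0), "post_k_unc": (0.2, 3.0),
            "post_d_f": (0.0, 0.8)},
}

#: parameters co-fitted with the scenario controls (the CCO and
#: phosphate-signal groups); haemoglobin and pH groups keep their values
SCENARIO_MODEL_PARAMS: tuple[str, ...] = (
    "CCO_tis", "CuA_frac_n", "ATP_n", "PCr_n", "PCr_Pi_ratio_n")
SCENARIO_SIGNALS: tuple[str, ...] = (
    "dOxCCO", "NTP_EPP", "PCr_EPP", "Pi_EPP")


def scenario_fit(base_params: ParameterSet,
                 traces: InputTraces,
                 protocol: Protocol,
                 measured: SignalSet,
                 scenario: str,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 model_params: Sequence[str] = SCENARIO_MODEL_PARAMS,
                 signals: Sequence[str] = SCENARIO_SIGNALS,
                 swarm: SwarmConfig | None = None,
                 seed: int = 0,
                 output_dt: float = 60.0,
                 rtol: float = 1e-5) -> FitResult:
    """Jointly optimise a non-recovery scenario's post-insult control
    parameter(s) with the CCO/phosphate-group model parameters against the
    whole signal time course.  Other parameters remain at their pre-insult
    values."""
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    bounds = bounds or default_ranges(base_params)
    scen_bounds = _SCENARIO_PARAMS[scenario]
    names = list(model_params) + list(scen_bounds)
    all_bounds = [bounds[p] for p in model_params] \
        + [scen_bounds[p] for p in scen_bounds]

    weights = {}
    for s in signals:
        sd = float(np.std(measured.data[s]))
        weights[s] = 1.0 / sd if sd > 0 else 1.0

    n_model = len(list(model_params))

    def objective(x: np.ndarray) -> float:
        params = base_params.replace(
            **{n: float(v) for n, v in zip(model_params, x[:n_model])})
        prot_kw = {f.name: getattr(protocol, f.name)
                   for f in protocol.__dataclass_fields__.values()}
        prot_kw["scenario"] = scenario
        for n, v in zip(list(scen_bounds), x[n_model:]):
            prot_kw[n] = float(v)
        prot = Protocol(**prot_kw)
        model = Model(params)
        result = simulate(model, traces, prot, output_dt=output_dt,
                          rtol=rtol, max_step=30.0)
        return sum(weights[s] * rms_objective(result.signals, measured, s)
                   for s in signals)

    fit = pswarm_minimise(objective, all_bounds, seed=seed,
                          swarm=swarm or SwarmConfig())
    fit.param_names = names
    # recompute per-signal RMS at the optimum (reproducibility contract)
    x = fit.x_best
    params = base_params.replace(
        **{n: float(v) for n, v in zip(model_params, x[:n_model])})
    prot_kw = {f.name: getattr(protocol, f.name)
               for f in protocol.__dataclass_fields__.values()}
    prot_kw["scenario"] = scenario
    for n, v in zip(list(scen_bounds), x[n_model:]):
        prot_kw[n] = float(v)
    result = simulate(Model(params), traces, Protocol(**prot_kw),
                      output_dt=output_dt, rtol=rtol, max_step=30.0)
    fit.per_signal_rms = {s: rms_objective(result.signals, measured, s)
                          for s in signals}
    return fit
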