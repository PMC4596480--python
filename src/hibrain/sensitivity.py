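"""Morris elementary-effects screening against per-signal RMS outputs.

The screening design subdivides each parameter's range into a regular grid
of levels and navigates ``r`` random trajectories through the grid: each
trajectory starts at a random grid point and changes every parameter
exactly once, in random order, by a fixed jump of half the grid span.
Elementary effects are computed on range-normalised parameters so they are
comparable across parameters; their mean absolute value mu* measures
influence and their standard deviation sigma non-linearity/interaction.
Per output signal, mu* is normalised by its maximum and parameters with a
dataset-averaged normalised mu* at or above a threshold (default 0.5) are
selected for optimisation, grouped by the signals they influence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .observables import SignalSet

__all__ = ["MorrisDesign", "MorrisResult", "build_design",
           "elementary_effects", "rms_objective", "screen"]


@dataclass
class MorrisDesign:
    """An r-trajectory one-at-a-time screening design.

    ``points`` has shape (r*(k+1), k) in physical units; ``changed[i]``
    gives the index of the parameter changed between point i-1 and point i
    (-1 for each trajectory's base point).
    """
    names: list[str]
    ranges: dict[str, tuple[float, float]]
    r: int
    levels: int
    seed: int
    points: np.ndarray
    changed: np.ndarray

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def build_design(ranges: dict[str, tuple[float, float]], r: int,
                 levels: int = 4, seed: int = 0) -> MorrisDesign:
    """Build a reproducible Morris trajectory design.

    Base points are drawn from the lower part of the level grid and each
    step jumps by delta = levels/(2(levels-1)) in unit space, the standard
    choice keeping all points on the grid.
    """
    if r < 1:
        raise ConfigError("need at least one trajectory")
    if levels < 2 or levels % 2:
        raise ConfigError("levels must be an even integer >= 2")
    names = list(ranges)
    k = len(names)
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    if np.any(hi <= lo):
        bad = [n for n in names if ranges[n][1] <= ranges[n][0]]
        raise ConfigError(f"degenerate range(s) for {bad}")

    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))
    base_levels = np.arange(levels // 2) / (levels - 1)  # grid points < 1-delta

    points = np.empty((r * (k + 1), k))
    changed = np.empty(r * (k + 1), dtype=int)
    row = 0
    for _ in range(r):
        x = rng.choice(base_levels, size=k)
        direction = np.ones(k)  # from the lower half-grid every jump is +delta
        order = rng.permutation(k)
        points[row] = x
        changed[row] = -1
        row += 1
        for j in order:
            x = x.copy()
            x[j] += direction[j] * delta
            points[row] = x
            changed[row] = j
            row += 1
    points = lo + points * (hi - lo)
    return MorrisDesign(names=names, ranges=dict(ranges), r=r, levels=levels,
                        seed=seed, points=points, changed=changed)


@dataclass
class MorrisResult:
    """mu*/sigma per (parameter, output), with per-output normalisation."""
    names: list[str]
    outputs: list[str]
    mu_star: pd.DataFrame          # parameter x output
    sigma: pd.DataFrame
    counts: pd.DataFrame           # valid elementary effects per cell
    n_failures: int = 0

    @property
    def mu_star_normalised(self) -> pd.DataFrame:
        norm = self.mu_star.max(axis=0).replace(0.0, np.nan)
        return self.mu_star / norm

    def report(self, threshold: float = 0.5) -> pd.DataFrame:
        """Long-format screening report: parameter x output with mu*, sigma,
        normalised mu* and the selection flag."""
        rows = []
        norm = self.mu_star_normalised
        for pname in self.names:
            for out in self.outputs:
                rows.append({
                    "parameter": pname, "output": out,
                    "mu_star": self.mu_star.loc[pname, out],
                    "sigma": self.sigma.loc[pname, out],
                    "mu_star_norm": norm.loc[pname, out],
                    "selected": bool(norm.loc[pname, out] >= threshold),
                })
        return pd.DataFrame(rows)


def elementary_effects(design: MorrisDesign,
                       outputs: np.ndarray | dict[str, np.ndarray]
                       ) -> MorrisResult:
    """Aggregate elementary effects from model outputs at the design points.

    ``outputs`` maps output names to arrays of length ``design.n_points``
    (a bare array is treated as a single unnamed output).  Non-finite
    output values mark failed evaluations; every step touching a failed
    point is excluded.  A parameter whose every effect failed is reported
    as NaN (missing), not zero.
    """
    if isinstance(outputs, np.ndarray):
        outputs = {"output": outputs}
    k, names = design.k, design.names
    lo = np.array([design.ranges[n][0] for n in names])
    hi = np.array([design.ranges[n][1] for n in names])
    span = hi - lo

    out_names = list(outputs)
    mu = pd.DataFrame(index=names, columns=out_names, dtype=float)
    sg = pd.DataFrame(index=names, columns=out_names, dtype=float)
    ct = pd.DataFrame(0, index=names, columns=out_names, dtype=int)
    n_fail = 0

    for oname in out_names:
        vals = np.asarray(outputs[oname], dtype=float)
        if vals.shape != (design.n_points,):
            raise ConfigError(
                f"output {oname!r} must have one value per design point")
        n_fail = int(np.sum(~np.isfinite(vals)))
        effects: dict[int, list[float]] = {j: [] for j in range(k)}
        for i in range(design.n_points):
            j = design.changed[i]
            if j < 0:
                continue
            y1, y0 = vals[i], vals[i - 1]
            if not (math.isfinite(y1) and math.isfinite(y0)):
                continue
            dx = (design.points[i, j] - design.points[i - 1, j]) / span[j]
            effects[j].append((y1 - y0) / dx)
        for j, name in enumerate(names):
            ee = np.asarray(effects[j])
            if len(ee) == 0:
                mu.loc[name, oname] = np.nan
                sg.loc[name, oname] = np.nan
            else:
                mu.loc[name, oname] = np.mean(np.abs(ee))
                sg.loc[name, oname] = np.std(ee, ddof=1) if len(ee) > 1 else 0.0
            ct.loc[name, oname] = len(ee)
    return MorrisResult(names=names, outputs=out_names, mu_star=mu,
                        sigma=sg, counts=ct, n_failures=n_fail)


def rms_objective(modelled: SignalSet, measured: SignalSet, signal: str,
                  t_window: tuple[float, float] | None = None) -> float:
    """Root-mean-square difference between a measured signal and its
    modelled equivalent, with the modelled signal linearly interpolated
    onto the measurement times (optionally restricted to a time window)."""
    if signal not in measured.data or signal not in modelled.data:
        raise ConfigError(f"signal {signal!r} missing from input sets")
    t = measured.time
    mask = np.ones_like(t, dtype=bool)
    if t_window is not None:
        mask = (t >= t_window[0]) & (t <= t_window[1])
    t_lo = max(t.min(), modelled.time.min())
    t_hi = min(t.max(), modelled.time.max())
    mask &= (t >= t_lo) & (t <= t_hi)
    if not np.any(mask):
        raise ConfigError("empty time overlap between modelled and measured")
    pred = np.interp(t[mask], modelled.time, modelled.data[signal])
    diff = pred - measured.data[signal][mask]
    return float(np.sqrt(np.mean(diff ** 2)))


def screen(results: MorrisResult | list[MorrisResult],
           threshold: float = 0.5) -> dict[str, list[str]]:
    """Select parameters whose dataset-averaged normalised mu* is at or
    above ``threshold`` for at least one output; returns, per output
    signal, the list of selected parameters (the optimisation groups)."""
    if isinstance(results, MorrisResult):
        results = [results]
    if not results:
        raise ConfigError("need at least one screening result")
    avg = sum(r.mu_star_normalised.fillna(0.0) for r in results) / len(results)
    groups: dict[str, list[str]] = {}
    for out in avg.columns:
        sel = [p for p in avg.index if avg.loc[p, out] >= threshold]
        if sel:
            groups[out] = sorted(sel, key=lambda p: -avg.loc[p, out])
    return groups
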