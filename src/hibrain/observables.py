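"""Forward models mapping state trajectories to measured-signal space.

NIRS signals (tissue concentration changes of oxy-/deoxy-haemoglobin and of
oxidised cytochrome c oxidase) and 31P-MRS phosphate ratios are computed
from the model state, including the corrections for a dead-cell fraction
``d_f``: dead tissue holds its CCO fully reduced and all its exchangeable
phosphate as inorganic phosphate, and contributes nothing to oxygen
consumption, while haemoglobin signals (blood-borne) are unaffected.

All delta-signals are referenced to the baseline state, i.e. they start at
exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import Model, _IDX

__all__ = [
    "SignalSet", "SIGNAL_NAMES", "phosphate_ratios", "delta_oxCCO",
    "cmro2_observed", "cytoplasmic_pH", "nirs_haemoglobin",
    "signals_from_trajectory",
]

#: Canonical signal column order for delimited output.
SIGNAL_NAMES: tuple[str, ...] = (
    "dHbO2", "dHHb", "dOxCCO", "NTP_EPP", "PCr_EPP", "Pi_EPP",
    "pH", "CBF", "CMRO2",
)


@dataclass
class SignalSet:
    """Named observable time courses on a common time axis.

    dHbO2/dHHb are tissue haemoglobin concentration changes (uM), dOxCCO the
    oxidised-CCO change (uM), the *_EPP columns dimensionless fractions of
    the exchangeable phosphate pool, pH in pH units, CBF and CMRO2
    normalised to baseline.
    """
    time: np.ndarray
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    @property
    def names(self) -> list[str]:
        return [n for n in SIGNAL_NAMES if n in self.data] + \
            [n for n in self.data if n not in SIGNAL_NAMES]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time}
        cols.update({n: self.data[n] for n in self.names})
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignalSet":
        time = df["time_s"].to_numpy(dtype=float)
        data = {c: df[c].to_numpy(dtype=float)
                for c in df.columns if c != "time_s"}
        return cls(time=time, data=data)

    def interpolate_to(self, time: np.ndarray) -> "SignalSet":
        """Linear resampling of every signal onto a new time grid."""
        data = {n: np.interp(time, self.time, v) for n, v in self.data.items()}
        return SignalSet(time=np.asarray(time, dtype=float), data=data)


# ---------------------------------------------------------------------------
# Point-wise observable corrections
# ---------------------------------------------------------------------------

def phosphate_ratios(ATP: float, PCr: float, Pi: float,
                     d_f: float = 0.0) -> tuple[float, float, float]:
    """31P-MRS fractions of the exchangeable phosphate pool
    (EPP = PCr + Pi + 2 ATP) with dead-cell correction.

    Dead cells hold all their exchangeable phosphate as Pi, so
    ``NTP/EPP = (1-d_f) ATP/EPP``, ``PCr/EPP = (1-d_f) PCr/EPP`` and
    ``Pi/EPP = (1-d_f) Pi/EPP + d_f``.  The identity
    ``2 NTP/EPP + PCr/EPP + Pi/EPP = 1`` holds for every ``d_f``.
    """
    if not 0.0 <= d_f < 1.0:
        raise DomainError(f"d_f={d_f} outside [0, 1)")
    epp = PCr + Pi + 2.0 * ATP
    if epp <= 0:
        raise DomainError(f"EPP={epp} must be strictly positive")
    live = 1.0 - d_f
    return (live * ATP / epp, live * PCr / epp, live * Pi / epp + d_f)


def delta_oxCCO(d_oxcco_live: float, d_f: float, oxCCO_n: float) -> float:
    """Dead-cell-corrected oxidised-CCO change (uM):
    ``(1-d_f) dOxCCO_live - d_f oxCCO_n``, where ``oxCCO_n`` is the
    normally-oxidised CCO amount (the CCO of dead cells sits fully reduced,
    i.e. at ``-oxCCO_n`` relative to baseline oxidation)."""
    if not 0.0 <= d_f < 1.0:
        raise DomainError(f"d_f={d_f} outside [0, 1)")
    return (1.0 - d_f) * d_oxcco_live - d_f * oxCCO_n


def cmro2_observed(cmro2_live: float, d_f: float) -> float:
    """Tissue-level oxygen consumption: only the living fraction consumes."""
    if not 0.0 <= d_f < 1.0:
        raise DomainError(f"d_f={d_f} outside [0, 1)")
    return (1.0 - d_f) * cmro2_live


def cytoplasmic_pH(H_cyt: float) -> float:
    """pH from a cytoplasmic proton concentration in molar."""
    if H_cyt <= 0:
        raise DomainError(f"H_cyt={H_cyt} must be strictly positive")
    return -math.log10(H_cyt)


# ---------------------------------------------------------------------------
# Trajectory-level signals
# ---------------------------------------------------------------------------

def _hb_concentrations(model: Model, r: np.ndarray, S_a: np.ndarray,
                       S_cap: np.ndarray, S_v: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Tissue HbO2 / HHb concentrations (uM) from compartment volumes and
    saturations.  The arterial volume scales with the vessel cross-section
    (r^2); capillary and venous volumes are fixed (no compliance)."""
    p = model.params
    V_a = p.art_frac * p.V_blood_n * (r / p.r_n) ** 2
    V_c = p.cap_frac * p.V_blood_n
    V_v = (1.0 - p.art_frac - p.cap_frac) * p.V_blood_n
    hbo2 = 1e3 * p.Hbtot_n * (V_a * S_a + V_c * S_cap + V_v * S_v)
    hhb = 1e3 * p.Hbtot_n * (V_a * (1 - S_a) + V_c * (1 - S_cap)
                             + V_v * (1 - S_v))
    return hbo2, hhb


def nirs_haemoglobin(model: Model, r: np.ndarray, S_a: np.ndarray,
                     S_cap: np.ndarray, S_v: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-referenced (dHbO2, dHHb) in uM along a trajectory."""
    hbo2, hhb = _hb_concentrations(model, np.asarray(r, dtype=float),
                                   np.asarray(S_a, dtype=float),
                                   np.asarray(S_cap, dtype=float),
                                   np.asarray(S_v, dtype=float))
    hbo2_n, hhb_n = _hb_concentrations(
        model, np.array([model.params.r_n]), np.array([model.params.SaO2_n]),
        np.array([model.S_cap_n]), np.array([model.S_v_n]))
    return hbo2 - hbo2_n[0], hhb - hhb_n[0]


def signals_from_trajectory(model: Model, time: np.ndarray,
                            states: np.ndarray,
                            inputs_at: "callable") -> SignalSet:
    """Map a dense state trajectory to the measured-signal space.

    ``states`` has shape (n_states, n_times); ``inputs_at(t)`` returns the
    effective :class:`~hibrain.model.Inputs` at time t (including any
    post-insult overrides of k_occ / k_unc / d_f).
    """
    p = model.params
    n = len(time)
    cols = {name: np.empty(n) for name in SIGNAL_NAMES}
    r_arr = np.empty(n)
    sa = np.empty(n)
    scap = np.empty(n)
    sv = np.empty(n)
    oxcco_n = p.CuA_frac_n * p.CCO_tis

    for i, t in enumerate(time):
        u = inputs_at(t)
        a = model.algebraics(states[:, i], u)
        r_arr[i], sa[i], scap[i], sv[i] = a["r"], a["S_a"], a["S_cap"], a["S_v"]
        ntp, pcr, pi = phosphate_ratios(states[_IDX["ATP"], i],
                                        states[_IDX["PCr"], i],
                                        states[_IDX["Pi"], i], u.d_f)
        cols["NTP_EPP"][i] = ntp
        cols["PCr_EPP"][i] = pcr
        cols["Pi_EPP"][i] = pi
        d_live = (states[_IDX["CuA_ox"], i] - p.CuA_frac_n) * p.CCO_tis
        cols["dOxCCO"][i] = delta_oxCCO(d_live, u.d_f, oxcco_n)
        cols["pH"][i] = states[_IDX["pH_cyt"], i]
        cols["CBF"][i] = a["CBF"] / p.CBF_n
        cols["CMRO2"][i] = a["CMRO2_obs"] / p.CMRO2_n

    cols["dHbO2"], cols["dHHb"] = nirs_haemoglobin(model, r_arr, sa, scap, sv)
    return SignalSet(time=np.asarray(time, dtype=float), data=cols)
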