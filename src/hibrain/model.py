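"""Core ODE model: circulation with carotid occlusion, and a reduced
metabolic network with explicit cytoplasmic protons, NAD pools and
cell-death scaling.

Structure
---------
Blood flows through two series compartments: the supplying arteries
(conductance ``G_0``, reduced by carotid occlusion) and the autoregulated
cerebral arterial compartment (``G``, Poiseuille scaling ``G ~ r^4`` with
the radius ``r`` governed by an elastic/muscular wall-tension balance).
Oxygen leaves the capillaries down a concentration gradient and is consumed
at cytochrome c oxidase (CCO), modelled as a two-state Cu_A redox pool.
The cytoplasm runs glycolysis (with NAD and ATP feedback), the
lactate dehydrogenase and creatine kinase equilibria, lactate/H+
co-transport, and exchanges reducing equivalents with the mitochondria via
the malate-aspartate shuttle.  A lumped TCA step feeds the electron
transport chain, which pumps protons to maintain a proton motive force
used by the ATP synthase and dissipated by an uncoupling-scaled leak.
Protons in both compartments are buffered through effective proton volumes.

Calibration
-----------
Rate constants that are not independently known (maximal glycolytic rate,
shuttle and LDH/CK rate constants, electron-transport and ATP-turnover
constants, the proton leak) are solved in ``Model.__init__`` so that the
declared normal state -- baseline CBF, cytoplasmic pH ``pH_o_n``, the
normal metabolite concentrations and the normal oxidised Cu_A fraction --
is an *exact* steady state at normal inputs.  The single flux scale is
``q = CMRO2_n / 5``: one unit of glycolytic flux generates (with default
stoichiometry) ten matrix NADH-equivalents and hence five O2 per five
glucose, tying the whole network to the normal metabolic rate.

Units: concentrations mM (per tissue for transport fluxes, per compartment
for states), protons as pH (concentrations in M where needed), pressures
mmHg, radius um, time s, flow normalised to baseline CBF = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ConfigError, ConvergenceError, DomainError
from .parameters import ParameterSet

__all__ = [
    "Model", "STATE_NAMES", "state_manifest",
    "supplying_conductance", "boundary_pressure", "cerebral_blood_flow",
    "glycolysis_rate", "lactate_transport_rate", "ma_shuttle_rate",
    "effective_proton_volume", "mitochondrial_oxygen_derivative",
    "integrate_shuttle_to_equilibrium", "shuttle_mass_action_ratio",
]

log = logging.getLogger(__name__)

#: Stable state-vector ordering (machine-readable manifest via state_manifest).
STATE_NAMES: tuple[str, ...] = (
    "r",          # cerebral arterial radius, um
    "O2",         # mitochondrial oxygen, mM
    "gluc",       # cytoplasmic glucose, mM
    "pyr",        # cytoplasmic pyruvate, mM
    "lac",        # cytoplasmic lactate, mM
    "NADH_cyt",   # cytoplasmic NADH, mM
    "NAD_cyt",    # cytoplasmic NAD+, mM
    "NADH_mit",   # mitochondrial NADH, mM
    "NAD_mit",    # mitochondrial NAD+, mM
    "ATP",        # cytoplasmic ATP, mM
    "ADP",        # cytoplasmic ADP, mM
    "PCr",        # phosphocreatine, mM
    "Cr",         # creatine, mM
    "Pi",         # inorganic phosphate, mM
    "pH_cyt",     # cytoplasmic pH
    "pH_mit",     # mitochondrial pH
    "psi",        # mitochondrial membrane potential proxy, mV
    "CuA_ox",     # oxidised Cu_A fraction of CCO, dimensionless
)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

_STATE_DOC = {
    "r": ("um", "cerebral arterial radius"),
    "O2": ("mM", "mitochondrial oxygen concentration"),
    "gluc": ("mM", "cytoplasmic glucose"),
    "pyr": ("mM", "cytoplasmic pyruvate"),
    "lac": ("mM", "cytoplasmic lactate"),
    "NADH_cyt": ("mM", "cytoplasmic NADH"),
    "NAD_cyt": ("mM", "cytoplasmic NAD+"),
    "NADH_mit": ("mM", "mitochondrial NADH"),
    "NAD_mit": ("mM", "mitochondrial NAD+"),
    "ATP": ("mM", "cytoplasmic ATP"),
    "ADP": ("mM", "cytoplasmic ADP"),
    "PCr": ("mM", "phosphocreatine"),
    "Cr": ("mM", "creatine"),
    "Pi": ("mM", "inorganic phosphate"),
    "pH_cyt": ("pH", "cytoplasmic pH"),
    "pH_mit": ("pH", "mitochondrial pH"),
    "psi": ("mV", "mitochondrial membrane potential proxy"),
    "CuA_ox": ("fraction", "oxidised Cu_A fraction of tissue CCO"),
}


def state_manifest(model: "Model | None" = None) -> list[dict]:
    """Documented, stable state ordering (name, units, description and,
    when a model is supplied, the calibrated normal value)."""
    out = []
    for i, name in enumerate(STATE_NAMES):
        units, desc = _STATE_DOC[name]
        entry = {"index": i, "name": name, "units": units, "description": desc}
        if model is not None:
            entry["normal"] = float(model.y0[i])
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# Elementary operations (usable standalone; the Model composes them)
# ---------------------------------------------------------------------------

def supplying_conductance(k_occ: float, params: ParameterSet,
                          G_n: float | None = None) -> float:
    """Conductance of the supplying-artery compartment under occlusion:
    ``G_0 = G_0_frac * G_n * (1 - k_occ * occ_frac)``."""
    if not 0.0 <= k_occ <= 1.0:
        raise DomainError(f"k_occ={k_occ} outside [0, 1]")
    if G_n is None:
        P_a2_n = boundary_pressure(params.P_a_n, params.P_v,
                                   params.G_0_frac, 1.0)
        G_n = params.CBF_n / (P_a2_n - params.P_v)
    return params.G_0_frac * G_n * (1.0 - k_occ * params.occ_frac)


def boundary_pressure(P_a: float, P_v: float, G_0: float, G: float) -> float:
    """Pressure between supplying and cerebral compartments from flow
    continuity ``G_0 (P_a - P_a2) = G (P_a2 - P_v)``."""
    if G_0 <= 0 or G <= 0:
        raise DomainError("conductances must be strictly positive")
    return (G_0 * P_a + G * P_v) / (G_0 + G)


def cerebral_blood_flow(G: float, P_a2: float, P_v: float) -> float:
    """Ohm's-law flow through the cerebral compartment, ``G (P_a2 - P_v)``."""
    if G <= 0:
        raise DomainError("conductance must be strictly positive")
    return G * (P_a2 - P_v)


def glycolysis_rate(ADP: float, Pi: float, gluc: float, NAD_cyt: float,
                    ATP: float, params: ParameterSet,
                    v_glyc: float = 1.0) -> float:
    """Michaelis-type glycolytic rate with ATP inhibition and NAD dependence.

    Returns ``v_glyc [ADP]^2 [Pi]^2 [gluc] [NAD]^2 /
    ((k_A^2+[ATP]^2)(k_P^2+[Pi]^2)(k_G+[gluc])(k_N^2+[NAD]^2))``.
    ``v_glyc`` defaults to 1 (rate in units of the maximal rate); the model
    supplies its calibrated value.
    """
    for name, val in (("ADP", ADP), ("Pi", Pi), ("gluc", gluc),
                      ("NAD_cyt", NAD_cyt), ("ATP", ATP)):
        if val < 0:
            raise DomainError(f"negative concentration {name}={val}")
    p = params
    num = v_glyc * ADP ** 2 * Pi ** 2 * gluc * NAD_cyt ** 2
    den = ((p.k_m_glycA ** 2 + ATP ** 2) * (p.k_m_glycP ** 2 + Pi ** 2)
           * (p.k_m_glycG + gluc) * (p.k_m_glycN ** 2 + NAD_cyt ** 2))
    return num / den


def lactate_transport_rate(lac: float, params: ParameterSet,
                           H_cyt: float | None = None) -> float:
    """Net lactate influx through the monocarboxylate transporter.

    With ``k_MCT_H = 0`` (default) the simplified symmetric form is used;
    a positive ``k_MCT_H`` selects the full pH-dependent form, which then
    requires the cytoplasmic proton concentration (M).
    """
    if lac < 0:
        raise DomainError(f"negative lactate {lac}")
    p = params
    if p.k_MCT_H > 0:
        if H_cyt is None:
            raise DomainError("full MCT form requires H_cyt")
        return p.v_MCT * (
            p.lac_cap * p.H_cap
            / ((p.k_MCT + p.lac_cap) * (p.k_MCT_H + p.H_cap))
            - lac * H_cyt / ((p.k_MCT + lac) * (p.k_MCT_H + H_cyt)))
    return p.v_MCT * (p.lac_cap / (p.k_MCT + p.lac_cap)
                      - lac / (p.k_MCT + lac))


def ma_shuttle_rate(NADH_cyt: float, NAD_mit: float, H_cyt: float,
                    NADH_mit: float, NAD_cyt: float, H_mit: float,
                    params: ParameterSet, k_r: float = 1.0) -> float:
    """Mass-action rate of the malate-aspartate shuttle
    ``NADH_cyt + NAD_mit + H_cyt <=> NADH_mit + NAD_cyt + H_mit`` with
    ``k_f / k_r = K_eq_MAshut``."""
    k_f = params.K_eq_MAshut * k_r
    return (k_f * NADH_cyt * NAD_mit * H_cyt
            - k_r * NADH_mit * NAD_cyt * H_mit)


def effective_proton_volume(pH_c: float, params: ParameterSet) -> float:
    """Cytoplasmic effective proton volume
    ``R_Hi,c = C_buffi,c (10^-pH - 10^-(pH+dpH)) / dpH * Vol_cyt``.

    All cytoplasmic proton fluxes are divided by this quantity when
    converted to d(pH)/dt, mirroring the mitochondrial treatment.  A config
    switch selects division by ``Vol_cyt`` instead of multiplication (the
    two readings of the printed relationship).
    """
    if not 5.0 < pH_c < 9.0:
        raise DomainError(f"pH_c={pH_c} outside (5, 9)")
    if params.dpH <= 0:
        raise ConfigError("dpH must be strictly positive")
    core = params.C_buffi_c * (10.0 ** (-pH_c)
                               - 10.0 ** (-pH_c - params.dpH)) / params.dpH
    if params.buffer_vol_divides:
        return core / params.Vol_cyt
    return core * params.Vol_cyt


def _buffer_core(pH: float, C_buffi: float, dpH: float) -> float:
    return C_buffi * (10.0 ** (-pH) - 10.0 ** (-pH - dpH)) / dpH


def mitochondrial_oxygen_derivative(O2_mit: float, T_O2_in: float,
                                    T_box: float,
                                    params: ParameterSet) -> float:
    """Mitochondrial oxygen balance with dead-cell scaling:
    ``d[O2]/dt = T_O2_in / (V_mit (1 - d_f)) - T_box``.

    ``T_O2_in`` is the tissue-referred capillary-to-mitochondria transfer
    rate and ``T_box`` the matrix-referred CCO consumption rate.  The
    per-unit-transfer concentration change grows as the living volume
    fraction ``(1 - d_f)`` shrinks.
    """
    if not 0.0 <= params.d_f <= params.D_F_MAX:
        raise DomainError(f"d_f={params.d_f} outside [0, {params.D_F_MAX}]")
    return T_O2_in / (params.V_mit * (1.0 - params.d_f)) - T_box


# ---------------------------------------------------------------------------
# Malate-aspartate shuttle in isolation (equilibration oracle)
# ---------------------------------------------------------------------------

def shuttle_mass_action_ratio(NADH_cyt, NAD_mit, H_cyt,
                              NADH_mit, NAD_cyt, H_mit) -> float:
    """Products-over-reactants mass-action ratio of the shuttle reaction."""
    return (NADH_mit * NAD_cyt * H_mit) / (NADH_cyt * NAD_mit * H_cyt)


def integrate_shuttle_to_equilibrium(
        y0: dict[str, float] | None = None,
        params: ParameterSet | None = None,
        k_r: float = 1.0,
        tol: float = 1e-12,
        t_max: float = 1e9) -> dict[str, float]:
    """Integrate the shuttle reaction alone from positive initial
    concentrations until the net rate vanishes; returns the final
    concentrations plus the achieved mass-action ``ratio``.

    With every other reaction disabled the six concentrations follow the
    single reaction coordinate, so the integration converges to the
    mass-action ratio ``K_eq_MAshut`` from any positive start.
    """
    params = params or ParameterSet()
    if y0 is None:
        y0 = dict(NADH_cyt=2.0, NAD_mit=1.5, H_cyt=1e-7,
                  NADH_mit=0.2, NAD_cyt=3.0, H_mit=2e-7)
    order = ("NADH_cyt", "NAD_mit", "H_cyt", "NADH_mit", "NAD_cyt", "H_mit")
    y = np.array([y0[k] for k in order], dtype=float)
    if np.any(y <= 0):
        raise DomainError("initial shuttle concentrations must be positive")
    # protons participate on the same scale as the pyridine pools here, so
    # scale them up front to keep the system well conditioned
    scale = np.max(y) / y
    stoich = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])

    def rhs(t, z):
        c = z / scale
        rate = ma_shuttle_rate(*c, params=params, k_r=k_r)
        return stoich * rate * scale

    def settled(t, z):
        c = z / scale
        r0 = ma_shuttle_rate(*[max(v, 0.0) for v in c], params=params, k_r=k_r)
        return abs(r0) - tol
    settled.terminal = True
    settled.direction = -1

    sol = solve_ivp(rhs, (0.0, t_max), y * scale, method="LSODA",
                    rtol=1e-12, atol=1e-14, events=settled)
    if not sol.success:
        raise ConvergenceError(f"shuttle integration failed: {sol.message}")
    final = sol.y[:, -1] / scale
    out = dict(zip(order, final))
    out["ratio"] = shuttle_mass_action_ratio(*final)
    return out


# ---------------------------------------------------------------------------
# Assembled model
# ---------------------------------------------------------------------------

@dataclass
class Inputs:
    """Effective instantaneous driving inputs and control parameters."""
    SaO2: float
    Pa: float
    k_occ: float = 0.0
    k_unc: float = 1.0
    d_f: float = 0.0


class Model:
    """The calibrated ODE system (see module docstring).

    Construction validates the :class:`ParameterSet`, solves the free rate
    constants so the declared normal state is an exact steady state, and
    exposes ``rhs(t, y, inputs)`` plus an ``algebraics`` helper returning
    every intermediate quantity (pressures, CBF, saturations, fluxes).
    """

    def __init__(self, params: ParameterSet | None = None,
                 strict: bool = True):
        p = params or ParameterSet()
        p.validate()
        self.params = p
        self._warned_radius = False
        self._sv_cache: float | None = None

        # --- circulation ------------------------------------------------
        self.P_a2_n = boundary_pressure(p.P_a_n, p.P_v,
                                        p.G_0_frac, 1.0)  # ratio form
        self.G_n = p.CBF_n / (self.P_a2_n - p.P_v)
        self.G_0_n = p.G_0_frac * self.G_n

        # --- oxygen carriage ---------------------------------------------
        q = p.CMRO2_n / 5.0
        self.q = q
        self.KX = 4.0 * p.Hbtot_n * p.phi_flow
        S_v_n = p.SaO2_n - p.CMRO2_n / (p.CBF_n * self.KX)
        if not 0.0 < S_v_n < p.SaO2_n:
            raise ConfigError(
                f"calibrated venous saturation {S_v_n:.3f} is unphysical; "
                "check Hbtot_n / CMRO2_n / phi_flow")
        self.S_v_n = S_v_n
        self.S_cap_n = 0.5 * (p.SaO2_n + S_v_n)
        self.O2_cap_n = self._o2_cap(self.S_cap_n)
        if self.O2_cap_n <= p.O2_n:
            raise ConfigError("capillary O2 must exceed mitochondrial O2 at "
                              "baseline for gradient-driven transfer")
        self.D_O2 = p.CMRO2_n / (self.O2_cap_n - p.O2_n)

        # --- metabolic calibration ---------------------------------------
        H_c_n = 10.0 ** (-p.pH_o_n)
        H_m_n = 10.0 ** (-p.pH_mit_n)
        self.Pi_n = p.PCr_n / p.PCr_Pi_ratio_n

        glut_drive = (p.gluc_cap / (p.k_glut + p.gluc_cap)
                      - p.gluc_n / (p.k_glut + p.gluc_n))
        if glut_drive <= 0:
            raise ConfigError("gluc_cap must exceed gluc_n for net glucose "
                              "influx at baseline")
        self.v_glut = q / glut_drive

        gf = glycolysis_rate(p.ADP_n, self.Pi_n, p.gluc_n, p.NAD_cyt_n,
                             p.ATP_n, p, v_glyc=1.0)
        self.v_glyc = q / gf

        # LDH at equilibrium at baseline (zero net flux)
        ldh_fwd = p.pyr_n * p.NADH_cyt_n * H_c_n
        self.k_LDH_f = p.c_LDH * q / ldh_fwd
        self.k_LDH_r = self.k_LDH_f * ldh_fwd / (p.lac_n * p.NAD_cyt_n)

        # malate-aspartate shuttle carries 2q at baseline
        drive = (p.K_eq_MAshut * p.NADH_cyt_n * p.NAD_mit_n * H_c_n
                 - p.NADH_mit_n * p.NAD_cyt_n * H_m_n)
        if drive <= 0:
            raise ConfigError("baseline NAD pools put the MA shuttle in "
                              "reverse; cannot carry forward flux")
        self.k_r_MAshut = 2.0 * q / drive
        self.k_f_MAshut = p.K_eq_MAshut * self.k_r_MAshut

        # lumped TCA consumes pyruvate at 2q
        self.k_TCA = 2.0 * q / (p.pyr_n * p.NAD_mit_n
                                / (p.k_m_NADm + p.NAD_mit_n))

        # electron transport: f_ox_n matrix NADH-equivalents per second
        f_ox_n = (2.0 * p.n_mitN + 2.0) * q
        self.f_ox_n = f_ox_n
        self.k_red = f_ox_n / (p.NADH_mit_n * p.CuA_frac_n)
        self.k_ox = f_ox_n / ((1.0 - p.CuA_frac_n) * p.O2_n)

        # ATP synthase and turnover
        s_n = 1.0 / (1.0 + math.exp(-p.k_s * (p.Dp_n - p.Dp_half)))
        f_synOx_n = p.p_ratio * f_ox_n
        self.f_synOx_n = f_synOx_n
        self.k_syn = f_synOx_n / ((p.ADP_n / (p.k_m_synA + p.ADP_n)) * s_n)
        f_use_n = 2.0 * q + f_synOx_n
        self.f_use_n = f_use_n
        self.k_use = f_use_n / (p.ATP_n / (p.k_m_use + p.ATP_n))

        # creatine kinase at equilibrium at baseline
        ck_fwd = p.PCr_n * p.ADP_n * H_c_n
        self.k_CK_f = p.c_CK * q / ck_fwd
        self.k_CK_r = p.c_CK * q / (p.ATP_n * p.Cr_n)

        # proton motive force bookkeeping
        J_pump_n = (p.n_pump1 + p.n_pump2) * f_ox_n
        leak_n = J_pump_n - p.n_syn * f_synOx_n - 2.0 * q
        if leak_n <= 0:
            raise ConfigError("pump stoichiometry leaves no baseline proton "
                              "leak; raise n_pump or lower n_syn/p_ratio")
        self.leak_n = leak_n
        # matrix proton yield of the lumped TCA step, solved for closure
        self.n_TCA_H = (J_pump_n - p.n_syn * f_synOx_n - leak_n - 2.0 * q
                        + 2.0 * f_ox_n) / (2.0 * q)

        # buffering capacities: Eq-9 effective volumes supply the pH
        # dependence; the absolute scale matches beta_*_n at baseline
        self.u_c = p.beta_cyt_n / effective_proton_volume(p.pH_o_n, p)
        # constant background acid extrusion balancing the baseline
        # cytosolic proton budget (pH regulation at the setpoint)
        self.J_Hc0 = -(p.n_glycH * q - 2.0 * q)
        core_m = _buffer_core(p.pH_mit_n, p.C_buffi_m, p.dpH) * p.V_mit
        self.u_m = p.beta_mit_n / core_m

        self.psi_n = p.Dp_n - p.Z_nernst * (p.pH_mit_n - p.pH_o_n)

        # wall-tension balance at baseline radius
        self.T_e_n = self._elastic_tension(p.r_n)
        self.T_m_n = self.P_a2_n * p.r_n - self.T_e_n
        self.r_min = p.r_min_frac * p.r_n
        self.r_max = p.r_max_frac * p.r_n

        self.CCO_mM = p.CCO_tis * 1e-3  # tissue mM

        # --- baseline state ----------------------------------------------
        y0 = np.empty(len(STATE_NAMES))
        y0[_IDX["r"]] = p.r_n
        y0[_IDX["O2"]] = p.O2_n
        y0[_IDX["gluc"]] = p.gluc_n
        y0[_IDX["pyr"]] = p.pyr_n
        y0[_IDX["lac"]] = p.lac_n
        y0[_IDX["NADH_cyt"]] = p.NADH_cyt_n
        y0[_IDX["NAD_cyt"]] = p.NAD_cyt_n
        y0[_IDX["NADH_mit"]] = p.NADH_mit_n
        y0[_IDX["NAD_mit"]] = p.NAD_mit_n
        y0[_IDX["ATP"]] = p.ATP_n
        y0[_IDX["ADP"]] = p.ADP_n
        y0[_IDX["PCr"]] = p.PCr_n
        y0[_IDX["Cr"]] = p.Cr_n
        y0[_IDX["Pi"]] = self.Pi_n
        y0[_IDX["pH_cyt"]] = p.pH_o_n
        y0[_IDX["pH_mit"]] = p.pH_mit_n
        y0[_IDX["psi"]] = self.psi_n
        y0[_IDX["CuA_ox"]] = p.CuA_frac_n
        self.y0 = y0

        self.baseline_inputs = Inputs(SaO2=p.SaO2_n, Pa=p.P_a_n, k_occ=0.0,
                                      k_unc=1.0, d_f=0.0)
        resid = self.rhs(0.0, y0, self.baseline_inputs)
        scale = np.maximum(np.abs(y0), 1e-3)
        self.baseline_residual = float(np.max(np.abs(resid) / scale))
        if strict and self.baseline_residual > 1e-9:
            raise ConfigError(
                "baseline is not a steady state (max scaled residual "
                f"{self.baseline_residual:.2e}); the supplied parameters "
                "break the calibration assumptions (e.g. lac_n != lac_cap)")

    # --- pieces ----------------------------------------------------------

    def _o2_cap(self, S: float) -> float:
        """Dissolved capillary O2 (mM) from saturation via the inverse Hill
        dissociation curve."""
        p = self.params
        S = min(max(S, 0.0), 0.999)
        if S <= 0.0:
            return 0.0
        P = p.P50 * (S / (1.0 - S)) ** (1.0 / p.hill_h)
        return p.alpha_O2 * P

    def _o2_cap_prime(self, S: float) -> float:
        """d(_o2_cap)/dS on the open interval (0, 0.999)."""
        p = self.params
        if S <= 0.0 or S >= 0.999:
            return 0.0
        ratio = S / (1.0 - S)
        return (p.alpha_O2 * p.P50 / p.hill_h
                * ratio ** (1.0 / p.hill_h - 1.0) / (1.0 - S) ** 2)

    def _elastic_tension(self, r: float) -> float:
        p = self.params
        return p.E_elast * p.r_0 * (
            math.exp(p.k_elast * (r - p.r_0) / p.r_0) - 1.0)

    def _solve_venous_saturation(self, CBF: float, S_a: float,
                                 O2: float) -> tuple[float, str]:
        """Quasi-steady venous saturation balancing convective delivery
        against gradient-driven transfer to the mitochondria.

        Returns ``(S_v, regime)`` with regime "interior" (balanced),
        "empty" (delivery-limited, maximal extraction) or "backflow"
        (tissue O2 at or above capillary O2: no extraction).
        """
        D, KX = self.D_O2, self.KX
        if S_a <= 1e-6:
            return max(S_a, 0.0), "backflow"

        def g(S_v: float) -> float:
            return (KX * CBF * (S_a - S_v)
                    - D * (self._o2_cap(0.5 * (S_a + S_v)) - O2))

        if g(S_a) >= 0.0:        # tissue O2 above capillary: no extraction
            return S_a, "backflow"
        lo = min(1e-9, S_a * 0.5)
        if g(lo) <= 0.0:         # delivery-limited: maximal extraction
            return lo, "empty"

        # warm-started Newton (g is smooth, monotone decreasing); fall back
        # to bracketed root finding if it strays
        sv = self._sv_cache
        if sv is not None and lo < sv < S_a:
            for _ in range(8):
                gv = g(sv)
                if abs(gv) < 1e-13 * max(KX * CBF, D):
                    self._sv_cache = sv
                    return sv, "interior"
                gp = -KX * CBF - 0.5 * D * self._o2_cap_prime(
                    0.5 * (S_a + sv))
                if gp == 0.0:
                    break
                nxt = sv - gv / gp
                if not lo < nxt < S_a:
                    break
                sv = nxt
        sv = brentq(g, lo, S_a, xtol=1e-16, rtol=4 * np.finfo(float).eps)
        self._sv_cache = sv
        return sv, "interior"

    # --- assembled right-hand side ----------------------------------------

    def algebraics(self, y: np.ndarray, u: Inputs) -> dict[str, float]:
        """All intermediate quantities at state ``y`` under inputs ``u``."""
        p = self.params
        s = {name: y[i] for name, i in _IDX.items()}
        r = min(max(s["r"], self.r_min), self.r_max)
        H_c = 10.0 ** (-s["pH_cyt"])
        H_m = 10.0 ** (-s["pH_mit"])

        # clip concentrations for rate evaluation only
        conc = {k: max(s[k], 0.0) for k in
                ("O2", "gluc", "pyr", "lac", "NADH_cyt", "NAD_cyt",
                 "NADH_mit", "NAD_mit", "ATP", "ADP", "PCr", "Cr", "Pi")}
        a = min(max(s["CuA_ox"], 0.0), 1.0)

        G = self.G_n * (r / p.r_n) ** 4
        G_0 = self.G_0_n * (1.0 - u.k_occ * p.occ_frac)
        P_a2 = boundary_pressure(u.Pa, p.P_v, G_0, G)
        CBF = cerebral_blood_flow(G, P_a2, p.P_v)

        S_a = min(max(u.SaO2, 0.0), 0.999)
        S_v, regime = self._solve_venous_saturation(CBF, S_a, conc["O2"])
        S_cap = 0.5 * (S_a + S_v)
        O2_cap = self._o2_cap(S_cap)
        if regime == "backflow":
            T_O2in = self.D_O2 * (O2_cap - conc["O2"])
        else:
            T_O2in = self.KX * CBF * (S_a - S_v)

        f1 = glycolysis_rate(conc["ADP"], conc["Pi"], conc["gluc"],
                             conc["NAD_cyt"], conc["ATP"], p,
                             v_glyc=self.v_glyc)
        J_glut = self.v_glut * (p.gluc_cap / (p.k_glut + p.gluc_cap)
                                - conc["gluc"] / (p.k_glut + conc["gluc"]))
        f_LDH = (self.k_LDH_f * conc["pyr"] * conc["NADH_cyt"] * H_c
                 - self.k_LDH_r * conc["lac"] * conc["NAD_cyt"])
        f_MCT = lactate_transport_rate(conc["lac"], p, H_cyt=H_c)
        f_shut = ma_shuttle_rate(conc["NADH_cyt"], conc["NAD_mit"], H_c,
                                 conc["NADH_mit"], conc["NAD_cyt"], H_m,
                                 p, k_r=self.k_r_MAshut)
        f_TCA = self.k_TCA * conc["pyr"] * conc["NAD_mit"] \
            / (p.k_m_NADm + conc["NAD_mit"])

        Dp = s["psi"] + p.Z_nernst * (s["pH_mit"] - s["pH_cyt"])
        phi = math.exp(-p.k_dp * (Dp - p.Dp_n))
        f_red = self.k_red * conc["NADH_mit"] * a * phi
        f_ox = self.k_ox * (1.0 - a) * conc["O2"]
        f_synOx = self.k_syn * (conc["ADP"] / (p.k_m_synA + conc["ADP"])) \
            * (1.0 / (1.0 + math.exp(-p.k_s * (Dp - p.Dp_half))))
        J_leak = u.k_unc * self.leak_n * math.exp(
            p.k_leak_exp * (Dp - p.Dp_n) / p.Dp_n)
        f_use = self.k_use * conc["ATP"] / (p.k_m_use + conc["ATP"])
        f_CK = (self.k_CK_f * conc["PCr"] * conc["ADP"] * H_c
                - self.k_CK_r * conc["ATP"] * conc["Cr"])
        J_pump = p.n_pump1 * f_red + p.n_pump2 * f_ox
        T_box = (f_ox / 2.0) / p.V_mit
        CMRO2_live = f_ox / 2.0          # tissue-referred, living tissue
        CMRO2_obs = (1.0 - u.d_f) * CMRO2_live

        return dict(
            r=r, G=G, G_0=G_0, P_a2=P_a2, CBF=CBF,
            S_a=S_a, S_v=S_v, S_cap=S_cap, O2_cap=O2_cap, T_O2in=T_O2in,
            f_glyc=f1, J_glut=J_glut, f_LDH=f_LDH, f_MCT=f_MCT,
            f_shut=f_shut, f_TCA=f_TCA, Dp=Dp, f_red=f_red, f_ox=f_ox,
            f_synOx=f_synOx, J_leak=J_leak, f_use=f_use, f_CK=f_CK,
            J_pump=J_pump, T_box=T_box, CMRO2_live=CMRO2_live,
            CMRO2_obs=CMRO2_obs, H_c=H_c, H_m=H_m,
        )

    def rhs(self, t: float, y: np.ndarray, u: Inputs) -> np.ndarray:
        """Time derivatives of the state vector.

        NAD pools, the creatine pool, the adenine pool and the exchangeable
        phosphate pool (EPP = PCr + Pi + 2 ATP) are conserved exactly by
        construction of the stoichiometry below.
        """
        p = self.params
        a = self.algebraics(y, u)
        dy = np.zeros_like(y)

        # vessel radius: wall tension balance with autoregulatory stimulus
        stim = (p.w_P * (u.Pa / p.P_a_n - 1.0)
                + p.w_O2 * (a["O2_cap"] / self.O2_cap_n - 1.0))
        mu = math.tanh(p.g_auto * stim)
        T_m = self.T_m_n * (1.0 + p.k_tm * mu)
        dr = p.k_r * (a["P_a2"] * a["r"] - self._elastic_tension(a["r"]) - T_m)
        r_raw = y[_IDX["r"]]
        if (r_raw <= self.r_min and dr < 0) or (r_raw >= self.r_max and dr > 0):
            if not self._warned_radius:
                log.warning("radius clipped to configured bounds "
                            "[%.1f, %.1f] um at t=%.1f s",
                            self.r_min, self.r_max, t)
                self._warned_radius = True
            dr = 0.0
        dy[_IDX["r"]] = dr

        if not 0.0 <= u.d_f <= p.D_F_MAX:
            raise DomainError(f"d_f={u.d_f} outside [0, {p.D_F_MAX}]")
        dy[_IDX["O2"]] = (a["T_O2in"] / (p.V_mit * (1.0 - u.d_f))
                          - a["T_box"])

        f1, f_LDH, f_MCT = a["f_glyc"], a["f_LDH"], a["f_MCT"]
        f_shut, f_TCA = a["f_shut"], a["f_TCA"]
        f_red, f_ox = a["f_red"], a["f_ox"]
        f_synOx, f_use, f_CK = a["f_synOx"], a["f_use"], a["f_CK"]

        dy[_IDX["gluc"]] = (a["J_glut"] - f1) / p.Vol_cyt
        dy[_IDX["pyr"]] = (2.0 * f1 - f_LDH - f_TCA) / p.Vol_cyt
        dy[_IDX["lac"]] = (f_LDH + f_MCT) / p.Vol_cyt

        dNADHc = (2.0 * f1 - f_LDH - f_shut) / p.Vol_cyt
        dy[_IDX["NADH_cyt"]] = dNADHc
        dy[_IDX["NAD_cyt"]] = -dNADHc

        dNADHm = (p.n_mitN * f_TCA + f_shut - f_red) / p.V_mit
        dy[_IDX["NADH_mit"]] = dNADHm
        dy[_IDX["NAD_mit"]] = -dNADHm

        dATP = (2.0 * f1 + f_synOx + f_CK - f_use) / p.Vol_cyt
        dy[_IDX["ATP"]] = dATP
        dy[_IDX["ADP"]] = -dATP
        dPCr = -f_CK / p.Vol_cyt
        dy[_IDX["PCr"]] = dPCr
        dy[_IDX["Cr"]] = -dPCr
        # EPP = PCr + Pi + 2 ATP conserved exactly (ADP beta-phosphate is
        # booked in the Pi pool; see methods note)
        dy[_IDX["Pi"]] = -dPCr - 2.0 * dATP

        # proton bookkeeping (tissue mM/s of proton equivalents)
        f_syn_tot = f_synOx + 2.0 * f1
        J_Hc = (p.n_glycH * f1 - f_LDH + f_MCT - f_shut
                + (f_use - f_syn_tot) - f_CK + self.J_Hc0
                + p.k_pHc_reg * (y[_IDX["pH_cyt"]] - p.pH_o_n))
        beta_c = self.u_c * effective_proton_volume(
            min(max(y[_IDX["pH_cyt"]], 5.01), 8.99), p)
        dy[_IDX["pH_cyt"]] = -J_Hc / beta_c

        J_Hm = (-a["J_pump"] + p.n_syn * f_synOx + a["J_leak"] + f_shut
                + self.n_TCA_H * f_TCA - 2.0 * f_ox
                + p.k_pHm_reg * (y[_IDX["pH_mit"]] - p.pH_mit_n))
        beta_m = self.u_m * _buffer_core(
            min(max(y[_IDX["pH_mit"]], 5.01), 8.99), p.C_buffi_m, p.dpH) \
            * p.V_mit
        dy[_IDX["pH_mit"]] = -J_Hm / beta_m

        dy[_IDX["psi"]] = (a["J_pump"] - p.n_syn * f_synOx - a["J_leak"]
                           - f_shut) / p.c_psi

        dy[_IDX["CuA_ox"]] = 2.0 * (f_ox - f_red) / self.CCO_mM

        if not np.all(np.isfinite(dy)):
            bad = [STATE_NAMES[i] for i in np.where(~np.isfinite(dy))[0]]
            raise ConvergenceError(
                f"non-finite derivative for {bad} at t={t:.3f}; "
                f"state={dict(zip(STATE_NAMES, y))}")
        return dy

    # convenience ----------------------------------------------------------
    def atol(self, scale: float = 1e-9) -> np.ndarray:
        """Per-variable absolute tolerances scaled by normal values."""
        return np.maximum(np.abs(self.y0), 1e-3) * scale * 1e3
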