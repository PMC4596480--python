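"""Model parameterisation.

All named constants of the circulation/metabolism model live in a single
:class:`ParameterSet` dataclass.  Concentrations are mM (protons are carried
internally as pH and reported in M where a concentration is required),
pressures mmHg, time seconds, radii um.  Flows are normalised so that
baseline cerebral blood flow is 1 flow unit, and conductances carry the
matching normalised unit (flow per mmHg).

Several kinetic constants are deliberately *not* fields here: they are solved
at model construction time so that the declared normal state is an exact
steady state (see :mod:`hibrain.model`).  Fields below are the quantities a
user may meaningfully set, screen or fit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError

__all__ = ["ParameterSet", "SENSITIVITY_EXCLUDED", "default_ranges"]


@dataclass
class ParameterSet:
    # --- circulation -----------------------------------------------------
    occ_frac: float = 0.8        # fraction of supply normally via carotids
    G_0_frac: float = 5.0        # ratio of supplying to cerebral conductance
    P_a_n: float = 50.0          # normal mean arterial pressure, mmHg
    P_v: float = 4.0             # venous-side boundary pressure, mmHg
    CBF_n: float = 1.0           # baseline CBF, normalised flow units
    r_n: float = 95.0            # normal cerebral arterial radius, um
    r_0: float = 126.0           # unstressed radius in the elastic tension law, um
    E_elast: float = 60.0        # elastic tension scale, mmHg
    k_elast: float = 4.0         # elastic tension exponent (dimensionless)
    k_tm: float = 0.6            # fractional muscular-tension modulation range
    g_auto: float = 1.2          # autoregulation sigmoid gain
    w_P: float = 1.0             # pressure weight in the demand stimulus
    w_O2: float = 1.0            # capillary-oxygen weight in the demand stimulus
    k_r: float = 0.002           # radius relaxation rate, um/(mmHg*um*s)
    r_min_frac: float = 0.5      # radius bounds, fractions of r_n
    r_max_frac: float = 2.0

    # --- blood oxygen carriage ------------------------------------------
    Hbtot_n: float = 5.4         # normal blood total haemoglobin, mM (tetramer)
    V_blood_n: float = 0.0325    # normal blood volume fraction of tissue
    art_frac: float = 0.3        # arterial share of blood volume at baseline
    cap_frac: float = 0.1        # capillary share (fixed volume)
    SaO2_n: float = 0.96         # normal arterial O2 saturation
    phi_flow: float = 0.0029868  # flow-unit O2-carriage scale (calibrates S_v,n)
    P50: float = 30.0            # haemoglobin P50, mmHg
    hill_h: float = 2.5          # Hill exponent of the dissociation curve
    alpha_O2: float = 0.0014     # plasma O2 solubility, mM/mmHg
    O2_n: float = 0.024          # normal mitochondrial O2 concentration, mM

    # --- metabolite pools (normal values; Table-default calibration) -----
    CMRO2_n: float = 0.02        # normal O2 consumption, tissue mM/s
    ATP_n: float = 2.2
    ADP_n: float = 0.03
    PCr_n: float = 2.6
    PCr_Pi_ratio_n: float = 2.73
    Cr_n: float = 1.0
    gluc_n: float = 1.2
    gluc_cap: float = 5.3        # capillary glucose, mM (fixed)
    k_glut: float = 6.2          # glucose carrier affinity, mM
    pyr_n: float = 0.1
    lac_n: float = 1.0
    lac_cap: float = 1.0         # capillary lactate, mM (fixed)
    H_cap: float = 5.0e-8        # capillary proton concentration, M (pH 7.3)
    NAD_cyt_n: float = 359.0     # printed value; see nad_unit_corrected()
    NADH_cyt_n: float = 50.0
    NAD_mit_n: float = 2.7
    NADH_mit_n: float = 0.3
    pH_o_n: float = 7.00         # normal cytoplasmic pH
    pH_mit_n: float = 7.4        # normal mitochondrial pH

    # --- cytochrome c oxidase -------------------------------------------
    CCO_tis: float = 2.2         # tissue CCO concentration, uM
    CuA_frac_n: float = 0.67     # normal oxidised Cu_A fraction

    # --- reaction constants ---------------------------------------------
    k_m_glycA: float = 2.2       # ATP constant in glycolysis, mM
    k_m_glycP: float = 0.95      # Pi constant, mM
    k_m_glycG: float = 0.5       # glucose constant, mM
    k_m_glycN: float = 1.0       # NAD constant, mM
    v_MCT: float = 0.02          # max lactate transport rate, tissue mM/s
    k_MCT: float = 1.0           # lactate affinity, mM
    k_MCT_H: float = 0.0         # proton affinity; 0 selects simplified form
    K_eq_MAshut: float = 10.0    # malate-aspartate shuttle equilibrium constant
    c_LDH: float = 20.0          # LDH one-way baseline flux, multiples of q
    c_CK: float = 50.0           # creatine kinase one-way baseline flux, multiples of q
    k_m_NADm: float = 0.4        # NAD_mit constant in the lumped TCA step, mM
    k_m_use: float = 1.0         # ATP constant in the ATP-turnover rate, mM

    # --- proton buffering (effective-volume relationship) ----------------
    C_buffi_c: float = 10.0      # cytoplasmic buffering constant
    C_buffi_m: float = 10.0      # mitochondrial buffering constant
    dpH: float = 0.001           # finite-difference pH increment
    Vol_cyt: float = 0.8         # cytoplasmic volume fraction of tissue
    V_mit: float = 0.067         # mitochondrial volume fraction of tissue
    buffer_vol_divides: bool = False  # Eq-form switch: divide instead of multiply
    beta_cyt_n: float = 40.0     # baseline cytoplasmic buffering capacity, tissue mM/pH
    beta_mit_n: float = 2.5      # baseline mitochondrial buffering capacity, tissue mM/pH
    k_pHm_reg: float = 0.02      # electroneutral K+/H+ antiport rate, mM/s per pH deviation
    k_pHc_reg: float = 0.01      # cytoplasmic pH regulation (NHE/bicarbonate-like), mM/s per pH deviation
    n_glycH: float = 4.0         # cytosolic proton yield per glucose through glycolysis

    # --- electron transport / oxidative phosphorylation ------------------
    n_pump1: float = 6.0         # protons pumped per NADH, complexes I+III
    n_pump2: float = 4.0         # protons pumped per 2e- at CCO
    n_syn: float = 3.0           # protons through the synthase per ATP
    n_mitN: float = 4.0          # matrix NADH equivalents per pyruvate (TCA lump)
    p_ratio: float = 2.5         # ATP per matrix NADH oxidised (P/O-like)
    Dp_n: float = 145.0          # normal proton motive force, mV
    Dp_half: float = 130.0       # synthase half-activation pmf, mV
    k_s: float = 0.2             # synthase pmf sigmoid steepness, 1/mV
    k_dp: float = 0.02           # ETC back-pressure sensitivity, 1/mV
    k_leak_exp: float = 6.0      # proton-leak exponential steepness
    k_m_synA: float = 0.025      # ADP constant of the synthase, mM
    c_psi: float = 0.002         # membrane charge capacitance, tissue mM/mV
    Z_nernst: float = 61.5       # 2.303 RT/F at 310 K, mV/pH

    # --- control parameters ----------------------------------------------
    k_unc: float = 1.0           # mitochondrial uncoupling factor (normal 1)
    k_occ: float = 0.0           # carotid occlusion control, 0..1
    d_f: float = 0.0             # dead-cell fraction, 0..<1

    # ---------------------------------------------------------------------
    D_F_MAX = 0.999  # upper bound avoiding the oxygen-equation singularity

    def validate(self) -> None:
        """Raise :class:`ConfigError` on any out-of-range field."""
        def _pos(name: str) -> None:
            if getattr(self, name) <= 0:
                raise ConfigError(f"parameter {name} must be strictly positive")

        for name in (
            "G_0_frac", "P_a_n", "CBF_n", "r_n", "r_0", "E_elast", "k_elast",
            "Hbtot_n", "V_blood_n", "SaO2_n", "phi_flow", "P50", "hill_h",
            "alpha_O2", "O2_n", "CMRO2_n", "ATP_n", "ADP_n", "PCr_n",
            "PCr_Pi_ratio_n", "Cr_n", "gluc_n", "gluc_cap", "k_glut", "pyr_n",
            "lac_n", "lac_cap", "H_cap", "NAD_cyt_n", "NADH_cyt_n",
            "NAD_mit_n", "NADH_mit_n", "CCO_tis", "k_m_glycA", "k_m_glycP",
            "k_m_glycG", "k_m_glycN", "v_MCT", "k_MCT", "K_eq_MAshut",
            "c_LDH", "c_CK", "k_m_NADm", "k_m_use", "C_buffi_c", "C_buffi_m", "k_pHm_reg", "k_pHc_reg", "n_glycH",
            "dpH", "Vol_cyt", "V_mit", "beta_cyt_n", "beta_mit_n", "n_pump1",
            "n_pump2", "n_syn", "n_mitN", "p_ratio", "Dp_n", "k_s",
            "k_m_synA", "c_psi", "Z_nernst", "k_unc", "k_r", "k_leak_exp",
        ):
            _pos(name)
        if not 0.0 <= self.occ_frac <= 1.0:
            raise ConfigError("occ_frac must lie in [0, 1]")
        if not 0.0 <= self.k_occ <= 1.0:
            raise ConfigError("k_occ must lie in [0, 1]")
        if not 0.0 <= self.d_f <= self.D_F_MAX:
            raise ConfigError(
                f"d_f must lie in [0, {self.D_F_MAX}] (d_f -> 1 is singular)")
        if not 0.0 < self.SaO2_n <= 1.0:
            raise ConfigError("SaO2_n must lie in (0, 1]")
        if not 0.0 < self.CuA_frac_n < 1.0:
            raise ConfigError("CuA_frac_n must lie in (0, 1)")
        if self.k_MCT_H < 0:
            raise ConfigError("k_MCT_H must be non-negative")
        if not 5.0 < self.pH_o_n < 9.0:
            raise ConfigError("pH_o_n must lie in (5, 9)")
        if not 5.0 < self.pH_mit_n < 9.0:
            raise ConfigError("pH_mit_n must lie in (5, 9)")
        if not 0 < self.art_frac < 1 or not 0 < self.cap_frac < 1 \
                or self.art_frac + self.cap_frac >= 1:
            raise ConfigError("art_frac and cap_frac must split (0,1)")
        if self.r_min_frac <= 0 or self.r_max_frac <= self.r_min_frac:
            raise ConfigError("radius bounds require 0 < r_min_frac < r_max_frac")

    # --- convenience -----------------------------------------------------
    def replace(self, **kwargs: Any) -> "ParameterSet":
        """A copy with the given fields overridden (validated)."""
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        out = dataclasses.replace(self, **kwargs)
        out.validate()
        return out

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def nad_unit_corrected(cls, **kwargs: Any) -> "ParameterSet":
        """Preset with cytoplasmic NAD/NADH scaled to physiological (uM-range)
        magnitudes, for users who prefer 0.359/0.050 mM over the tabulated
        359/50 mM defaults."""
        base = dict(NAD_cyt_n=0.359, NADH_cyt_n=0.050)
        base.update(kwargs)
        return cls().replace(**base)

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ParameterSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"parameter file {path!r} must map names to values")
        return cls().replace(**raw)


#: Parameters treated as physical constants or structural switches, excluded
#: from sensitivity screening and fitting by default (configurable).
SENSITIVITY_EXCLUDED: tuple[str, ...] = (
    "Z_nernst", "alpha_O2", "dpH", "buffer_vol_divides", "k_MCT_H",
    "k_occ", "d_f", "k_unc", "r_min_frac", "r_max_frac", "D_F_MAX",
)

#: Parameters with heuristic values get a wider screening range.
_WIDE = {"g_auto", "w_P", "w_O2", "k_tm", "k_dp", "k_s", "c_psi", "k_r", "k_leak_exp",
         "c_LDH", "c_CK", "beta_cyt_n", "beta_mit_n", "k_pHm_reg", "k_pHc_reg"}

#: Parameters defined as fractions clipped to [0, 1].
_UNIT_INTERVAL = {"occ_frac", "CuA_frac_n", "SaO2_n", "art_frac", "cap_frac",
                  "V_blood_n", "Vol_cyt", "V_mit"}


def default_ranges(params: ParameterSet | None = None,
                   rel: float = 0.2,
                   wide_rel: float = 0.5) -> dict[str, tuple[float, float]]:
    """Screening/fitting ranges: +/-`rel` of normal (wider for heuristic
    parameters), clipped to meaningful bounds."""
    p = params or ParameterSet()
    out: dict[str, tuple[float, float]] = {}
    for f in dataclasses.fields(p):
        name = f.name
        if name in SENSITIVITY_EXCLUDED:
            continue
        val = getattr(p, name)
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            continue
        r = wide_rel if name in _WIDE else rel
        lo, hi = val * (1 - r), val * (1 + r)
        if name in _UNIT_INTERVAL:
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        if lo >= hi:
            continue
        out[name] = (lo, hi)
    return out
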