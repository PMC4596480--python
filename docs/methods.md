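# Methods

`hibrain` simulates cerebral blood flow and energy metabolism in the
neonatal piglet brain during and after a hypoxic-ischaemic (HI) insult, and
maps the simulated state onto the quantities measured by broadband
near-infrared spectroscopy (NIRS) and phosphorus magnetic resonance
spectroscopy (31P-MRS).  This note documents the model, its assumptions,
the start-up calibration, the numerical choices, and what the synthetic
studies used in testing do and do not demonstrate.

## Circulation

Blood flow follows the electrical-circuit analogy: flow through a
compartment equals its conductance times the pressure drop.  Two series
compartments are modelled.

* **Supplying arteries** with conductance
  `G0 = G0_frac * G_n * (1 - k_occ * occ_frac)`, where `occ_frac = 0.8` is
  the fraction of cerebral supply normally carried by the carotid arteries
  and `k_occ` in [0, 1] is the experimental occlusion control.  With the
  default conductance ratio `G0_frac = 5`, complete bilateral occlusion
  reduces `G0` to 20% of normal and steady-state CBF to roughly 58% of
  baseline — inside the 45–75% band reported for piglets with both
  carotids occluded at normal oxygenation.
* **Cerebral arterial compartment** with autoregulated conductance
  `G = G_n (r / r_n)^4` (Poiseuille scaling of a representative radius
  `r`).  The boundary pressure between the compartments follows from flow
  continuity, `P_a2 = (G0 P_a + G P_v) / (G0 + G)`, and
  `CBF = G (P_a2 - P_v)`.  Venous pressure `P_v` is a fixed 4 mmHg;
  capillary-bed resistance is neglected; vessel compliance is not
  modelled.

The radius relaxes toward a wall-tension balance
`P_a2 * r = T_e(r) + T_m(mu)`, with an exponential elastic term
`T_e = E_elast * r_0 * (exp(k_elast (r - r_0)/r_0) - 1)` anchored at the
unstressed radius `r_0` (default 126 um) and a muscular term
`T_m = T_m_n (1 + k_tm * mu)` whose activation
`mu = tanh(g_auto * stim)` responds to deviations of systemic arterial
pressure and capillary oxygen from normal.  The systemic pressure (not the
post-occlusion boundary pressure) drives the myogenic stimulus; this is
inherited from the single-compartment ancestry of the circulation model
and, importantly, prevents the autoregulation from cancelling the effect
of carotid occlusion, which the steady-state design constraint above
requires.  `T_m_n` is calibrated so the normal radius balances at normal
inputs.  The defaults `g_auto = 1.2`, `k_tm = 0.6` put steady-state CBF
within 20% of baseline for arterial pressures of 30–70 mmHg (the
autoregulatory plateau) while keeping the occluded flow inside its band.
The radius is clipped to `[0.5, 2] * r_n` with a logged warning.

## Oxygen carriage

Arterial saturation `SaO2` is a driving input.  Venous saturation is the
quasi-steady solution of convective delivery = diffusive transfer:
`4 Hbtot_n * phi_flow * CBF * (S_a - S_v) = D_O2 (O2_cap - O2_mit)`, with
capillary dissolved oxygen obtained from the mean capillary saturation
through the inverse Hill dissociation curve (P50 = 30 mmHg, h = 2.5).
`phi_flow` and `D_O2` are calibrated so that the normal state extracts
exactly the normal metabolic rate `CMRO2_n` at a normal venous saturation
of 0.65.  This scalar balance is solved inside the right-hand side with a
warm-started Newton iteration (bracketed fallback), with explicit
delivery-limited and backflow regimes for extreme states.

## Metabolism

The metabolic network is a reduced core containing exactly the processes
needed for the measured signals, with explicit cytoplasmic protons and
NAD pools:

* **Glycolysis** (Michaelis form with ATP inhibition and NAD dependence):
  rate `v_glyc [ADP]^2 [Pi]^2 [gluc] [NAD_cyt]^2 / ((k_A^2+[ATP]^2)
  (k_P^2+[Pi]^2)(k_G+[gluc])(k_N^2+[NAD_cyt]^2))`; glucose is supplied by
  a symmetric saturable carrier from a fixed capillary concentration.
* **Lactate dehydrogenase** (mass action, `pyr + NADH + H <-> lac + NAD`)
  and **lactate/H+ co-transport** out of the cell.  The transporter's pH
  dependence is retained behind `k_MCT_H` but disabled by default
  (`k_MCT_H = 0`), selecting the simplified symmetric form.
* **Malate-aspartate shuttle** (mass action,
  `NADH_cyt + NAD_mit + H_cyt <-> NADH_mit + NAD_cyt + H_mit`) with
  equilibrium constant 10; its rate constants are calibrated so the
  baseline shuttle flux carries the cytosolic NADH production that matches
  normal CMRO2.
* **Lumped TCA step** consuming pyruvate and reducing `n_mitN = 4` matrix
  NAD per pyruvate.
* **Electron transport** with a two-state Cu_A redox pool for cytochrome c
  oxidase: NADH reduces oxidised Cu_A (with exponential thermodynamic
  back-pressure from the proton-motive force) and O2 reoxidises it;
  oxygen consumption is tied to the reoxidation flux.
* **Oxidative phosphorylation**: proton pumping (6 + 4 charges per NADH
  equivalent), an ATP synthase driven by ADP availability and a sigmoidal
  pmf dependence, and an ATP-independent proton leak
  `k_unc * leak_n * exp(k_leak_exp (Dp - Dp_n)/Dp_n)` scaled by the
  uncoupling control `k_unc` (normal 1).  The proton-motive force is
  `Dp = psi + Z (pH_mit - pH_cyt)` with the membrane-potential proxy `psi`
  integrating the net charge flux.  The leak is exponential in `Dp`
  because a linear leak leaves the pmf subsystem unstable against the
  ATP/ADP feedback loop (higher `Dp` -> more ATP -> less ADP -> less
  synthase proton re-entry -> higher `Dp`).
* **Creatine kinase** (`PCr + ADP + H <-> ATP + Cr`, mass action) and a
  saturable ATP turnover `k_use [ATP]/(k_m_use + [ATP])`.

### Proton bookkeeping and buffering

Cytoplasmic proton sources are: glycolysis (`n_glycH = 4` per glucose,
with a calibrated constant background extrusion absorbing the baseline
surplus so that complete glycolysis to *exported* lactate is
proton-neutral), LDH consumption, lactate/H+ co-transport, the shuttle,
net ATP hydrolysis (`f_use - f_synthesis`), creatine kinase, and a weak
setpoint regulation term `k_pHc_reg (pH_cyt - pH_o_n)` representing
Na+/H+ exchange and bicarbonate transport.  Without the export-neutral
stoichiometry the cell alkalinises without bound under sustained
ischaemia and no steady state exists.  Matrix protons balance pumping,
synthase and leak re-entry, shuttle transport, a calibrated TCA proton
yield, water formation at the oxidase, and an electroneutral K+/H+
antiport term pinning matrix pH; the antiport is required because every
pmf-driven flux depends only on `Dp`, leaving the psi-vs-pH_mit split
otherwise unconstrained.

Buffering uses the effective-proton-volume relationship
`R_Hi,c = C_buffi,c (10^-pH - 10^-(pH+dpH))/dpH * Vol_cyt` (and its
mitochondrial analogue).  The printed relationship fixes the pH
*dependence* of buffering; its absolute scale depends on a proton-flux
unit convention that is not reconstructable here, so the package
calibrates the scale to physiological buffering capacities
(`beta_cyt_n = 40`, `beta_mit_n = 2.5` tissue-mM per pH unit at baseline).
`dpH` defaults to 0.001 pH units; whether `Vol_cyt` multiplies or divides
is switchable (`buffer_vol_divides`, default multiply).

### Conservation by construction

The state derivatives are assembled so that five pools are conserved to
machine precision: cytosolic NAD+NADH, mitochondrial NAD+NADH, ATP+ADP,
PCr+Cr, and the exchangeable phosphate pool EPP = [PCr]+[Pi]+2[ATP].
For EPP this requires a bookkeeping convention: chemically the conserved
pool is EPP+[ADP] (the ADP beta-phosphate), so the model books that
phosphate into the Pi pool (`dPi = -dPCr - 2 dATP`).  The discrepancy is
the change in free ADP, tens of micromolar, far below 31P-MRS resolution.

## Cell death

A dead fraction `d_f` in [0, 1) scales the system in three ways: the
oxygen balance becomes `d[O2]/dt = T_O2in / (V_mit (1 - d_f)) - T_box`
(dead cells neither consume oxygen nor contribute functioning
mitochondrial volume; `d_f` is capped at 0.999 to avoid the singularity);
the observables are corrected assuming dead cells hold all exchangeable
phosphate as Pi and their CCO fully reduced:

```
NTP/EPP = (1-d_f) [ATP]/EPP          PCr/EPP = (1-d_f) [PCr]/EPP
Pi/EPP  = (1-d_f) [Pi]/EPP + d_f     dOxCCO  = (1-d_f) dOxCCO_live - d_f oxCCO_n
CMRO2   = (1-d_f) CMRO2_live
```

with `oxCCO_n = CuA_frac_n * CCO_tis` (the normally-oxidised amount —
taken as the reference against which dead, fully-reduced CCO appears).
The identity `2 NTP/EPP + PCr/EPP + Pi/EPP = 1` holds for every `d_f`.
These corrections change predicted measurements only, not the dynamics
(apart from the oxygen equation).

## Observables

NIRS haemoglobin signals use a volume-weighted compartment model: the
arterial volume scales with `r^2`, capillary and venous volumes are fixed
fractions of `V_blood_n`; tissue HbO2/HHb concentrations (uM) combine
compartment saturations with `Hbtot_n`; all delta-signals are zeroed at
the first output sample.  Cytoplasmic pH is reported directly
(`-log10[H+]`), CBF and CMRO2 normalised to baseline.

## Start-up calibration

All rate constants that are not independently known are solved in
`Model.__init__` so that the declared normal state — CBF = 1 flow unit,
pH 7.00, [ATP] 2.2 mM, [PCr] 2.6 mM, PCr/Pi 2.73, oxidised Cu_A fraction
0.67, CMRO2_n — is an exact steady state (residual ~1e-14 relative).
The single flux scale is `q = CMRO2_n / 5`: per five glucose the default
stoichiometry generates ten matrix NADH equivalents and thus five O2.
Changing any normal-value parameter (e.g. when fitting `[ATP]_n` or
`Hbtot_n`) recalibrates the whole model around the new baseline, so
fitted normals shift both the baseline signal levels and the dynamics.

## Numerics

* Time integration: LSODA with per-variable absolute tolerances scaled by
  normal values; default `rtol 1e-7` (1e-5 inside fitting loops, where
  signal errors from the tolerance are below measurement noise by two
  orders); `max_step` bounded so one-minute input features are resolved.
* Steady states: settling integration alternated with a trust-region
  least-squares polish in which the five conserved pools replace their
  (linearly dependent) derivative rows.  The system's timescales span
  milliseconds (CCO redox, ~2 uM pool) to days (the tabulated 409 mM
  cytosolic NAD pool), a ~1e12 stiffness ratio; the default convergence
  tolerance is a residual drift below 1e-6 of each variable's normal
  value per second (under 0.4% per hour), the practical limit for
  finite-difference-based polishing at this conditioning.  Severe inputs
  far outside the physiological envelope (e.g. arterial pressure
  ~20 mmHg) drive the model to a degenerate depleted state; steady-state
  claims are made for the 30–70 mmHg range.
* The tabulated cytosolic pyridine pool ([NAD]=359, [NADH]=50 mM) is kept
  as the default; `ParameterSet.nad_unit_corrected()` provides the
  thousand-fold smaller physiological preset.

## Sensitivity screening

Morris elementary-effects screening (trajectory design): each of `r`
trajectories starts at a random point of a `levels`-level grid (default
4) and changes every parameter once, in random order, by half the grid
span.  Effects are computed on range-normalised parameters; mu* (mean
absolute effect) and sigma (their SD) are aggregated per output, mu* is
normalised per output by its maximum, and parameters with dataset-averaged
normalised mu* >= 0.5 are selected, grouped by the signals they influence.
Failed simulations invalidate only the steps that touch them.  Default
ranges are +/-20% of normal (+/-50% for heuristic constants), clipped to
meaningful bounds; the screening outputs are per-signal RMS errors
against the measurements.

## Fitting

Bound-constrained global-best particle swarm (constriction coefficients
w = 0.729, c1 = c2 = 1.49445; positions clamped at bounds with velocity
reset; deterministic under a fixed seed).  Defaults are 40 particles and
200 iterations with convergence declared after 20 iterations of relative
improvement below 1e-6; the test suite uses a scaled-down swarm
(8 particles, 18 iterations) sized to the synthetic-recovery problem.
Multi-signal objectives sum per-signal RMS errors, each divided by the
measured signal's standard deviation.  The grouped strategy fits, in
order: (Hbtot_n, r_0, V_blood_n) to the haemoglobin signals; pH_o_n to
cytoplasmic pH; (CCO_tis, CuA_frac_n) to the CCO signal; (ATP_n, PCr_n,
PCr_n/Pi_n) to the phosphate fractions — later groups seeing earlier
groups' values.  Scenario fits free the relevant post-insult control
(`post_k_occ`, `post_k_unc`, `post_d_f`) jointly with the CCO and
phosphate groups against the whole time course; the haemoglobin and pH
groups are not re-optimised.  Ensembles repeat fits with distinct seeds
and report per-parameter mean +/- SD and pairwise correlations; the
fitted values of a sloppy model like this one are not unique, and the
ensemble spread is the honest summary.

## Protocol machinery

A `Protocol` defines baseline (default 10 min), a one-minute occlusion
ramp, the insult, a one-minute release ramp, and recovery.  Non-recovery
scenarios override controls after the insult: a persistent `k_occ` ramps
in during the release (so flow never recovers, without a reperfusion
dip); `k_unc` and `d_f` transition linearly over 60 s starting at the end
of the release ramp (the change time is configurable; the original
timing is not documented, and an instantaneous switch would inject a
state discontinuity).

## Synthetic studies

`make_insult_protocol` emulates the experimental insult: SaO2 decays
exponentially (tau = 120 s) to a floor of 0.30 during occlusion and
recovers the same way; arterial pressure is near-constant; both carry
first-order autocorrelated jitter (lag-1 correlation 0.9, 1% marginal SD)
mimicking the minute-to-minute variability of monitored vitals; sampling
is at the experimental 1-minute interval.  Pseudo-measurements add
seeded Gaussian noise with per-signal SD defaulting to 5% of each
signal's dynamic range.  What passing recovery tests shows: the pipeline
can identify a cell-death fraction and discriminate it from flow or
uncoupling explanations *when the generating model is the fitted model*.
It does not show robustness to model misspecification, spatial
heterogeneity, drifting baselines or non-Gaussian artefacts, all of which
real recordings contain.

## Known limitations

* The metabolic core is a documented reduction; pathway intermediates,
  CO2/bicarbonate chemistry, and ion homeostasis beyond the two pH
  regulation terms are absent.  CO2 reactivity of CBF is not implemented.
* Dead tissue is a single static fraction; no secondary energy failure,
  oedema, haematocrit changes or distinct cell populations.
* NIRS signals are ideal tissue concentrations (no optode/path-length
  physics); MRS ratios are noiseless functions of state (no spectral
  fitting), and pH is not derived from chemical shifts.
* Under extreme sustained insults the model settles into a degenerate
  depleted state that should be read as "beyond viability", not as
  physiology.
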