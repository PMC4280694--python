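# Methods

## Model structure

The circulation is a closed-loop lumped-parameter (0D) network.  Every node
of the circuit carries exactly one storage element — a linear compliance
(`P = V/C + P_ref`) or a variable-elastance chamber — so all node pressures
are algebraic functions of the state and no implicit solve is needed.  The
state vector holds the stored volume of each compliance/chamber and the flow
of each inertial branch; resistive and valve flows are algebraic.  Networks
violating the one-storage-per-node rule are rejected with a topology error.

Series resistances that share no storage node are lumped into single
branches: the aortic valve carries the windkessel characteristic resistance
(`Rlo + Rcs`), and the small-pulmonary-artery R/L is lumped with the
arteriolar and capillary resistances (`Rpas + Rpar + Rpc`) between the
small-PA and pulmonary-venous compliances.  This is electrically exact for
this topology.

Pressure references: heart chambers, all pulmonary compartments and the TAL
chambers sit inside the thorax and reference the mean intrathoracic pressure
`Pt = −4 mmHg`; systemic arterial and venous compliances reference ambient
(0 mmHg); the coronary intramyocardial compliance references `γ·P_lv`
(γ = 0.75 by default), which realises the intramyocardial-pump effect:
systolic left-ventricular pressure squeezes the intramural vessels and
shifts coronary inflow into diastole.  Note that with this *linear* coupling
the cycle-mean coronary flow is (to first order) independent of γ — the
mean flow is fixed by the mean aortic-to-atrial gradient; γ shapes the
phase of the flow and hence the CBF-AoP loop, not its mean.

## Heart

Four chambers with `e(t) = Emin + (Emax − Emin)·a(t)` and a single-lobe
raised-cosine activation `a(τ) = (1 − cos 2πτ/Tsys)/2` on `τ ∈ [0, Tsys)`.
The functional form of `a` is a design choice (the source literature for
variable-elastance models admits several); raised-cosine is the simplest
C⁰-continuous shape producing smooth P-V loops.  Timing defaults:
ventricular `Tsys = 0.3·√period` (Bazett-inspired, 0.27 s at 75 bpm); atria
activate for 0.1 s starting 0.16 s before the ventricles (PR-like delay).
Valves are ideal diodes in series with a resistance, so valve flow is never
negative.  An optional linear septal-coupling coefficient (default 0) adds
interventricular cross-talk of transmural pressures; it is an extension
knob, off in every shipped preset.

## Parameters and calibration

None of the virtual-patient parameter values are published with the study
conditions this package reproduces, so the presets are the package's own
calibration, fixed once:

* **Normal preset** (all mmHg·s/ml, ml/mmHg, ml): LV Emax/Emin/V0 =
  2.5/0.08/15, RV 0.7/0.04/15, atria 0.25/0.15/10; valves 0.005 (tricuspid
  0.012 — the right-heart inflow lumps the cavo-atrial junction); windkessel
  Rcs 0.045, Cas 1.3, Ras 0.95; veins Rvs 0.05, Cvs 60; pulmonary Rpam =
  Rpas = 0.005, Lpam = Lpas = 5·10⁻⁴, Cpam = Cpas = 0.6, Rpar 0.09
  (= 120 g·cm⁻⁴·s⁻¹, the "physiological" arteriolar value), Rpc 0.01, Rvp
  0.006, Cvp 9; coronary R_in/C/R_out = 11/0.35/9, γ 0.75; HR 75 bpm,
  Pt −4 mmHg.  At the periodic orbit this lands at CO 4.9 l/min, mean AoP
  80 mmHg, mean PAP 14 mmHg, mean LAP 4 mmHg — textbook values.
* **Pulmonary-hypertensive patient**: built by `calibrate_pulmonary_
  hypertension`, which reduces RV Emax by 30 % and bisects a common scale
  factor on (Rpar, Rpc, Rpas) within [1, 20] until the steady-state mean PAP
  is within 1 mmHg of 35 mmHg; the result must dilate RVEDV by ≥ 20 % over
  the normal preset.  The audit log (scale/PAP pairs) is returned with the
  preset.  With the defaults the bisection settles at scale ≈ 5.16,
  mean PAP 35.9 mmHg, RVEDV +27 %.
* **TAL block**: inlet graft R 0.01, inductances 10⁻⁴, graft compliance 1.5,
  chamber compliances 2.0, fibre-bundle R0 0.02 with quadratic coefficient
  k = 10⁻⁴ mmHg·s²/ml² (mild flow-dependent losses), LA-return graft 0.09,
  distal-PA return graft 0.002, band 2.0 mmHg·s/ml.  The return-graft and
  band values are calibration against the study's printed percentage
  effects: the band is nearly occlusive (hybrid surgical practice), the
  LA-return graft is the flow-limiting element of the shunt, and the
  distal-PA return is a short low-resistance graft.  All are plain config
  fields (`TALParams`) and per-run overridable.
* **Initial state**: capacitor volumes follow nominal starting pressures
  (aorta 85, systemic veins 6, pulmonary veins 5.5, PA 15–16 mmHg), chambers
  start at mid-diastolic volumes.  The periodic orbit depends only on the
  total stressed volume these imply (≈ 1 litre); if a preset states a total
  blood volume the systemic venous reservoir absorbs the difference.

## Numerics

* Explicit Euler, `dt = 10⁻⁴ s`; first-order convergence is verified against
  the RC closed form, and cycle means agree with a classical RK4 on the same
  equations to < 1 %.  The RK4 path exists as a cross-check only.
* "Infinite resistance" (mode switching, disabled branches) is branch
  *removal*, not a large number — no artificial stiffness, flows identically
  zero.  The flow-dependent resistance is inverted with the rationalised
  quadratic root, well-conditioned for k → 0.
* Periodic steady state: whole cycles are integrated until every cycle-mean
  node pressure and every chamber stroke volume changes by < 10⁻³ (relative,
  floored at 0.01 in absolute units) for three consecutive cycles, with a
  minimum of 4 and default maximum of 60 cycles.  The protocol's percent
  changes move by ≲ 0.3 points when the tolerance is tightened to 3·10⁻⁴.
* Divergence guard: any state entry beyond 10⁵ aborts with an instability
  error suggesting a smaller step.  Closed-loop volume is conserved to
  machine precision by construction (every flow enters one node and leaves
  another).
* Determinism: there is no randomness anywhere; identical inputs give
  bit-identical outputs.

## The course protocol

For each arteriolar resistance (240, then 120 g·cm⁻⁴·s⁻¹, converted at
1 mmHg = 1333.22 dyn/cm²) a TAL-off baseline is run, then each mode ×
compliance combination (C_TALin ∈ {1.5, 0.4}, C_TALad = C_TALap ∈
{2.0, 0.1} ml/mmHg); percent changes are taken against the *same-resistance*
baseline, isolating the device effect from the drug (resistance-lowering)
effect.  Nine variables are tabulated: LVEDV, LVESV, RVEDV, RVESV, CO,
mean PAP, mean LAP, mean SVP, CBF-AoP area.  EDV/ESV are per-cycle volume
extrema (equivalent to valve-event timing for diode valves); CO is the LV
stroke volume × HR; loop areas use the shoelace formula on the closed
sampled curve.

A closed-loop consequence worth knowing: at the periodic orbit both
ventricles always eject the same volume per beat, TAL or no TAL — the
PA→LA shunt bypasses the *natural lung*, not the right ventricle, so the
shunt appears as reduced trans-pulmonary (lung) flow rather than as an
LV/RV output difference.

Observed behaviour with the shipped calibration (Rpar = 240): parallel
attachment raises LVEDV/LVESV/CO/mean LAP/CBF-AoP area and lowers
RVEDV/RVESV/mean PAP in all four compliance combinations; parallel mean-PAP
reductions span ≈ 23–32 %, the hybrid best case ≈ 34 %, and hybrid exceeds
parallel for every combination.  One structural property of the mode
algebra deserves emphasis: the hybrid circuit is the parallel circuit plus
one extra monotone branch (the distal-PA return), so at shared device
parameters hybrid can never transport less — its CO gain is always at
least parallel's.  A CO ordering with parallel on top therefore requires
per-mode device settings, which the shared-parameter protocol deliberately
does not use.

## What the virtual patient does and does not emulate

The presets emulate resting haemodynamics of an adult with (calibrated)
pulmonary hypertension and a mildly failing right ventricle.  There is no
baroreflex or autonomic control, no heart-rate variability, no gas exchange
(the TAL is haemodynamic only), no regurgitant/stenotic valves, and no
distributed (1D/3D) wave propagation.  Passing the protocol checks shows the
*directions and relative magnitudes* of TAL effects in a controlled
lumped-parameter setting; it does not validate absolute magnitudes for any
real patient, which would require patient-specific parameters and reflex
control.

## Known limitations

* Percent changes depend on the calibration; the shipped values are one
  defensible operating point, not a fit to any individual.
* The atrial septum is rigid and ventricular interdependence is off by
  default.
* The coronary branch is a single lumped path; layer-specific perfusion and
  autoregulation are out of scope.
* At the drug-mitigated resistance (120 g·cm⁻⁴·s⁻¹) some compliance
  combinations flip the sign of individual variables (e.g. mean PAP under
  parallel attachment with the stiffest chambers), mirroring the mixed
  trends the protocol is designed to expose; only the overloaded-resistance
  directions are asserted.
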