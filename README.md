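# cardiotal

Lumped-parameter (0D) simulation of the human circulation with a pumpless
**thoracic artificial lung (TAL)** attachable to the pulmonary artery in
parallel, series or hybrid mode.

## Who this is for

Patients with severely elevated pulmonary vascular resistance overload the
right ventricle and lose cardiac output; a TAL — a low-resistance gas-exchange
device anastomosed to the pulmonary artery without a blood pump — can unload
the right heart.  How much it helps depends strongly on *how* it is attached
(where the outflow graft returns) and on the device compliances.  `cardiotal`
lets you build a virtual patient, attach the device and quantify the
haemodynamic consequences per cardiac cycle, which makes it useful both for
device-configuration studies and for teaching cardiopulmonary interaction.

## The model

The circulation is an electrical analogue: pressure ↔ voltage, flow ↔
current, vessels ↔ RLC branches.  Each heart chamber follows the
time-varying-elastance law

```
P(t) = e(t) · (V(t) − V0) + Pt,      e(t) = Emin + (Emax − Emin) · a(t)
```

with a raised-cosine activation `a(t)` and the intrathoracic pressure `Pt`
as external reference; valves are ideal diodes in series with a small
resistance, so preload and contractility changes propagate to stroke volume
(Frank–Starling behaviour).  Around the heart sit a three-element windkessel
(systemic arteries), systemic venous RC return, main/small pulmonary artery
RLC segments, arteriolar + capillary resistances, pulmonary venous RC, and a
coronary branch whose intramyocardial compliance is squeezed by `γ·P_lv`
(the intramyocardial pump, which suppresses systolic coronary inflow).

The TAL block is an inlet graft (R, L, graft compliance), two compliant
chambers separated by flow-dependent resistances `ΔP = R0·Q + k·Q·|Q|` (the
fibre bundle), a return graft to the left atrium, a return graft to the
distal pulmonary artery, and a band resistance `R_TALpab` on the native
segment between the anastomoses.  Modes are realised by disabling branches:
**parallel** (PA → TAL → left atrium), **series** (proximal PA → TAL →
distal PA), **hybrid** (both returns open, split governed by the band).

Everything is integrated with explicit Euler at `dt = 0.1 ms` (a classical
RK4 on the same equations ships as a cross-check), cycle by cycle, until the
periodic orbit is reached.

## Worked example

Simulate the normal virtual patient with a parallel TAL after raising the
pulmonary arteriolar resistance to 240 g·cm⁻⁴·s⁻¹ (elevated, ≙ 0.18
mmHg·s/ml):

```sh
$ cardiotal simulate --tal-mode parallel --rpar-cgs 240 --out waves.csv
{
  "cycles": 15,
  "LVEDV": 132.0119542612547,
  "LVESV": 62.45151802864605,
  "RVEDV": 136.07808944883175,
  "RVESV": 66.51607967250216,
  "CO": 5.217032717445648,
  "mean PAP": 18.0402790445158,
  "mean LAP": 4.519599733629868,
  "mean SVP": 5.893599735635064,
  "CBF-AoP area": 361.5634987739516,
  "mean AoP": 84.563174681365
}
```

The run converged in 15 cardiac cycles.  Volumes are in ml, pressures in
mmHg, cardiac output (CO) in l/min; "CBF-AoP area" is the area of the
coronary-blood-flow vs aortic-pressure loop (mmHg·ml/s), an index of coronary
perfusion dynamics.  `waves.csv` holds every pressure, flow and volume
waveform of the final cycle.  Despite the stiff arterioles, the shunt keeps
CO at 5.2 l/min and mean PAP at 18 mmHg.

For the full study — calibrate a pulmonary-hypertensive patient (mean PAP
35 mmHg, dilated right ventricle), then sweep {parallel, hybrid} ×
Rpar {240, 120} g·cm⁻⁴·s⁻¹ × TAL compliances {1.5, 0.4} × {2.0, 0.1}
ml/mmHg against per-resistance baselines:

```sh
$ cardiotal protocol --out percent_changes.csv
```

which prints a signed percent-change table (18 rows) and a directional
report.  In parallel mode at Rpar = 240 the model shows the expected
pattern: left ventricular volumes, CO, mean left atrial pressure and
CBF-AoP area all rise, right ventricular volumes and mean pulmonary
arterial pressure fall; the hybrid attachment lowers mean PAP further than
the parallel one.

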