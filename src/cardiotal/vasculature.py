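"""Full closed-loop circulation: systemic, pulmonary and coronary sections.

The circuit implements, section by section:

* left and right heart - four variable-elastance chambers and four diode
  valves (:mod:`cardiotal.heart`);
* systemic arterial tree - three-element windkessel (characteristic
  resistance in series with the aortic valve, arterial compliance, variable
  peripheral resistance);
* systemic veins - compliance plus a variable venous resistance back to the
  right atrium;
* main and small pulmonary artery - two RLC segments referenced to
  intrathoracic pressure;
* pulmonary arterioles and capillaries - pure resistances in series with the
  small-artery segment;
* pulmonary veins - RC element returning to the left atrium;
* coronary circulation - inflow resistance from the aortic node into an
  intramyocardial compliance squeezed by gamma * P_lv (the "intramyocardial
  pump": systolic ventricular pressure impedes coronary inflow), draining
  into the right atrium.

Heart chambers, pulmonary compartments (and any TAL chambers) are referenced
to the mean intrathoracic pressure Pt; systemic compliances to ambient.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import circuits
from .circuits import (Network, State, capacitor, chamber, inductive,
                       resistor, valve)
from .heart import HeartParams, normal_heart
from .tal import TALParams, attach_tal

__all__ = [
    "SystemicParams",
    "PulmonaryParams",
    "CoronaryParams",
    "PatientPreset",
    "build_full_network",
    "initial_state",
    "cgs_resistance_to_internal",
    "intramyocardial_pressure",
    "set_parameter",
    "normal_preset",
    "PARAMETER_SYMBOLS",
]

logger = logging.getLogger(__name__)

#: 1 mmHg = 1333.22 dyn/cm^2, and dyn*s/cm^5 is the same unit as g*cm^-4*s^-1
DYN_PER_CM2_PER_MMHG = 1333.22

_CGS_UNIT_SPELLINGS = {
    "cgs", "g.cm-4.s-1", "g*cm-4*s-1", "g·cm⁻⁴·s⁻¹", "dyn.s.cm-5",
    "dyn*s/cm5",
}


def cgs_resistance_to_internal(r_cgs: float) -> float:
    """Convert a resistance from g*cm^-4*s^-1 (CGS) to mmHg*s/ml."""
    if r_cgs < 0:
        raise ValueError("resistance must be >= 0")
    return r_cgs / DYN_PER_CM2_PER_MMHG


def intramyocardial_pressure(p_lv: float, gamma: float) -> float:
    """External pressure squeezing the intramyocardial compliance.

    P_im = gamma * P_lv; with gamma > 0 coronary inflow is impeded during
    systole (the intramyocardial pump effect).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return gamma * p_lv


@dataclass(frozen=True)
class SystemicParams:
    """Three-element windkessel plus venous return (mmHg*s/ml, ml/mmHg)."""

    Rcs: float = 0.045  # characteristic resistance
    Cas: float = 1.3  # arterial compliance
    Ras: float = 0.95  # peripheral resistance (variable)
    Rvs: float = 0.05  # venous resistance (variable)
    Cvs: float = 60.0  # venous compliance

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class PulmonaryParams:
    """Main/small pulmonary artery RLC, arteriolar/capillary R, venous RC."""

    Rpam: float = 0.005
    Lpam: float = 5e-4
    Cpam: float = 0.6
    Rpas: float = 0.005
    Lpas: float = 5e-4
    Cpas: float = 0.6
    Rpar: float = 0.09  # arteriolar resistance (the protocol's main knob)
    Rpc: float = 0.01  # capillary resistance
    Rvp: float = 0.006
    Cvp: float = 9.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class CoronaryParams:
    """Intramyocardial-pump coronary branch."""

    R_in: float = 11.0
    C: float = 0.35
    R_out: float = 9.0
    gamma: float = 0.75  # fraction of LV pressure squeezing the compliance

    def __post_init__(self):
        if self.R_in <= 0 or self.R_out <= 0 or self.C <= 0:
            raise ValueError("coronary resistances and compliance must be > 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


#: starting pressures (mmHg) / chamber volumes (ml) used to seed a run;
#: the periodic orbit the solver converges to does not depend on the exact
#: split, only on the total stored volume they imply
DEFAULT_INITIAL_PRESSURES: Mapping[str, float] = {
    "as": 85.0, "vs": 6.0, "vp": 5.5, "pam": 16.0, "pas": 15.0, "cor": 40.0,
    "talin": 15.0, "talad": 15.0, "talap": 15.0,
}
DEFAULT_INITIAL_CHAMBER_VOLUMES: Mapping[str, float] = {
    "LA": 40.0, "LV": 105.0, "RA": 40.0, "RV": 105.0,
}


@dataclass(frozen=True)
class PatientPreset:
    """Complete parameterisation of one virtual patient."""

    label: str
    heart: HeartParams
    systemic: SystemicParams = field(default_factory=SystemicParams)
    pulmonary: PulmonaryParams = field(default_factory=PulmonaryParams)
    coronary: CoronaryParams = field(default_factory=CoronaryParams)
    Pt: float = -4.0  # mean intrathoracic pressure, mmHg
    total_blood_volume: float | None = None  # stressed volume, ml
    tal: TALParams | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.tal is None:
            d.pop("tal")
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatientPreset":
        d = dict(d)
        heart = d.pop("heart")
        from .heart import ChamberParams, ValveParams  # local to avoid cycle
        chambers = {k: ChamberParams(**heart.pop(k))
                    for k in ("la", "lv", "ra", "rv")}
        valves = {k: ValveParams(**heart.pop(k))
                  for k in ("mitral", "aortic", "tricuspid", "pulmonary")}
        d["heart"] = HeartParams(**heart, **chambers, **valves)
        for key, typ in (("systemic", SystemicParams),
                         ("pulmonary", PulmonaryParams),
                         ("coronary", CoronaryParams)):
            d[key] = typ(**d[key])
        if d.get("tal") is not None:
            d["tal"] = TALParams(**d["tal"])
        return cls(**d)


def build_full_network(preset: PatientPreset) -> Network:
    """Assemble the full electrical analogue for a patient preset."""
    h = preset.heart
    s = preset.systemic
    p = preset.pulmonary
    c = preset.coronary
    elements = [
        # heart
        chamber("LA", "la", h.la.Emax, h.la.Emin, h.la.V0, h.la.onset,
                h.la.Tsys),
        chamber("LV", "lv", h.lv.Emax, h.lv.Emin, h.lv.V0, h.lv.onset,
                h.lv.Tsys),
        chamber("RA", "ra", h.ra.Emax, h.ra.Emin, h.ra.V0, h.ra.onset,
                h.ra.Tsys),
        chamber("RV", "rv", h.rv.Emax, h.rv.Emin, h.rv.V0, h.rv.onset,
                h.rv.Tsys),
        valve("Rli", "la", "lv", h.mitral.R),
        # the windkessel characteristic resistance sits in series with the
        # aortic valve, so the open-valve branch carries Rlo + Rcs
        valve("Rlo", "lv", "as", h.aortic.R + s.Rcs),
        valve("Rri", "ra", "rv", h.tricuspid.R),
        valve("Rro", "rv", "pam", h.pulmonary.R),
        # systemic
        capacitor("Cas", "as", s.Cas, ref="ambient"),
        resistor("Ras", "as", "vs", s.Ras),
        capacitor("Cvs", "vs", s.Cvs, ref="ambient"),
        resistor("Rvs", "vs", "ra", s.Rvs),
        # pulmonary
        capacitor("Cpam", "pam", p.Cpam, ref="intrathoracic"),
        inductive("Rpam", "pam", "pas", p.Rpam, p.Lpam),
        capacitor("Cpas", "pas", p.Cpas, ref="intrathoracic"),
        # small-artery R/L in series with the arteriolar and capillary
        # resistances (no storage separates them in this topology)
        inductive("Rlung", "pas", "vp", p.Rpas + p.Rpar + p.Rpc, p.Lpas),
        capacitor("Cvp", "vp", p.Cvp, ref="intrathoracic"),
        resistor("Rvp", "vp", "la", p.Rvp),
        # coronary
        resistor("Rcor_in", "as", "cor", c.R_in),
        capacitor("Ccor", "cor", c.C, ref="intramyocardial"),
        resistor("Rcor_out", "cor", "ra", c.R_out),
    ]
    aliases = {
        "Pla": "P:la", "Plv": "P:lv", "Pra": "P:ra", "Prv": "P:rv",
        "Pas": "P:as", "AoP": "P:as", "Pvs": "P:vs", "Ppam": "P:pam",
        "Ppas": "P:pas", "Pvp": "P:vp", "Pcor": "P:cor",
        "Qli": "Q:Rli", "Qlo": "Q:Rlo", "Qri": "Q:Rri", "Qro": "Q:Rro",
        "Qlia": "Q:Rvp", "Qria": "Q:Rvs", "Qas": "Q:Ras",
        "Qpam": "Q:Rpam", "Qnl": "Q:Rlung",
        "Qcor": "Q:Rcor_in", "Qcor_out": "Q:Rcor_out",
        "Vla": "V:LA", "Vlv": "V:LV", "Vra": "V:RA", "Vrv": "V:RV",
    }
    net = Network(
        name=preset.label,
        elements=elements,
        pt=preset.Pt,
        period=h.period,
        gamma=c.gamma,
        lv_chamber="LV",
        rv_chamber="RV",
        septal_coupling=h.septal_coupling,
        aliases=aliases,
    )
    if preset.tal is not None:
        net = attach_tal(net, preset.tal)
    return net


def initial_state(preset: PatientPreset,
                  network: Network | None = None) -> State:
    """Initial volumes from nominal pressures, honouring total blood volume.

    Capacitor volumes follow V = C * (P - P_ref) from the nominal starting
    pressures; chamber volumes are set directly.  If the preset states a
    total (stressed) blood volume, the systemic venous reservoir absorbs the
    difference; the implied total must then match the stated one to 1 ml by
    construction.
    """
    if network is None:
        network = build_full_network(preset)
    compiled = network.compiled()
    values: dict[str, float] = {}
    # chamber pressures at t=0 feed the intramyocardial reference
    lv_v = DEFAULT_INITIAL_CHAMBER_VOLUMES["LV"]
    lv = preset.heart.lv
    plv0 = lv.elastance(0.0, preset.heart.period) * (lv_v - lv.V0) + preset.Pt
    refs = {"ambient": 0.0, "intrathoracic": preset.Pt,
            "intramyocardial": preset.coronary.gamma * plv0}
    for el in compiled.storages:
        if el.kind == "chamber":
            values[f"V:{el.name}"] = DEFAULT_INITIAL_CHAMBER_VOLUMES[el.name]
        else:
            p0 = DEFAULT_INITIAL_PRESSURES[el.node_a]
            values[f"V:{el.name}"] = el.params["C"] * (p0 - refs[el.pressure_ref])
    implied = sum(values.values())
    if preset.total_blood_volume is not None:
        diff = preset.total_blood_volume - implied
        new_vs = values["V:Cvs"] + diff
        if new_vs <= 0:
            raise ValueError("total blood volume too small for this preset")
        values["V:Cvs"] = new_vs
    return circuits.make_state(network, values)


def implied_blood_volume(preset: PatientPreset) -> float:
    """Total stressed volume implied by the preset's starting pressures."""
    st = initial_state(preset)
    n = len(build_full_network(preset).compiled().storages)
    return float(np.sum(st.values[:n]))


# --- named-parameter access ---------------------------------------------------

#: Table of settable parameters: symbol -> (section path, kind)
PARAMETER_SYMBOLS: dict[str, tuple[tuple[str, ...], str]] = {
    # heart
    "HR": (("heart", "heart_rate"), "rate"),
    "Rli": (("heart", "mitral", "R"), "resistance"),
    "Rlo": (("heart", "aortic", "R"), "resistance"),
    "Rri": (("heart", "tricuspid", "R"), "resistance"),
    "Rro": (("heart", "pulmonary", "R"), "resistance"),
    # systemic
    "Rcs": (("systemic", "Rcs"), "resistance"),
    "Cas": (("systemic", "Cas"), "compliance"),
    "Ras": (("systemic", "Ras"), "resistance"),
    "Rvs": (("systemic", "Rvs"), "resistance"),
    "Cvs": (("systemic", "Cvs"), "compliance"),
    # pulmonary
    "Rpam": (("pulmonary", "Rpam"), "resistance"),
    "Lpam": (("pulmonary", "Lpam"), "inertance"),
    "Cpam": (("pulmonary", "Cpam"), "compliance"),
    "Rpas": (("pulmonary", "Rpas"), "resistance"),
    "Lpas": (("pulmonary", "Lpas"), "inertance"),
    "Cpas": (("pulmonary", "Cpas"), "compliance"),
    "Rpar": (("pulmonary", "Rpar"), "resistance"),
    "Rpc": (("pulmonary", "Rpc"), "resistance"),
    "Rvp": (("pulmonary", "Rvp"), "resistance"),
    "Cvp": (("pulmonary", "Cvp"), "compliance"),
    # coronary
    "Rcor_in": (("coronary", "R_in"), "resistance"),
    "Ccor": (("coronary", "C"), "compliance"),
    "Rcor_out": (("coronary", "R_out"), "resistance"),
    "gamma": (("coronary", "gamma"), "fraction"),
    # environment
    "Pt": (("Pt",), "pressure"),
    # TAL
    "RTALin": (("tal", "R_in"), "resistance"),
    "LTALin": (("tal", "L_in"), "inertance"),
    "CTALin": (("tal", "C_in"), "compliance"),
    "CTALad": (("tal", "C_ad"), "compliance"),
    "RTALad": (("tal", "R_ad0"), "resistance"),
    "CTALap": (("tal", "C_ap"), "compliance"),
    "RTALap": (("tal", "R_ap0"), "resistance"),
    "RTALala": (("tal", "R_ala"), "resistance"),
    "LTALala": (("tal", "L_ala"), "inertance"),
    "RTALan": (("tal", "R_an"), "resistance"),
    "LTALan": (("tal", "L_an"), "inertance"),
    "RTALpab": (("tal", "R_pab"), "resistance"),
}


class UnknownParameterError(KeyError):
    pass


class UnitError(ValueError):
    pass


def get_parameter(preset: PatientPreset, symbol: str) -> float:
    if symbol not in PARAMETER_SYMBOLS:
        raise UnknownParameterError(
            f"unknown parameter {symbol!r}; valid symbols:"
            f" {', '.join(sorted(PARAMETER_SYMBOLS))}")
    path, _ = PARAMETER_SYMBOLS[symbol]
    obj = preset
    for name in path:
        obj = getattr(obj, name)
    return obj


def set_parameter(preset: PatientPreset, symbol: str, value: float,
                  units: str | None = None) -> PatientPreset:
    """Return a copy of the preset with one named parameter changed.

    ``units`` defaults to the internal units (mmHg, s, ml and their
    combinations).  Resistances additionally accept CGS units
    (g*cm^-4*s^-1, e.g. ``units="cgs"``), converted on the spot.
    """
    if symbol not in PARAMETER_SYMBOLS:
        raise UnknownParameterError(
            f"unknown parameter {symbol!r}; valid symbols:"
            f" {', '.join(sorted(PARAMETER_SYMBOLS))}")
    path, kind = PARAMETER_SYMBOLS[symbol]
    if units is not None:
        if units in _CGS_UNIT_SPELLINGS:
            if kind != "resistance":
                raise UnitError(
                    f"{symbol} is a {kind}, not a resistance;"
                    " CGS resistance units do not apply")
            value = cgs_resistance_to_internal(value)
        else:
            raise UnitError(f"unsupported units {units!r}; pass internal"
                            " units (mmHg, s, ml) or CGS resistance units")
    if path[0] == "tal" and preset.tal is None:
        raise UnknownParameterError(
            f"{symbol} refers to the TAL but the preset has no TAL block")

    def _set(obj, names, val):
        if len(names) == 1:
            return replace(obj, **{names[0]: val})
        child = _set(getattr(obj, names[0]), names[1:], val)
        return replace(obj, **{names[0]: child})

    logger.info("set %s = %g on preset %r", symbol, value, preset.label)
    return _set(preset, list(path), value)


def normal_preset(heart_rate: float = 75.0) -> PatientPreset:
    """The calibrated normal adult: AoP ~70-105 mmHg, CO ~4-6.5 l/min."""
    return PatientPreset(label="normal", heart=normal_heart(heart_rate))
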