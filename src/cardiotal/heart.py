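"""Time-varying elastance heart: four chambers, four diode valves, timing.

Each chamber obeys P = e(t)*(V - V0) + Pt with e(t) = Emin + (Emax-Emin)*a(t)
and a single-lobe raised-cosine activation a(t).  This minimal formulation
reproduces the Frank-Starling behaviour relevant here: raising filling
(preload) or Emax (contractility) raises stroke volume.  Valves are ideal
diodes in series with a small resistance, so valve flow is never negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ChamberParams",
    "ValveParams",
    "HeartParams",
    "activation_fraction",
    "chamber_elastance",
    "chamber_pressure",
    "valve_flow",
    "normal_heart",
]

# timing defaults: ventricular systole scales with sqrt(period)
# (Bazett-like), atrial systole is a fixed 0.1 s burst preceding it
ATRIAL_DELAY = 0.16  # s between atrial and ventricular activation onset
ATRIAL_TSYS = 0.10  # s


def activation_fraction(t: float, onset: float, tsys: float,
                        period: float) -> float:
    """Raised-cosine activation in [0, 1].

    a(tau) = (1 - cos(2*pi*tau/Tsys))/2 for tau = (t - onset) mod period in
    [0, Tsys), zero otherwise; continuous and peaking at exactly 1 at
    tau = Tsys/2.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    tau = (t - onset) % period
    if tau < tsys:
        return 0.5 * (1.0 - math.cos(2.0 * math.pi * tau / tsys))
    return 0.0


def chamber_elastance(a: float, emax: float, emin: float) -> float:
    """e = Emin + (Emax - Emin) * a for an activation fraction a in [0, 1]."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation fraction must lie in [0, 1]")
    return emin + (emax - emin) * a


def chamber_pressure(v: float, e: float, v0: float, p_ref: float) -> float:
    """P = e*(V - V0) + P_ref; negative transmural pressure (suction) is fine."""
    return e * (v - v0) + p_ref


def valve_flow(p_up: float, p_down: float, r: float) -> float:
    """Ideal diode in series with R: Q = (Pup - Pdown)/R if Pup > Pdown else 0."""
    if r <= 0:
        raise ValueError("valve resistance must be > 0")
    return (p_up - p_down) / r if p_up > p_down else 0.0


@dataclass(frozen=True)
class ChamberParams:
    """Variable-elastance chamber (mmHg/ml, ml, s)."""

    Emax: float
    Emin: float
    V0: float
    onset: float = 0.0  # activation onset within the cycle
    Tsys: float = 0.3  # active duration

    def __post_init__(self):
        if not (self.Emax >= self.Emin > 0.0):
            raise ValueError("need Emax >= Emin > 0")
        if self.Tsys <= 0.0:
            raise ValueError("Tsys must be > 0")
        if self.onset < 0.0:
            raise ValueError("onset must be >= 0")

    def elastance(self, t: float, period: float) -> float:
        a = activation_fraction(t, self.onset, self.Tsys, period)
        return chamber_elastance(a, self.Emax, self.Emin)


@dataclass(frozen=True)
class ValveParams:
    R: float  # mmHg*s/ml

    def __post_init__(self):
        if self.R <= 0.0:
            raise ValueError("valve resistance must be > 0")


@dataclass(frozen=True)
class HeartParams:
    """Four chambers, four valves and the activation clock."""

    heart_rate: float  # bpm
    la: ChamberParams
    lv: ChamberParams
    ra: ChamberParams
    rv: ChamberParams
    mitral: ValveParams = field(default_factory=lambda: ValveParams(0.005))
    aortic: ValveParams = field(default_factory=lambda: ValveParams(0.005))
    # the right-heart inflow lumps the valve with the cavo-atrial junction,
    # hence the slightly larger default
    tricuspid: ValveParams = field(default_factory=lambda: ValveParams(0.012))
    pulmonary: ValveParams = field(default_factory=lambda: ValveParams(0.005))
    septal_coupling: float = 0.0  # optional extension knob, off by default

    def __post_init__(self):
        if self.heart_rate <= 0.0:
            raise ValueError("heart rate must be > 0")
        if not 0.0 <= self.septal_coupling < 1.0:
            raise ValueError("septal coupling must lie in [0, 1)")
        for c in (self.la, self.lv, self.ra, self.rv):
            if c.onset >= self.period or c.Tsys >= self.period:
                raise ValueError("chamber timing must fit within the period")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


def normal_heart(heart_rate: float = 75.0) -> HeartParams:
    """Normal adult heart; elastances place the preset in textbook ranges."""
    period = 60.0 / heart_rate
    tsys_v = 0.3 * math.sqrt(period)
    v_onset = ATRIAL_DELAY
    return HeartParams(
        heart_rate=heart_rate,
        la=ChamberParams(Emax=0.25, Emin=0.15, V0=10.0, onset=0.0,
                         Tsys=ATRIAL_TSYS),
        ra=ChamberParams(Emax=0.25, Emin=0.15, V0=10.0, onset=0.0,
                         Tsys=ATRIAL_TSYS),
        lv=ChamberParams(Emax=2.5, Emin=0.08, V0=15.0, onset=v_onset,
                         Tsys=tsys_v),
        rv=ChamberParams(Emax=0.7, Emin=0.04, V0=15.0, onset=v_onset,
                         Tsys=tsys_v),
    )
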