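"""Per-cycle haemodynamic summaries and percentage-change tables.

End-diastolic / end-systolic volumes are the per-cycle extrema of the
ventricular volume (equivalent to valve-event timing for diode valves and
robust at flow reversal).  Cardiac output is reported from the left
ventricular stroke volume, the clinical convention.  Note that at the
periodic orbit of this closed loop both ventricles eject the same volume per
beat even with a TAL attached: the left-atrial return bypasses the natural
lung, not the right ventricle, so the shunt shows up as reduced lung flow,
not as an LV/RV output difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import SimulationResult

__all__ = [
    "VARIABLES",
    "CycleSummary",
    "PercentChangeTable",
    "cycle_mean",
    "edv_esv",
    "cardiac_output",
    "loop_area",
    "percent_change",
    "summarize_cycle",
]

#: the nine analysed haemodynamic variables, in reporting order
VARIABLES = ("LVEDV", "LVESV", "RVEDV", "RVESV", "CO", "mean PAP",
             "mean LAP", "mean SVP", "CBF-AoP area")

KEY_COLUMNS = ("mode", "Rpar_cgs", "CTALin", "CTALchambers")


def _window(series: np.ndarray, window) -> slice:
    i0, i1 = window
    if i1 <= i0 or i1 > len(series):
        raise ValueError("cycle window is empty or outside the series")
    return slice(i0, i1)


def cycle_mean(time: np.ndarray, series: np.ndarray, window) -> float:
    """Time-weighted (trapezoidal) mean of a waveform over a cycle window."""
    sl = _window(series, window)
    t = time[sl]
    if len(t) < 2:
        raise ValueError("cycle window must contain at least two samples")
    return float(np.trapezoid(series[sl], t) / (t[-1] - t[0]))


def edv_esv(volume: np.ndarray, window) -> tuple[float, float]:
    """(EDV, ESV) = (max, min) of a ventricular volume over one cycle."""
    sl = _window(volume, window)
    v = volume[sl]
    return float(v.max()), float(v.min())


def cardiac_output(edv: float, esv: float, heart_rate: float) -> float:
    """CO [l/min] = (EDV - ESV) [ml] * HR [bpm] / 1000."""
    if edv < esv:
        raise ValueError("EDV must be >= ESV")
    return (edv - esv) * heart_rate / 1000.0


def loop_area(x: np.ndarray, y: np.ndarray, window=None) -> float:
    """Signed shoelace area of the closed (x, y) loop over one cycle.

    The curve is closed by joining the last sample back to the first;
    positive sign means counter-clockwise orientation.
    """
    if window is not None:
        sl = _window(x, window)
        x, y = x[sl], y[sl]
    if len(x) != len(y):
        raise ValueError("x and y must share a grid")
    if len(x) < 3:
        raise ValueError("a loop needs at least 3 points")
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def percent_change(baseline: float, assisted: float) -> float:
    """Signed percent change, 100 * (assisted - baseline) / baseline."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (assisted - baseline) / baseline


@dataclass(frozen=True)
class CycleSummary:
    """Haemodynamic means and per-beat volumes over one converged cycle."""

    cycle_index: int
    lvedv: float
    lvesv: float
    rvedv: float
    rvesv: float
    co: float  # l/min, from LV stroke volume
    mean_pap: float  # cycle-mean main pulmonary artery pressure, mmHg
    mean_lap: float
    mean_svp: float
    mean_aop: float
    mean_cbf: float  # cycle-mean coronary inflow, ml/s
    cbf_aop_area: float  # magnitude of the CBF-AoP loop area, mmHg*ml/s

    def __post_init__(self):
        if self.lvedv < self.lvesv or self.rvedv < self.rvesv:
            raise ValueError("EDV must be >= ESV")
        if self.co < 0:
            raise ValueError("CO must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "LVEDV": self.lvedv, "LVESV": self.lvesv,
            "RVEDV": self.rvedv, "RVESV": self.rvesv, "CO": self.co,
            "mean PAP": self.mean_pap, "mean LAP": self.mean_lap,
            "mean SVP": self.mean_svp, "CBF-AoP area": self.cbf_aop_area,
        }


def summarize_cycle(result: SimulationResult, heart_rate: float,
                    cycle: int = -1) -> CycleSummary:
    """Summarise one cardiac cycle of a simulation result.

    ``cycle`` indexes the cycles delimited by ``result.cycle_boundaries``;
    the default is the last complete cycle.
    """
    b = result.cycle_boundaries
    if len(b) < 2:
        window = (0, len(result.time))
        idx = 0
    else:
        windows = list(zip(b[:-1], b[1:] + 1))
        idx = range(len(windows))[cycle]
        window = windows[cycle]
    t = result.time
    lvedv, lvesv = edv_esv(result["Vlv"], window)
    rvedv, rvesv = edv_esv(result["Vrv"], window)
    sl = slice(*window)
    area = loop_area(result["Qcor"][sl], result["AoP"][sl])
    return CycleSummary(
        cycle_index=idx,
        lvedv=lvedv, lvesv=lvesv, rvedv=rvedv, rvesv=rvesv,
        co=cardiac_output(lvedv, lvesv, heart_rate),
        mean_pap=cycle_mean(t, result["Ppam"], window),
        mean_lap=cycle_mean(t, result["Pla"], window),
        mean_svp=cycle_mean(t, result["Pvs"], window),
        mean_aop=cycle_mean(t, result["AoP"], window),
        mean_cbf=cycle_mean(t, result["Qcor"], window),
        cbf_aop_area=abs(area),
    )


@dataclass
class PercentChangeTable:
    """Signed percent changes of the analysed variables per protocol run.

    Rows are keyed by (mode, Rpar in CGS units, C_TALin, C_TALad = C_TALap);
    baseline rows (mode ``"baseline"``) are identically zero by construction.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in KEY_COLUMNS + VARIABLES
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"table is missing columns: {missing}")

    def get(self, mode: str, rpar_cgs: float, ctal_in: float | None = None,
            ctal_chambers: float | None = None) -> pd.DataFrame:
        d = self.data
        m = (d["mode"] == mode) & (d["Rpar_cgs"] == rpar_cgs)
        if ctal_in is not None:
            m &= d["CTALin"] == ctal_in
        if ctal_chambers is not None:
            m &= d["CTALchambers"] == ctal_chambers
        return d[m]

    def value(self, mode: str, rpar_cgs: float, ctal_in: float,
              ctal_chambers: float, variable: str) -> float:
        rows = self.get(mode, rpar_cgs, ctal_in, ctal_chambers)
        if len(rows) != 1:
            raise KeyError(
                f"no unique row for ({mode}, {rpar_cgs}, {ctal_in},"
                f" {ctal_chambers})")
        return float(rows.iloc[0][variable])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)
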