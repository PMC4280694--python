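"""Pulmonary-hypertensive virtual patient and the TAL training protocol.

The pathological baseline reproduces right-ventricular pressure overload:
elevated mean pulmonary arterial pressure and a dilated right ventricle.
It is built from the normal preset by reducing right-ventricular
contractility and scaling the distal pulmonary resistances (arteriolar,
capillary, small-artery) by a common factor found by bisection against a
target mean PAP.

The protocol then sets the pulmonary arteriolar resistance to 240 (overload)
or 120 (drug-mitigated) g*cm^-4*s^-1, and applies the TAL in parallel and
hybrid mode at the four combinations of device compliances
C_TALin in {1.5, 0.4} and C_TALad = C_TALap in {2.0, 0.1} ml/mmHg.  Every
assisted run is compared against the TAL-off baseline at the same arteriolar
resistance, isolating the device effect from the drug effect.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .circuits import (DEFAULT_DT, NonConvergenceError,
                       run_to_periodic_steady_state)
from .cycles import (VARIABLES, PercentChangeTable, percent_change,
                     summarize_cycle)
from .tal import TALParams, configure_tal
from .vasculature import (PatientPreset, build_full_network, initial_state,
                          set_parameter)

__all__ = [
    "ProtocolSpec",
    "DirectionalExpectation",
    "PARALLEL_EXPECTED_SIGNS",
    "CalibrationError",
    "ProtocolError",
    "CalibrationLog",
    "run_steady",
    "calibrate_pulmonary_hypertension",
    "run_course_protocol",
    "directional_check",
]

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    pass


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class ProtocolSpec:
    """The course's factorial sweep: 2 modes x 2 Rpar x 2 x 2 compliances."""

    modes: tuple[str, ...] = ("parallel", "hybrid")
    rpar_cgs: tuple[float, ...] = (240.0, 120.0)
    c_tal_in: tuple[float, ...] = (1.5, 0.4)
    c_tal_chambers: tuple[float, ...] = (2.0, 0.1)
    variables: tuple[str, ...] = VARIABLES

    def runs(self):
        """Yield (rpar, mode, c_in, c_chambers) cells, baselines excluded."""
        return itertools.product(self.rpar_cgs, self.modes, self.c_tal_in,
                                 self.c_tal_chambers)


#: expected sign of each percent change under parallel TAL assistance at the
#: overloaded (240 g*cm^-4*s^-1) arteriolar resistance
PARALLEL_EXPECTED_SIGNS: dict[str, int] = {
    "LVEDV": +1, "LVESV": +1, "RVEDV": -1, "RVESV": -1, "CO": +1,
    "mean PAP": -1, "CBF-AoP area": +1, "mean LAP": +1,
}


@dataclass(frozen=True)
class DirectionalExpectation:
    """Expected percent-change signs per (mode, variable)."""

    signs: dict[str, int] = field(
        default_factory=lambda: dict(PARALLEL_EXPECTED_SIGNS))
    mode: str = "parallel"
    rpar_cgs: float = 240.0


def run_steady(preset: PatientPreset, dt: float = DEFAULT_DT,
               tol: float = 1e-3, max_cycles: int = 60,
               record_every: int = 1):
    """Build, integrate to the periodic orbit and summarise one preset."""
    net = build_full_network(preset)
    state = initial_state(preset, net)
    result, cycles = run_to_periodic_steady_state(
        net, state, dt=dt, tol=tol, max_cycles=max_cycles,
        record_every=record_every)
    summary = summarize_cycle(result, preset.heart.heart_rate)
    return result, summary, cycles


@dataclass
class CalibrationLog:
    """Audit trail of the bisection: (scale, achieved mean PAP) pairs."""

    target_mean_pap: float
    rv_emax_reduction: float
    iterations: list[tuple[float, float]] = field(default_factory=list)
    final_scale: float = 1.0
    achieved_mean_pap: float = float("nan")
    normal_rvedv: float = float("nan")
    achieved_rvedv: float = float("nan")


def _scaled_preset(normal: PatientPreset, scale: float,
                   rv_emax_reduction: float) -> PatientPreset:
    p = normal
    for symbol in ("Rpar", "Rpc", "Rpas"):
        from .vasculature import get_parameter
        p = set_parameter(p, symbol, get_parameter(normal, symbol) * scale)
    rv = dataclasses.replace(
        p.heart.rv, Emax=normal.heart.rv.Emax * (1.0 - rv_emax_reduction))
    heart = dataclasses.replace(p.heart, rv=rv)
    return dataclasses.replace(p, heart=heart,
                               label=f"{normal.label}-ph(x{scale:.3f})")


def calibrate_pulmonary_hypertension(
        normal: PatientPreset,
        target_mean_ppam: float = 35.0,
        target_rv_dilation: float = 0.20,
        rv_emax_reduction: float = 0.30,
        dt: float = DEFAULT_DT,
        tol: float = 1e-3,
        max_cycles: int = 60,
        scale_bounds: tuple[float, float] = (1.0, 20.0),
        pressure_tol: float = 1.0,
        max_iter: int = 40,
) -> tuple[PatientPreset, CalibrationLog]:
    """Calibrate the pulmonary-hypertensive virtual patient.

    Bisection on a common scale factor applied to (Rpar, Rpc, Rpas), with the
    right-ventricular Emax reduced by ``rv_emax_reduction``, until the
    steady-state mean pulmonary arterial pressure lies within
    ``pressure_tol`` mmHg of the target.  The calibrated preset must also
    dilate the right ventricle (RVEDV) by at least ``target_rv_dilation``
    over the normal preset.  Raises :class:`CalibrationError` when the target
    is unreachable within ``scale_bounds``.
    """
    log = CalibrationLog(target_mean_pap=target_mean_ppam,
                         rv_emax_reduction=rv_emax_reduction)
    _, normal_summary, _ = run_steady(normal, dt=dt, tol=tol,
                                      max_cycles=max_cycles)
    log.normal_rvedv = normal_summary.rvedv
    if target_mean_ppam < normal_summary.mean_pap - pressure_tol:
        raise CalibrationError(
            f"target mean PAP {target_mean_ppam} mmHg is below the normal"
            f" preset's {normal_summary.mean_pap:.1f} mmHg")

    def evaluate(scale: float):
        preset = _scaled_preset(normal, scale, rv_emax_reduction)
        _, summary, _ = run_steady(preset, dt=dt, tol=tol,
                                   max_cycles=max_cycles)
        log.iterations.append((scale, summary.mean_pap))
        logger.info("calibration: scale %.4f -> mean PAP %.2f mmHg",
                    scale, summary.mean_pap)
        return preset, summary

    lo, hi = scale_bounds
    preset, summary = evaluate(lo)
    scale = lo
    if summary.mean_pap < target_mean_ppam - pressure_tol:
        _, summary_hi = evaluate(hi)
        if summary_hi.mean_pap < target_mean_ppam - pressure_tol:
            raise CalibrationError(
                f"mean PAP target {target_mean_ppam} mmHg unreachable within"
                f" scale bounds {scale_bounds}; achieved"
                f" {summary_hi.mean_pap:.1f} mmHg at scale {hi}")
        for _ in range(max_iter):
            scale = 0.5 * (lo + hi)
            preset, summary = evaluate(scale)
            if abs(summary.mean_pap - target_mean_ppam) <= pressure_tol:
                break
            if summary.mean_pap < target_mean_ppam:
                lo = scale
            else:
                hi = scale
        else:
            raise CalibrationError(
                "bisection failed to bracket the mean PAP target")
    log.final_scale = scale
    log.achieved_mean_pap = summary.mean_pap
    log.achieved_rvedv = summary.rvedv
    if log.final_scale > 1.0 + 1e-9:
        dilation = summary.rvedv / normal_summary.rvedv - 1.0
        if dilation < target_rv_dilation:
            raise CalibrationError(
                f"calibrated RVEDV dilation {100 * dilation:.1f}% is below the"
                f" required {100 * target_rv_dilation:.0f}%")
    return preset, log


def _with_tal(patient: PatientPreset, mode: str, c_in: float,
              c_chambers: float) -> PatientPreset:
    base = patient.tal if patient.tal is not None else TALParams()
    tal = dataclasses.replace(base, C_in=c_in, C_ad=c_chambers,
                              C_ap=c_chambers)
    return dataclasses.replace(patient, tal=configure_tal(tal, mode))


def run_course_protocol(patient: PatientPreset,
                        spec: ProtocolSpec = ProtocolSpec(),
                        dt: float = DEFAULT_DT, tol: float = 1e-3,
                        max_cycles: int = 60,
                        record_every: int = 1) -> PercentChangeTable:
    """Run the three-step course protocol and tabulate percent changes.

    For each arteriolar-resistance setting a TAL-off baseline is run first;
    every (mode x compliance) combination is then compared against the
    matching baseline.  A non-converged run aborts the whole protocol with
    the offending cell identified.
    """
    rows = []
    untal = dataclasses.replace(patient, tal=None)
    for rpar in spec.rpar_cgs:
        base_preset = set_parameter(untal, "Rpar", rpar, units="cgs")
        try:
            _, base, _ = run_steady(base_preset, dt=dt, tol=tol,
                                    max_cycles=max_cycles,
                                    record_every=record_every)
        except NonConvergenceError as err:
            raise ProtocolError(
                f"baseline run at Rpar={rpar:g} did not converge: {err}"
            ) from err
        rows.append({"mode": "baseline", "Rpar_cgs": rpar,
                     "CTALin": float("nan"), "CTALchambers": float("nan"),
                     **{v: 0.0 for v in spec.variables}})
        base_values = base.as_dict()
        for mode in spec.modes:
            for c_in in spec.c_tal_in:
                for c_ch in spec.c_tal_chambers:
                    preset = _with_tal(base_preset, mode, c_in, c_ch)
                    try:
                        _, summary, _ = run_steady(
                            preset, dt=dt, tol=tol, max_cycles=max_cycles,
                            record_every=record_every)
                    except NonConvergenceError as err:
                        raise ProtocolError(
                            f"run (mode={mode}, Rpar={rpar:g}, CTALin={c_in},"
                            f" CTALad=CTALap={c_ch}) did not converge: {err}"
                        ) from err
                    values = summary.as_dict()
                    rows.append({
                        "mode": mode, "Rpar_cgs": rpar, "CTALin": c_in,
                        "CTALchambers": c_ch,
                        **{v: percent_change(base_values[v], values[v])
                           for v in spec.variables},
                    })
                    logger.info("protocol cell done: %s", rows[-1])
    return PercentChangeTable(pd.DataFrame(rows))


@dataclass
class DirectionalCheck:
    name: str
    expected: str
    value: float
    passed: bool


@dataclass
class DirectionalReport:
    checks: list[DirectionalCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> list[DirectionalCheck]:
        return [c for c in self.checks if not c.passed]

    def __str__(self) -> str:
        lines = [f"{'ok' if c.passed else 'FAIL':4s} {c.name:55s}"
                 f" expected {c.expected:>4s}, got {c.value:+8.2f}%"
                 for c in self.checks]
        verdict = "all checks passed" if self.passed else (
            f"{len(self.failures)} of {len(self.checks)} checks failed")
        return "\n".join(lines + [verdict])


def directional_check(table: PercentChangeTable,
                      expected: DirectionalExpectation | None = None
                      ) -> DirectionalReport:
    """Compare the protocol table against the expected directions.

    Checks every compliance combination of the parallel rows at the
    overloaded arteriolar resistance against the expected signs, and that the
    best-case hybrid mean-PAP reduction exceeds the best-case parallel one.
    """
    if expected is None:
        expected = DirectionalExpectation()
    checks: list[DirectionalCheck] = []
    rows = table.get(expected.mode, expected.rpar_cgs)
    for _, row in rows.iterrows():
        cell = (f"CTALin={row['CTALin']:g}, CTALad=CTALap="
                f"{row['CTALchambers']:g}")
        for var, sign in expected.signs.items():
            value = float(row[var])
            checks.append(DirectionalCheck(
                name=f"{expected.mode} {var} ({cell})",
                expected="+" if sign > 0 else "-",
                value=value,
                passed=(value > 0) == (sign > 0) and value != 0,
            ))
    hybrid = table.get("hybrid", expected.rpar_cgs)
    if len(hybrid):
        best_hybrid = -hybrid["mean PAP"].min()
        best_parallel = -rows["mean PAP"].min()
        checks.append(DirectionalCheck(
            name="hybrid best mean-PAP reduction exceeds parallel's",
            expected="+",
            value=best_hybrid - best_parallel,
            passed=best_hybrid > best_parallel,
        ))
    return DirectionalReport(checks)
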