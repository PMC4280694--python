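"""Run configuration files, waveform export and preset (de)serialisation.

Configs are YAML with strict key validation; waveforms are exported as plain
CSV ("." decimal, one header row, first column the time in s) that
round-trips at full precision.  An Excel-compatible export is available for
spreadsheet users.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .circuits import DEFAULT_DT, SimulationResult
from .tal import MODES, TALParams
from .vasculature import PatientPreset, normal_preset, set_parameter

__all__ = ["RunConfig", "ConfigError", "load_config", "save_preset",
           "load_preset", "export_waveforms", "export_waveforms_excel",
           "read_waveforms", "BUILTIN_PRESETS"]


class ConfigError(ValueError):
    pass


BUILTIN_PRESETS = {
    "normal": normal_preset,
}

_TOP_KEYS = {"preset", "patient_file", "overrides", "tal", "dt", "tol",
             "max_cycles", "record_every", "rpar_cgs"}
_TAL_KEYS = {f.name for f in dataclasses.fields(TALParams)}


@dataclass
class RunConfig:
    """One simulation run: a patient, optional TAL, solver settings."""

    preset: PatientPreset
    dt: float = DEFAULT_DT
    tol: float = 1e-3
    max_cycles: int = 60
    record_every: int = 1

    def __post_init__(self):
        if self.dt <= 0 or self.tol < 0:
            raise ConfigError("dt must be > 0 and tol >= 0")
        if self.max_cycles < 1 or self.record_every < 1:
            raise ConfigError("max_cycles and record_every must be >= 1")


def _build_preset(doc: dict, base_dir: Path) -> PatientPreset:
    if "patient_file" in doc:
        preset = load_preset(base_dir / doc["patient_file"])
    else:
        name = doc.get("preset", "normal")
        if name not in BUILTIN_PRESETS:
            raise ConfigError(
                f"unknown preset {name!r}; built-ins: "
                f"{', '.join(sorted(BUILTIN_PRESETS))}")
        preset = BUILTIN_PRESETS[name]()

    tal_doc = doc.get("tal")
    if tal_doc is not None:
        unknown = set(tal_doc) - _TAL_KEYS
        if unknown:
            raise ConfigError(
                f"unknown TAL keys {sorted(unknown)}; valid keys:"
                f" {sorted(_TAL_KEYS)}")
        mode = tal_doc.get("mode", "off")
        if mode not in MODES:
            raise ConfigError(f"unknown TAL mode {mode!r}; one of {MODES}")
        base = preset.tal if preset.tal is not None else TALParams()
        preset = dataclasses.replace(
            preset, tal=dataclasses.replace(base, **tal_doc))

    if "rpar_cgs" in doc:
        preset = set_parameter(preset, "Rpar", float(doc["rpar_cgs"]),
                               units="cgs")
    for symbol, value in (doc.get("overrides") or {}).items():
        if isinstance(value, dict):
            unknown = set(value) - {"value", "units"}
            if unknown:
                raise ConfigError(
                    f"override {symbol!r}: unknown keys {sorted(unknown)}"
                    " (expected 'value' and optional 'units')")
            preset = set_parameter(preset, symbol, float(value["value"]),
                                   units=value.get("units"))
        else:
            preset = set_parameter(preset, symbol, float(value))
    return preset


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected with the list of valid ones; resistances in
    ``overrides`` may carry CGS units (``{value: 240, units: cgs}``) and are
    converted to mmHg*s/ml on load.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}; valid"
                          f" keys: {sorted(_TOP_KEYS)}")
    try:
        preset = _build_preset(doc, path.parent)
    except (KeyError, ValueError) as err:
        raise ConfigError(str(err)) from err
    return RunConfig(
        preset=preset,
        dt=float(doc.get("dt", DEFAULT_DT)),
        tol=float(doc.get("tol", 1e-3)),
        max_cycles=int(doc.get("max_cycles", 60)),
        record_every=int(doc.get("record_every", 1)),
    )


def save_preset(preset: PatientPreset, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(preset.to_dict(), fh, sort_keys=False)


def load_preset(path) -> PatientPreset:
    with open(path) as fh:
        return PatientPreset.from_dict(yaml.safe_load(fh))


def _frame(result: SimulationResult) -> pd.DataFrame:
    columns = {"time_s": result.time}
    for name, key in result.aliases.items():
        if key in result.waveforms:
            columns[name] = result.waveforms[key]
    return pd.DataFrame(columns)


def export_waveforms(result: SimulationResult, path) -> None:
    """Write the named waveforms as CSV; lossless at full precision."""
    frame = _frame(result)
    if len(frame) == 0:
        warnings.warn("exporting an empty result: header-only file written")
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(path, index=False, float_format="%.17g")


def export_waveforms_excel(result: SimulationResult, path) -> None:
    """Spreadsheet-compatible variant of :func:`export_waveforms`."""
    _frame(result).to_excel(path, index=False)


def read_waveforms(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
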