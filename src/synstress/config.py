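"""Configuration schema: model parameters, scenario conditions, file I/O.

A configuration bundles the parameter sets of the three model layers
(cytosolic core, signaling cascade, membrane trafficking), the two S-curve
blocks, and the scenario condition constants.  Configuration files are flat,
human-editable INI text with one section per block::

    [core]
    p_NSF = 1.0
    [k0_curve]
    high_rate = 3.4
    [cascade]
    M_GR = 5
    [membrane]
    k11 = 0
    [conditions]
    cortisol_high = 8.5
    [run]
    seed = 0

Unknown sections or keys are rejected by name; values are merged over the
defaults, and every loaded value passes the same validation as the
dataclasses themselves (nonnegativity, M_MR < M_GR, rise_start < rise_end).
"""

from __future__ import annotations

import configparser
import hashlib
import io
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Union

from .cascade import CascadeParameters
from .kinetics import CoreParameters, SCurve, SCurveShape
from .membrane import MembraneParameters

__all__ = [
    "ScenarioConditions",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "config_hash",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


@dataclass(frozen=True)
class ScenarioConditions:
    """Condition constants shared by the named scenarios.

    The reaction scheme fixes rate constants but not the experimental
    conditions; these defaults were calibrated once so the six
    cortisol × coincidence scenarios reproduce the qualitative outcomes
    (full LTP ≈ 2× at low cortisol, attenuated LTP under stress, marked
    LTD under stress with noncorrelated activity) — see docs/methods.md.

    * ``cortisol_low``: low-normal level, near the top of the TrkB bell.
    * ``cortisol_high``: stress level (GR well occupied).
    * ``cortisol_verylow``: glucocorticoid-depleted (MR mostly empty).
    * ``sigma_correlated`` / ``sigma_noncorrelated``: coincidence gain for
      correlated / noncorrelated pre-/postsynaptic activity (zero
      coincidence means no proBDNF→mBDNF conversion).
    * stimulation is a boxcar: the correlated (tetanus-like) protocol uses
      ``stimulus_amplitude`` on [``stimulus_start``, ``stimulus_end``];
      the noncorrelated (low-frequency-like) protocol uses
      ``noncorr_amplitude`` on [``stimulus_start``, ``noncorr_end``] —
      prolonged weak drive rather than a brief strong one, mirroring the
      HFS/LFS asymmetry of the slice experiments the scenarios emulate.
    * transmission is probed with a unit test pulse at ``probe_baseline``
      and ``probe_final`` (the "hour 5" readout).
    * fig8 interventions: production elevated ``elevation_factor``-fold on
      [0, ``elevation_end``], reduced by ``reduction_strong`` or
      ``reduction_small`` from ``reduction_start`` for a window length
      that the scan varies (``fig8_window`` for the two registered
      single-run scenarios).
    """

    cortisol_low: float = 0.05
    cortisol_high: float = 5.0
    cortisol_verylow: float = 4e-6
    sigma_correlated: float = 32.0
    sigma_noncorrelated: float = 0.0
    stimulus_amplitude: float = 0.045
    stimulus_start: float = 0.1
    stimulus_end: float = 1.2
    noncorr_amplitude: float = 0.1
    noncorr_end: float = 2.5
    probe_baseline: float = 0.05
    probe_final: float = 5.0
    probe_amplitude: float = 1.0
    horizon: float = 10.0
    pre_equilibration: float = 10.0
    elevation_factor: float = 3.0
    elevation_end: float = 1.0
    reduction_start: float = 4.0
    reduction_strong: float = 0.3
    reduction_small: float = 0.75
    fig8_window: float = 1.5
    fig8_horizon: float = 30.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigError(f"{f.name} must be nonnegative")
        if not self.stimulus_start < self.stimulus_end:
            raise ConfigError("stimulus_start must precede stimulus_end")
        if not self.stimulus_start < self.noncorr_end:
            raise ConfigError("stimulus_start must precede noncorr_end")
        if not self.probe_baseline < self.stimulus_start:
            raise ConfigError(
                "probe_baseline must precede the stimulation window"
            )
        if self.probe_final > self.horizon:
            raise ConfigError("probe_final must lie within the horizon")


@dataclass(frozen=True)
class ModelConfig:
    """Full resolved configuration of the simulator."""

    core: CoreParameters = field(default_factory=CoreParameters)
    cascade: CascadeParameters = field(default_factory=CascadeParameters)
    membrane: MembraneParameters = field(default_factory=MembraneParameters)
    conditions: ScenarioConditions = field(default_factory=ScenarioConditions)
    #: reserved for stochastic extensions; the model itself is deterministic
    seed: int = 0


# --- flat-file round trip ---------------------------------------------------

_CURVE_KEYS = ("low_rate", "high_rate", "rise_start", "rise_end", "shape")
_RUN_KEYS = ("seed",)


def _curve_to_dict(curve: SCurve) -> dict:
    return {
        "low_rate": curve.low_rate,
        "high_rate": curve.high_rate,
        "rise_start": curve.rise_start,
        "rise_end": curve.rise_end,
        "shape": curve.shape.value,
    }


def _section_items(obj, skip=()) -> dict:
    out = {}
    for f in fields(obj):
        if f.name.startswith("_") or f.name in skip:
            continue
        v = getattr(obj, f.name)
        if isinstance(v, bool):
            out[f.name] = str(v).lower()
        elif isinstance(v, (int, float, str)):
            out[f.name] = repr(v) if isinstance(v, float) else str(v)
    return out


def dump_config(config: ModelConfig, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a configuration to the flat INI text (optionally to a
    file); ``load_config(dump_config(c))`` reproduces ``c``."""
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys are case-sensitive model symbols
    cp["core"] = _section_items(config.core, skip=("k0_curve", "k4_curve"))
    cp["k0_curve"] = _curve_to_dict(config.core.k0_curve)
    cp["k4_curve"] = _curve_to_dict(config.core.k4_curve)
    cp["cascade"] = _section_items(config.cascade)
    cp["membrane"] = _section_items(config.membrane)
    cp["conditions"] = _section_items(config.conditions)
    cp["run"] = {"seed": str(config.seed)}
    for sec in cp.values():
        for k, v in list(sec.items()):
            sec[k] = str(v)
    buf = io.StringIO()
    cp.write(buf)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def _coerce(name: str, raw: str, target_type):
    raw = raw.strip()
    try:
        if target_type is bool:
            if raw.lower() in ("true", "1", "yes"):
                return True
            if raw.lower() in ("false", "0", "no"):
                return False
            raise ValueError
        if target_type is int:
            return int(raw)
        if target_type is float:
            return float(raw)
        return raw
    except ValueError as exc:
        raise ConfigError(f"invalid value for {name}: {raw!r}") from exc


def _update_dataclass(obj, section_name: str, items: dict, skip=()):
    valid = {f.name: f for f in fields(obj)
             if not f.name.startswith("_") and f.name not in skip}
    updates = {}
    for key, raw in items.items():
        if key not in valid:
            raise ConfigError(f"unknown key [{section_name}] {key}")
        current = getattr(obj, key)
        target = type(current) if not isinstance(current, bool) else bool
        if isinstance(current, bool):
            target = bool
        elif isinstance(current, (int, float)):
            target = type(current)
        elif isinstance(current, str) or isinstance(current, SCurveShape):
            target = str
        updates[key] = _coerce(f"[{section_name}] {key}", raw, target)
    try:
        return replace(obj, **updates)
    except (ValueError, ConfigError) as exc:
        raise ConfigError(str(exc)) from exc


def _update_curve(curve: SCurve, section_name: str, items: dict) -> SCurve:
    updates = {}
    for key, raw in items.items():
        if key not in _CURVE_KEYS:
            raise ConfigError(f"unknown key [{section_name}] {key}")
        if key == "shape":
            try:
                updates[key] = SCurveShape(raw.strip())
            except ValueError as exc:
                raise ConfigError(
                    f"invalid value for [{section_name}] shape: {raw!r}"
                ) from exc
        else:
            updates[key] = _coerce(f"[{section_name}] {key}", raw, float)
    try:
        return replace(curve, **updates)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(source: Union[str, Path, None] = None) -> ModelConfig:
    """Load a configuration, merging a flat INI file over the defaults.

    ``source`` may be a path, raw INI text, or None (pure defaults).
    Unknown sections/keys and invalid values raise :class:`ConfigError`
    naming the offending key.
    """
    config = ModelConfig()
    if source is None:
        return config
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and "=" not in source
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    cp = configparser.ConfigParser()
    cp.optionxform = str
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"unparseable config: {exc}") from exc

    core = config.core
    cascade = config.cascade
    membrane = config.membrane
    conditions = config.conditions
    seed = config.seed
    for section in cp.sections():
        items = dict(cp.items(section))
        if section == "core":
            core = _update_dataclass(core, section, items,
                                     skip=("k0_curve", "k4_curve"))
        elif section == "k0_curve":
            core = replace(core, k0_curve=_update_curve(core.k0_curve, section, items))
        elif section == "k4_curve":
            core = replace(core, k4_curve=_update_curve(core.k4_curve, section, items))
        elif section == "cascade":
            cascade = _update_dataclass(cascade, section, items)
        elif section == "membrane":
            membrane = _update_dataclass(membrane, section, items)
        elif section == "conditions":
            conditions = _update_dataclass(conditions, section, items)
        elif section == "run":
            for key, raw in items.items():
                if key not in _RUN_KEYS:
                    raise ConfigError(f"unknown key [run] {key}")
                seed = _coerce("[run] seed", raw, int)
        else:
            raise ConfigError(f"unknown section [{section}]")
    try:
        return ModelConfig(core=core, cascade=cascade, membrane=membrane,
                           conditions=conditions, seed=seed)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: ModelConfig) -> str:
    """Short stable hash of the resolved configuration (for logs and
    output provenance)."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:12]
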