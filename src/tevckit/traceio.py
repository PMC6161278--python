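"""Readers and writers for trace tables, run configurations, and reports.

Canonical trace format is a long-form CSV with fixed units encoded in the
headers (time_s, step_index, command_mV, current_uA) — no unit
auto-detection.  Run configurations are YAML or JSON.  An Axon Text Format
(ATF) importer maps vendor-exported text tables onto the same model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ghk import Composition, Environment
from .simulate import DEFAULT_INTERNAL, TraceSet, VoltageProtocol, standard_baths

__all__ = [
    "TraceFormatError",
    "ConfigValidationError",
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_run_config",
    "write_run_config",
]

TRACE_COLUMNS = ("time_s", "step_index", "command_mV", "current_uA")
META_PREFIX = "# "


class TraceFormatError(ValueError):
    """Malformed trace table (missing column, non-monotone time, ...)."""


class ConfigValidationError(ValueError):
    """Run configuration fails validation."""


def write_trace_csv(trace: TraceSet, path: str | Path) -> None:
    """Write one oocyte's sweeps as long-form CSV with a metadata header."""
    path = Path(path)
    n_steps, n_samples = trace.currents_uA.shape
    frame = pd.DataFrame(
        {
            "time_s": np.tile(trace.time_s, n_steps),
            "step_index": np.repeat(np.arange(n_steps), n_samples),
            "command_mV": np.repeat(trace.step_voltages_mV, n_samples),
            "current_uA": trace.currents_uA.ravel(),
        }
    )
    meta = {
        "oocyte_id": trace.oocyte_id,
        "injection": trace.injection,
        "cnmp": trace.cnmp,
        "bath_label": trace.bath_label,
        "temperature_K": trace.env.temperature,
    }
    with open(path, "w") as fh:
        fh.write(META_PREFIX + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False, float_format="%.9g")


def read_trace_csv(path: str | Path) -> TraceSet:
    """Read a long-form trace CSV back into a validated :class:`TraceSet`."""
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"no such trace file: {path}")
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(META_PREFIX):
            meta = json.loads(first[len(META_PREFIX):])
            frame = pd.read_csv(fh)
        else:
            frame = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required column(s) {missing}")

    steps = sorted(frame["step_index"].unique())
    times = None
    voltages = []
    currents = []
    for s in steps:
        sub = frame[frame["step_index"] == s]
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            row = int(sub.index[np.argmin(np.diff(t) > 0)])
            raise TraceFormatError(f"{path}: non-monotone time in step {s} near row {row}")
        if times is None:
            times = t
        elif len(t) != len(times) or not np.allclose(t, times):
            raise TraceFormatError(
                f"{path}: step {s} has a different time base (mixed sampling rates?)"
            )
        v = sub["command_mV"].unique()
        if len(v) != 1:
            raise TraceFormatError(f"{path}: step {s} has non-constant command voltage")
        voltages.append(float(v[0]))
        currents.append(sub["current_uA"].to_numpy())
    if times is None:
        raise TraceFormatError(f"{path}: no sweeps found")
    return TraceSet(
        oocyte_id=str(meta.get("oocyte_id", path.stem)),
        injection=str(meta.get("injection", "unknown")),
        cnmp=str(meta.get("cnmp", "none")),
        bath_label=str(meta.get("bath_label", "bath")),
        time_s=times,
        step_voltages_mV=np.array(voltages),
        currents_uA=np.vstack(currents),
        env=Environment(temperature=float(meta.get("temperature_K", 293.15))),
    )


def read_trace_atf(path: str | Path, current_column: int = 1) -> TraceSet:
    """Import an Axon Text Format (ATF) table: one time column plus one
    current column per sweep, or a single current column selected by index.

    Sweep command voltages are not stored in ATF signal tables; they must be
    attached afterwards from the protocol.
    """
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline()
        if not magic.startswith("ATF"):
            raise TraceFormatError(f"{path}: not an ATF file (bad magic)")
        counts = fh.readline().split()
        n_header = int(counts[0])
        for _ in range(n_header):
            fh.readline()
        frame = pd.read_csv(fh, sep=r"\s+|\t|,", engine="python", header=0)
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    currents = frame.iloc[:, 1:].to_numpy(dtype=float).T
    return TraceSet(
        oocyte_id=path.stem,
        injection="unknown",
        cnmp="none",
        bath_label="bath",
        time_s=t - t[0] if len(t) else t,
        step_voltages_mV=np.full(currents.shape[0], np.nan),
        currents_uA=currents,
    )


@dataclass
class RunConfig:
    """Validated study configuration with defaults applied."""

    protocol: VoltageProtocol = field(default_factory=VoltageProtocol)
    baths: dict[str, Composition] = field(default_factory=standard_baths)
    internal: Composition = DEFAULT_INTERNAL
    env: Environment = field(default_factory=Environment)
    steady_state_window_s: float | None = None  # default: last 10% of step
    kinetics_offset_s: float = 0.01
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.steady_state_window_s is None:
            self.steady_state_window_s = 0.1 * self.protocol.step_duration_s
        if self.steady_state_window_s <= 0:
            raise ConfigValidationError("steady-state window must be > 0")
        if self.steady_state_window_s > self.protocol.step_duration_s:
            raise ConfigValidationError(
                f"steady-state window ({self.steady_state_window_s} s) exceeds the "
                f"step duration ({self.protocol.step_duration_s} s)"
            )
        if self.kinetics_offset_s >= self.protocol.step_duration_s:
            raise ConfigValidationError("kinetics offset exceeds step duration")
        labels = list(self.baths)
        if len(labels) != len(set(labels)):
            raise ConfigValidationError("bath labels must be unique")


def _composition_from_dict(d: dict, label: str = "") -> Composition:
    try:
        return Composition({str(k): float(v) for k, v in d.items()}, label=label)
    except Exception as exc:
        raise ConfigValidationError(f"bad composition {label!r}: {exc}") from exc


def read_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Missing keys take defaults: temperature 293.15 K, steady-state window =
    last 10% of the step, typical oocyte internal composition.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigValidationError(f"{path}: config must be a mapping")

    prot_kwargs = {}
    p = raw.get("protocol", {})
    if "holding_mV" in p:
        prot_kwargs["holding_mV"] = float(p["holding_mV"])
    if "step_levels_mV" in p:
        prot_kwargs["step_levels_mV"] = tuple(float(v) for v in p["step_levels_mV"])
    for key in ("step_duration_s", "inter_step_s", "sampling_hz"):
        if key in p:
            prot_kwargs[key] = float(p[key])
    protocol = VoltageProtocol(**prot_kwargs)

    env = Environment(temperature=float(raw.get("temperature_K", 293.15)))
    baths = (
        {lbl: _composition_from_dict(d, lbl) for lbl, d in raw["baths"].items()}
        if "baths" in raw
        else standard_baths()
    )
    internal = (
        _composition_from_dict(raw["internal"], "internal")
        if "internal" in raw
        else DEFAULT_INTERNAL
    )
    windows = raw.get("windows", {})
    return RunConfig(
        protocol=protocol,
        baths=baths,
        internal=internal,
        env=env,
        steady_state_window_s=(
            float(windows["steady_state_s"]) if "steady_state_s" in windows else None
        ),
        kinetics_offset_s=float(windows.get("kinetics_offset_s", 0.01)),
        groups=raw.get("groups", {}),
    )


def write_run_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig (YAML or JSON chosen by suffix); loss-free for
    all declared fields."""
    path = Path(path)
    doc = {
        "protocol": {
            "holding_mV": cfg.protocol.holding_mV,
            "step_levels_mV": list(cfg.protocol.step_levels_mV),
            "step_duration_s": cfg.protocol.step_duration_s,
            "inter_step_s": cfg.protocol.inter_step_s,
            "sampling_hz": cfg.protocol.sampling_hz,
        },
        "temperature_K": cfg.env.temperature,
        "baths": {lbl: dict(c.concentrations) for lbl, c in cfg.baths.items()},
        "internal": dict(cfg.internal.concentrations),
        "windows": {
            "steady_state_s": cfg.steady_state_window_s,
            "kinetics_offset_s": cfg.kinetics_offset_s,
        },
        "groups": cfg.groups,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
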