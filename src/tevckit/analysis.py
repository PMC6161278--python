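"""From raw sweeps to derived quantities: steady-state currents, I-V curves,
reversal potentials, and relative open probability.

Measurement conventions
-----------------------
* steady-state current: mean over the final window of each step
  (default = last 10% of the step, i.e. 200 ms of a 2 s step)
* instantaneous current: mean of a 10 ms window starting 5 ms after onset
* reversal potential: x-intercept of the line through the two mean currents
  closest to the x-axis on either side (the two-point interpolation rule)
* relative open probability: chord conductance G(V) = I/(V - E_rev)
  normalized to its maximum, with points within an exclusion zone of E_rev
  dropped to avoid the chord singularity
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TraceSet

__all__ = [
    "StepMeasurement",
    "IVCurve",
    "ReversalEstimate",
    "AnalysisError",
    "extract_steady_state",
    "build_iv",
    "estimate_reversal_potential",
    "relative_open_probability",
]


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class StepMeasurement:
    command_mV: float
    steady_state_uA: float
    instantaneous_uA: float
    oocyte_id: str


@dataclass
class IVCurve:
    """Per-voltage aggregated currents for one experimental group."""

    voltages_mV: np.ndarray
    mean_uA: np.ndarray
    sd_uA: np.ndarray
    n: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "command_mV": self.voltages_mV,
                "mean_uA": self.mean_uA,
                "sd_uA": self.sd_uA,
                "n": self.n,
                "group": self.label,
            }
        )


@dataclass(frozen=True)
class ReversalEstimate:
    e_rev_mV: float
    bracket_mV: tuple[float, float]
    method: str = "two-point-linear"


def extract_steady_state(
    trace: TraceSet,
    window_s: float | None = None,
    instantaneous_offset_s: float = 0.005,
    instantaneous_window_s: float = 0.010,
) -> list[StepMeasurement]:
    """Measure steady-state and instantaneous current for every sweep."""
    duration = float(trace.time_s[-1]) + float(np.median(np.diff(trace.time_s)))
    if window_s is None:
        window_s = 0.1 * duration
    if window_s <= 0:
        raise AnalysisError(f"steady-state window must be > 0 s, got {window_s}")
    if window_s > duration + 1e-12:
        raise AnalysisError(
            f"steady-state window ({window_s} s) exceeds the step duration ({duration} s)"
        )
    ss_mask = trace.time_s >= duration - window_s
    inst_mask = (trace.time_s >= instantaneous_offset_s) & (
        trace.time_s < instantaneous_offset_s + instantaneous_window_s
    )
    if not ss_mask.any():
        raise AnalysisError("steady-state window contains no samples")
    out = []
    for v, sweep in zip(trace.step_voltages_mV, trace.currents_uA):
        out.append(
            StepMeasurement(
                command_mV=float(v),
                steady_state_uA=float(sweep[ss_mask].mean()),
                instantaneous_uA=float(sweep[inst_mask].mean()) if inst_mask.any() else np.nan,
                oocyte_id=trace.oocyte_id,
            )
        )
    return out


def build_iv(measurements: list[StepMeasurement], label: str = "") -> IVCurve:
    """Aggregate per-oocyte steady-state currents into mean +/- SD per voltage.

    Each oocyte may contribute at most one value per voltage; sample SD uses
    the n-1 denominator and is reported as 0 where n = 1.
    """
    if not measurements:
        raise AnalysisError("no measurements to aggregate")
    frame = pd.DataFrame(
        {
            "command_mV": [m.command_mV for m in measurements],
            "steady_state_uA": [m.steady_state_uA for m in measurements],
            "oocyte_id": [m.oocyte_id for m in measurements],
        }
    )
    dup = frame.duplicated(subset=["command_mV", "oocyte_id"])
    if dup.any():
        pair = frame.loc[dup.idxmax()]
        raise AnalysisError(
            f"duplicate measurement for oocyte {pair.oocyte_id!r} at {pair.command_mV} mV"
        )
    g = frame.groupby("command_mV")["steady_state_uA"]
    agg = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
    agg = agg.sort_index()
    return IVCurve(
        voltages_mV=agg.index.to_numpy(dtype=float),
        mean_uA=agg["mean"].to_numpy(),
        sd_uA=agg["sd"].to_numpy(),
        n=agg["n"].to_numpy(dtype=int),
        label=label,
    )


def estimate_reversal_potential(iv: IVCurve) -> ReversalEstimate:
    """Two-point reversal-potential rule.

    Takes the smallest-|I| point with negative mean current and the
    smallest-|I| point with positive mean current and returns the x-intercept
    of the straight line through them.  A sampled mean of exactly zero wins
    outright.
    """
    v = np.asarray(iv.voltages_mV, dtype=float)
    i = np.asarray(iv.mean_uA, dtype=float)
    zero = np.flatnonzero(i == 0.0)
    if zero.size:
        vz = float(v[zero[np.argmin(np.abs(v[zero]))]])
        return ReversalEstimate(e_rev_mV=vz, bracket_mV=(vz, vz), method="exact-zero")
    neg = i < 0
    pos = i > 0
    if not neg.any() or not pos.any():
        raise AnalysisError(
            "I-V curve does not cross zero: need at least one positive and one "
            "negative mean current"
        )
    k_neg = np.flatnonzero(neg)[np.argmin(np.abs(i[neg]))]
    k_pos = np.flatnonzero(pos)[np.argmin(np.abs(i[pos]))]
    v1, i1 = float(v[k_neg]), float(i[k_neg])
    v2, i2 = float(v[k_pos]), float(i[k_pos])
    e_rev = v1 - i1 * (v2 - v1) / (i2 - i1)
    lo, hi = sorted((v1, v2))
    return ReversalEstimate(e_rev_mV=float(e_rev), bracket_mV=(lo, hi))


def relative_open_probability(
    iv: IVCurve, e_rev_mV: float, exclusion_mV: float = 5.0
) -> list[tuple[float, float]]:
    """Relative open probability from steady-state chord conductance.

    G(V) = I(V)/(V - E_rev); Po(V) = G(V)/max G.  Voltages within
    ``exclusion_mV`` of E_rev are dropped (chord singularity); the retained
    maximum is exactly 1 by construction.
    """
    if not np.isfinite(e_rev_mV):
        raise AnalysisError("E_rev must be finite")
    v = np.asarray(iv.voltages_mV, dtype=float)
    i = np.asarray(iv.mean_uA, dtype=float)
    keep = np.abs(v - e_rev_mV) > exclusion_mV
    if not keep.any():
        raise AnalysisError("all I-V points fall inside the E_rev exclusion zone")
    g = i[keep] / (v[keep] - e_rev_mV)
    gmax = g.max()
    if gmax <= 0:
        raise AnalysisError("non-positive chord conductances throughout; cannot normalize")
    return [(float(vv), float(gg / gmax)) for vv, gg in zip(v[keep], g)]
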