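"""Forward gating model: modified Boltzmann steady state and exponential kinetics.

The steady-state open probability follows a modified Boltzmann curve with a
voltage-independent floor Pmin:

    P(V) = (Pmax - Pmin) / (1 + exp(zd F (V - V0.5) / RT)) + Pmin

With the exponent written this way (positive sign), hyperpolarization opens
the channel: P -> Pmax as V -> -inf.  zd is the apparent gating charge (the
charge z displaced through fraction d of the membrane field).

After a voltage step the open probability relaxes first-order toward its new
steady state, dP/dt = (Pinf(V) - P)/tau, whose solution is the
mono-exponential P(t) = Pinf + (Pstart - Pinf) exp(-t/tau); the current then
relaxes as I(t) = A exp(-t/tau) + Iinf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ghk import Environment

__all__ = [
    "BoltzmannParams",
    "ExpRelaxation",
    "boltzmann_open_probability",
    "exponential_time_course",
    "open_probability_relaxation",
    "gated_current",
]


@dataclass(frozen=True)
class BoltzmannParams:
    """Parameters of the modified Boltzmann activation curve.

    z_delta : apparent gating charge (dimensionless, >= 0)
    v_half  : half-activation membrane potential, mV
    p_max   : maximum open probability (ceiling)
    p_min   : voltage-independent minimum open probability (floor)
    """

    z_delta: float
    v_half: float
    p_max: float = 1.0
    p_min: float = 0.0

    def __post_init__(self) -> None:
        if self.z_delta < 0:
            raise ValueError(f"gating charge must be >= 0, got {self.z_delta}")
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ValueError(
                f"need 0 <= p_min <= p_max <= 1, got p_min={self.p_min}, p_max={self.p_max}"
            )


@dataclass(frozen=True)
class ExpRelaxation:
    """Mono-exponential current relaxation I(t) = A exp(-t/tau) + Iinf.

    ``amplitude`` (A, uA) is the coefficient of the decaying term, so the
    literal value at t = 0 is A + Iinf; ``steady`` (Iinf, uA) is the
    asymptote; ``tau`` (s) is the e-fold time constant.
    """

    amplitude: float
    steady: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0 s, got {self.tau}")


def boltzmann_open_probability(
    v_mV: float | np.ndarray,
    p: BoltzmannParams,
    env: Environment | None = None,
) -> float | np.ndarray:
    """Steady-state open probability at voltage(s) ``v_mV``."""
    env = env or Environment()
    v = np.asarray(v_mV, dtype=float)
    x = p.z_delta * (v - p.v_half) / env.thermal_voltage_mV
    out = (p.p_max - p.p_min) / (1.0 + np.exp(x)) + p.p_min
    return float(out) if out.ndim == 0 else out


def exponential_time_course(
    t_s: float | np.ndarray, r: ExpRelaxation
) -> float | np.ndarray:
    """Current at time(s) ``t_s`` after the step: A exp(-t/tau) + Iinf."""
    t = np.asarray(t_s, dtype=float)
    out = r.amplitude * np.exp(-t / r.tau) + r.steady
    return float(out) if out.ndim == 0 else out


def open_probability_relaxation(
    t_s: float | np.ndarray, p_inf: float, p_start: float, tau_s: float
) -> float | np.ndarray:
    """Closed-form solution of dP/dt = (Pinf - P)/tau from P(0) = Pstart."""
    if tau_s <= 0:
        raise ValueError(f"tau must be > 0 s, got {tau_s}")
    t = np.asarray(t_s, dtype=float)
    out = p_inf + (p_start - p_inf) * np.exp(-t / tau_s)
    return float(out) if out.ndim == 0 else out


def gated_current(
    v_mV: float,
    t_s: float | np.ndarray,
    p: BoltzmannParams,
    tau_s: float,
    p_start: float,
    driving_uA: float,
    env: Environment | None = None,
    scale: float = 1.0,
) -> float | np.ndarray:
    """Time course of the gated current after a step to ``v_mV``.

    ``driving_uA`` is the fully-open (P = 1) multi-ion GHK current at the step
    voltage; the observable current is scale * P(t) * driving.  Activation
    after a step is mono-exponential with time constant ``tau_s``.
    """
    p_inf = boltzmann_open_probability(v_mV, p, env)
    p_t = open_probability_relaxation(t_s, p_inf, p_start, tau_s)
    return scale * p_t * driving_uA
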