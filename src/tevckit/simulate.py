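"""Generative model of TEVC voltage-step recordings from Xenopus oocytes.

Synthesizes the statistical structure of whole-oocyte recordings of a weakly
voltage-dependent, slowly activating, cyclic-nucleotide-gated conductance:

* multi-ion GHK flux (default permeability ratios P_K:P_Na:P_Cl = 1:0.63:0.03)
* modified-Boltzmann steady-state gating with a large voltage-independent
  floor, relaxing mono-exponentially (tau ~ 0.6 s) after each step
* activation gated by the cyclic-nucleotide state (8Br-cAMP activates,
  8Br-cGMP and cNMP-free do not) and by the co-presence of external Na+ and
  K+ above a threshold — a phenomenological encoding of the two-ion
  requirement, not a mechanistic claim
* linear leak, optional endogenous outward-rectifier contamination,
  i.i.d. Gaussian sample noise, and lognormal per-oocyte amplitude factors

Everything is bit-reproducible from (config, protocol, seed, oocyte index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gating import BoltzmannParams, boltzmann_open_probability, open_probability_relaxation
from .ghk import Composition, Environment, GHKError, PermeabilitySet, total_ghk_current

__all__ = [
    "VoltageProtocol",
    "SimulationConfig",
    "TraceSet",
    "simulate_recording",
    "generate_cohort",
    "standard_baths",
    "DEFAULT_INTERNAL",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


#: Typical Xenopus oocyte internal milieu (mM); overridable everywhere.
DEFAULT_INTERNAL = Composition({"K": 110.0, "Na": 10.0, "Cl": 33.0}, label="oocyte_internal")


def standard_baths() -> dict[str, Composition]:
    """The bath compositions of the substitution series (nominal mM of the
    monovalent salts; divalents and pH-titration ions are excluded from GHK
    bookkeeping)."""
    return {
        "Na": Composition({"Na": 96.0, "K": 0.0, "Cl": 96.0}, label="Na"),
        "K": Composition({"Na": 0.0, "K": 96.0, "Cl": 96.0}, label="K"),
        "NaK_1_1": Composition({"Na": 48.0, "K": 48.0, "Cl": 96.0}, label="NaK_1_1"),
        "NaK_1_4": Composition({"Na": 19.2, "K": 76.8, "Cl": 96.0}, label="NaK_1_4"),
        "gluconate": Composition(
            {"Na": 48.0, "K": 48.0, "Cl": 48.0, "gluconate": 48.0}, label="gluconate"
        ),
        "NMDG": Composition(
            {"Na": 9.6, "K": 9.6, "NMDG": 76.8, "Cl": 96.0}, label="NMDG"
        ),
    }


@dataclass(frozen=True)
class VoltageProtocol:
    """Voltage-step protocol: 2 s steps from +40 to -120 mV in -20 mV
    decrements from a -30 mV holding potential, sampled at 1 kHz."""

    holding_mV: float = -30.0
    step_levels_mV: tuple[float, ...] = (40, 20, 0, -20, -40, -60, -80, -100, -120)
    step_duration_s: float = 2.0
    inter_step_s: float = 2.0
    sampling_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.step_duration_s <= 0:
            raise ConfigurationError("step duration must be > 0")
        if self.sampling_hz < 100:
            raise ConfigurationError("sampling rate must be >= 100 Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.step_duration_s * self.sampling_hz))

    def time_base(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_hz


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterization of one simulated experiment."""

    permeabilities: PermeabilitySet = field(
        default_factory=lambda: PermeabilitySet({"K": 1.0, "Na": 0.63, "Cl": 0.03})
    )
    reference_perm_cm_s: float = 5e-7  # absolute P_K; sets the current scale
    membrane_area_cm2: float = 0.2
    gating: BoltzmannParams = field(
        default_factory=lambda: BoltzmannParams(z_delta=0.016, v_half=-62.0, p_max=1.0, p_min=0.43)
    )
    tau_s: float = 0.59
    internal: Composition = DEFAULT_INTERNAL
    external: Composition = field(default_factory=lambda: standard_baths()["NaK_1_1"])
    leak_conductance_uS: float = 1.0
    leak_reversal_mV: float = -40.0
    rectifier: bool = False
    rectifier_uS: float = 25.0
    rectifier_vhalf_mV: float = 20.0
    rectifier_slope_mV: float = 15.0
    rectifier_reversal_mV: float = -20.0
    cnmp: str = "8Br-cAMP"
    cnmp_gains: tuple[tuple[str, float], ...] = (
        ("none", 0.0),
        ("8Br-cAMP", 1.0),
        ("8Br-cGMP", 0.0),
    )
    coion_threshold_mM: float = 5.0  # both Na+ and K+ needed externally
    noise_sd_uA: float = 0.02
    amplitude_cv: float = 0.3
    n_oocytes: int = 6
    seed: int = 0
    injection: str = "cRNA"  # {"water", "cRNA", "mutant"}
    env: Environment = field(default_factory=Environment)

    def __post_init__(self) -> None:
        if self.noise_sd_uA < 0 or self.amplitude_cv < 0:
            raise ConfigurationError("noise SD and amplitude CV must be >= 0")
        if self.cnmp not in dict(self.cnmp_gains):
            raise ConfigurationError(f"unknown cNMP state {self.cnmp!r}")

    @property
    def channel_gain(self) -> float:
        """Activation gain: cNMP state times the Na+/K+ co-presence switch;
        zero for water-injected or pore-dead mutant oocytes."""
        if self.injection in ("water", "mutant"):
            return 0.0
        g = dict(self.cnmp_gains)[self.cnmp]
        both = (
            self.external.get("Na") >= self.coion_threshold_mM
            and self.external.get("K") >= self.coion_threshold_mM
        )
        return g if both else 0.0


@dataclass
class TraceSet:
    """One oocyte's voltage-step sweeps plus metadata.

    ``currents_uA`` has shape (n_steps, n_samples); all sweeps share
    ``time_s``.
    """

    oocyte_id: str
    injection: str
    cnmp: str
    bath_label: str
    time_s: np.ndarray
    step_voltages_mV: np.ndarray
    currents_uA: np.ndarray
    env: Environment = field(default_factory=Environment)

    def __post_init__(self) -> None:
        if self.currents_uA.shape != (len(self.step_voltages_mV), len(self.time_s)):
            raise ValueError("currents array shape must be (n_steps, n_samples)")


def _rectifier_current(cfg: SimulationConfig, v: float) -> float:
    """Instantaneous endogenous outward rectifier (contaminant above 0 mV)."""
    act = 1.0 / (1.0 + np.exp(-(v - cfg.rectifier_vhalf_mV) / cfg.rectifier_slope_mV))
    return cfg.rectifier_uS * act * (v - cfg.rectifier_reversal_mV) * 1e-3


def channel_driving_current(cfg: SimulationConfig, v_mV: float | np.ndarray) -> float | np.ndarray:
    """Fully-open (P = 1) whole-oocyte GHK current at ``v_mV``, in uA."""
    dens = total_ghk_current(
        cfg.permeabilities,
        v_mV,
        cfg.external,
        cfg.internal,
        cfg.env,
        reference_perm_cm_s=cfg.reference_perm_cm_s,
    )
    return cfg.membrane_area_cm2 * dens


def _check_permeant(cfg: SimulationConfig) -> None:
    if cfg.reference_perm_cm_s <= 0:
        return
    for ion, p in cfg.permeabilities.items():
        if p > 0 and (cfg.internal.get(ion) > 0 or cfg.external.get(ion) > 0):
            return
    raise ConfigurationError(
        "nonzero conductance scale but no permeant ion present on either side"
    )


def simulate_recording(
    cfg: SimulationConfig,
    prot: VoltageProtocol | None = None,
    oocyte_index: int = 0,
) -> TraceSet:
    """Simulate one oocyte's full voltage-step family.

    Deterministic given (cfg.seed, oocyte_index): the RNG stream is keyed on
    both, so cohort members are independent yet individually reproducible.
    Gating starts each step from the steady state at the holding potential:
    the inter-step holding interval is assumed long enough to re-equilibrate.
    With the defaults (2 s holding, tau = 0.59 s) the residual error is
    exp(-2/0.59) ~ 3% of the step-to-step P excursion; treated as negligible.
    """
    prot = prot or VoltageProtocol()
    _check_permeant(cfg)
    rng = np.random.default_rng([cfg.seed, oocyte_index])
    # amplitude factor drawn first so the noise stream is state-independent
    if cfg.amplitude_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.amplitude_cv**2))
        amp = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
    else:
        amp = 1.0
        rng.lognormal(mean=0.0, sigma=0.0)  # keep stream alignment across CVs

    t = prot.time_base()
    p_start = boltzmann_open_probability(prot.holding_mV, cfg.gating, cfg.env)
    gain = cfg.channel_gain
    sweeps = np.empty((len(prot.step_levels_mV), prot.n_samples))
    for k, v in enumerate(prot.step_levels_mV):
        p_inf = boltzmann_open_probability(v, cfg.gating, cfg.env)
        p_t = open_probability_relaxation(t, p_inf, p_start, cfg.tau_s)
        i_chan = gain * amp * p_t * channel_driving_current(cfg, v)
        i_leak = cfg.leak_conductance_uS * (v - cfg.leak_reversal_mV) * 1e-3
        i = i_chan + i_leak
        if cfg.rectifier:
            i = i + _rectifier_current(cfg, v)
        if cfg.noise_sd_uA > 0:
            i = i + rng.normal(0.0, cfg.noise_sd_uA, size=prot.n_samples)
        else:
            rng.normal(0.0, 1.0, size=prot.n_samples)  # keep stream alignment
        sweeps[k] = i

    return TraceSet(
        oocyte_id=f"oocyte_{oocyte_index:03d}",
        injection=cfg.injection,
        cnmp=cfg.cnmp,
        bath_label=cfg.external.label or "bath",
        time_s=t,
        step_voltages_mV=np.asarray(prot.step_levels_mV, dtype=float),
        currents_uA=sweeps,
        env=cfg.env,
    )


def generate_cohort(
    cfg: SimulationConfig, prot: VoltageProtocol | None = None
) -> list[TraceSet]:
    """Simulate ``cfg.n_oocytes`` oocytes with independent amplitude factors
    and noise, reproducible from ``cfg.seed``."""
    if cfg.n_oocytes < 1:
        raise ConfigurationError("n_oocytes must be >= 1")
    return [simulate_recording(cfg, prot, i) for i in range(cfg.n_oocytes)]


def water_injected(cfg: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A water-injected control template: leak and noise only."""
    base = cfg or SimulationConfig()
    return replace(base, injection="water", **overrides)
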