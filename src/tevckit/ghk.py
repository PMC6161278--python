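"""Electro-diffusion math: Nernst and Goldman-Hodgkin-Katz (GHK) equations.

The constant-field (GHK) formalism describes a membrane permeable to several
monovalent ions.  Forward direction: given relative permeabilities and ionic
compositions on both sides, the GHK voltage equation yields the reversal
potential, and the GHK current (flux) equation yields the per-ion current
density at any voltage.  Inverse direction: given reversal potentials measured
under several bath compositions, :func:`solve_permeability_ratios` recovers the
relative permeabilities by weighted nonlinear least squares over log-ratios.

Conventions
-----------
* voltages in mV, concentrations in mM, temperature in K
* current density in uA/cm^2, outward current positive (inward negative)
* relative permeabilities are dimensionless with the reference ion fixed at 1
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Environment",
    "IonSpecies",
    "Composition",
    "PermeabilitySet",
    "GHKCondition",
    "GHKConditionSet",
    "PermeabilityRatioFit",
    "ION_VALENCES",
    "nernst_potential",
    "ghk_reversal_potential",
    "ghk_current_density",
    "solve_permeability_ratios",
    "GHKError",
    "IdentifiabilityError",
    "FitFailureError",
]


class GHKError(ValueError):
    """Domain error in an electro-diffusion computation."""


class IdentifiabilityError(GHKError):
    """The condition set cannot identify the requested free ratios."""


class FitFailureError(GHKError):
    """The ratio optimizer failed to converge; diagnostics attached."""


@dataclass(frozen=True)
class Environment:
    """Physical constants and temperature.

    Defaults: 293.15 K (20 degC, the recording temperature), CODATA values for
    the gas constant R and Faraday constant F.
    """

    temperature: float = 293.15  # K
    gas_constant: float = 8.314462618  # J mol^-1 K^-1
    faraday: float = 96485.33212  # C mol^-1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise GHKError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def thermal_voltage_mV(self) -> float:
        """RT/F in millivolts (25.2617 mV at 293.15 K)."""
        return 1e3 * self.gas_constant * self.temperature / self.faraday


#: Valences of the ions occurring in oocyte bath recipes.  NMDG (N-methyl-
#: D-glucamine) and gluconate are the standard impermeant substitution ions.
ION_VALENCES: dict[str, int] = {
    "K": +1,
    "Na": +1,
    "Li": +1,
    "Rb": +1,
    "Cs": +1,
    "NMDG": +1,
    "Cl": -1,
    "gluconate": -1,
}


@dataclass(frozen=True)
class IonSpecies:
    """A monovalent ion; divalents are outside the GHK formalism used here."""

    name: str
    valence: int

    def __post_init__(self) -> None:
        if self.valence not in (-1, +1):
            raise GHKError(
                f"ion {self.name!r}: valence must be +1 or -1 for the monovalent "
                f"GHK formalism, got {self.valence}"
            )


def ion_valence(name: str) -> int:
    try:
        return ION_VALENCES[name]
    except KeyError:
        raise GHKError(f"unknown ion label {name!r}; known: {sorted(ION_VALENCES)}") from None


@dataclass(frozen=True)
class Composition:
    """Ionic composition of one solution (ion label -> concentration in mM)."""

    concentrations: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        for ion, c in self.concentrations.items():
            ion_valence(ion)
            if c < 0:
                raise GHKError(f"negative concentration for {ion}: {c} mM")

    def get(self, ion: str) -> float:
        return float(self.concentrations.get(ion, 0.0))

    def items(self):
        return self.concentrations.items()


@dataclass(frozen=True)
class PermeabilitySet:
    """Relative permeabilities (reference ion fixed at exactly 1).

    ``absolute_scale`` is the optional absolute permeability of the reference
    ion in cm/s, used when computing dimensional current densities.
    """

    ratios: Mapping[str, float]
    reference: str = "K"
    absolute_scale: float | None = None

    def __post_init__(self) -> None:
        if self.reference not in self.ratios:
            raise GHKError(f"reference ion {self.reference!r} missing from ratios")
        if self.ratios[self.reference] != 1.0:
            raise GHKError(
                f"reference ion {self.reference!r} permeability must be exactly 1, "
                f"got {self.ratios[self.reference]}"
            )
        for ion, p in self.ratios.items():
            ion_valence(ion)
            if p < 0:
                raise GHKError(f"negative permeability for {ion}: {p}")

    def get(self, ion: str) -> float:
        return float(self.ratios.get(ion, 0.0))

    def items(self):
        return self.ratios.items()


@dataclass(frozen=True)
class GHKCondition:
    """One bath condition with its measured reversal potential."""

    external: Composition
    e_rev_mV: float
    sd_mV: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.e_rev_mV):
            raise GHKError("reversal potential must be finite")


@dataclass(frozen=True)
class GHKConditionSet:
    """Conditions sharing one internal composition, feeding the ratio solver."""

    conditions: Sequence[GHKCondition]
    internal: Composition
    env: Environment = field(default_factory=Environment)

    def __len__(self) -> int:
        return len(self.conditions)


def nernst_potential(
    ion: IonSpecies | str,
    internal_mM: float,
    external_mM: float,
    env: Environment | None = None,
) -> float:
    """Equilibrium (Nernst) potential of a single ion species, in mV.

    E = (RT/zF) ln([ion]_out / [ion]_in)
    """
    env = env or Environment()
    z = ion.valence if isinstance(ion, IonSpecies) else ion_valence(ion)
    if internal_mM <= 0 or external_mM <= 0:
        raise GHKError(
            f"Nernst potential requires strictly positive concentrations, "
            f"got internal={internal_mM}, external={external_mM} mM"
        )
    return env.thermal_voltage_mV / z * math.log(external_mM / internal_mM)


def ghk_reversal_potential(
    perms: PermeabilitySet,
    external: Composition,
    internal: Composition,
    env: Environment | None = None,
) -> float:
    """GHK voltage equation: zero-current potential of a multi-ion membrane, mV.

    E_rev = (RT/F) ln[(sum_cations P_i [i]_out + sum_anions P_j [j]_in) /
                      (sum_cations P_i [i]_in  + sum_anions P_j [j]_out)]
    """
    env = env or Environment()
    num = 0.0
    den = 0.0
    any_perm = False
    for ion, p in perms.items():
        if p == 0.0:
            continue
        any_perm = True
        z = ion_valence(ion)
        if z == +1:
            num += p * external.get(ion)
            den += p * internal.get(ion)
        else:
            num += p * internal.get(ion)
            den += p * external.get(ion)
    if not any_perm:
        raise GHKError("all permeabilities are zero: reversal potential undefined")
    if num <= 0 or den <= 0:
        raise GHKError(
            f"GHK sums must be positive (numerator={num}, denominator={den}); "
            "every permeant ion needs nonzero concentration on at least one side"
        )
    return env.thermal_voltage_mV * math.log(num / den)


def ghk_current_density(
    perm_abs_cm_s: float,
    ion: IonSpecies | str,
    v_mV: float | np.ndarray,
    internal_mM: float,
    external_mM: float,
    env: Environment | None = None,
) -> float | np.ndarray:
    """GHK (constant-field) current density of one ion, in uA/cm^2.

    I = P z^2 F^2 V / RT * ([ion]_in - [ion]_out e^(-zFV/RT)) / (1 - e^(-zFV/RT))

    The removable singularity at V = 0 is evaluated analytically
    (limit P z F ([in] - [out]) plus the first-order term).  Outward current
    is positive; inward current is negative.
    """
    env = env or Environment()
    z = ion.valence if isinstance(ion, IonSpecies) else ion_valence(ion)
    if internal_mM < 0 or external_mM < 0:
        raise GHKError("concentrations must be >= 0")
    v = np.asarray(v_mV, dtype=float)
    p_si = perm_abs_cm_s * 1e-2  # cm/s -> m/s
    c_in = internal_mM  # mM == mol/m^3
    c_out = external_mM
    F = env.faraday
    u = z * v * 1e-3 * F / (env.gas_constant * env.temperature)  # zFV/RT

    small = np.abs(u) < 1e-6
    u_safe = np.where(small, 1.0, u)
    exact = p_si * z * F * u_safe * (c_in - c_out * np.exp(-u_safe)) / -np.expm1(-u_safe)
    # series about u=0: P z F [(c_in - c_out) + u (c_in + c_out)/2]
    series = p_si * z * F * ((c_in - c_out) + u * (c_in + c_out) / 2.0)
    i_si = np.where(small, series, exact)  # A/m^2
    out = i_si * 100.0  # A/m^2 -> uA/cm^2
    return float(out) if np.isscalar(v_mV) or out.ndim == 0 else out


def total_ghk_current(
    perms: PermeabilitySet,
    v_mV: float | np.ndarray,
    external: Composition,
    internal: Composition,
    env: Environment | None = None,
    reference_perm_cm_s: float = 1.0,
) -> float | np.ndarray:
    """Summed GHK current over all permeant ions, uA/cm^2.

    ``reference_perm_cm_s`` is the absolute permeability assigned to the
    reference ion; other ions scale by their ratios.  With the default of 1
    the result is a dimensionless current *shape* useful for normalized work.
    """
    env = env or Environment()
    total: float | np.ndarray = 0.0
    for ion, p in perms.items():
        if p == 0.0:
            continue
        total = total + ghk_current_density(
            reference_perm_cm_s * p, ion, v_mV, internal.get(ion), external.get(ion), env
        )
    return total


def _model_reversals(
    log_ratios: np.ndarray,
    free_ions: Sequence[str],
    fixed: Mapping[str, float],
    reference: str,
    conditions: GHKConditionSet,
) -> np.ndarray:
    ratios = dict(fixed)
    ratios[reference] = 1.0
    for ion, lr in zip(free_ions, log_ratios):
        ratios[ion] = math.exp(lr)
    perms = PermeabilitySet(ratios, reference=reference)
    return np.array(
        [
            ghk_reversal_potential(perms, c.external, conditions.internal, conditions.env)
            for c in conditions.conditions
        ]
    )


@dataclass
class PermeabilityRatioFit:
    """Result of the inverse GHK problem."""

    perms: PermeabilitySet
    free_ions: tuple[str, ...]
    log_ratio_cov: np.ndarray  # linearized covariance of log-ratios
    residuals_mV: np.ndarray
    cost: float
    converged: bool
    message: str

    def ratio_se(self) -> dict[str, float]:
        """Approximate standard errors of the ratios (delta method)."""
        se = {}
        for i, ion in enumerate(self.free_ions):
            se[ion] = self.perms.get(ion) * math.sqrt(max(self.log_ratio_cov[i, i], 0.0))
        return se


def solve_permeability_ratios(
    conditions: GHKConditionSet,
    free_ions: Sequence[str],
    reference: str = "K",
    fixed: Mapping[str, float] | None = None,
) -> PermeabilityRatioFit:
    """Estimate relative permeabilities from multi-condition reversal potentials.

    Minimizes sum_c w_c (E_rev,model(c) - E_rev,measured(c))^2 over the
    log-ratios of ``free_ions`` (positivity enforced by the log transform).
    Weights are n_c / SD_c^2 when every condition carries an SD, else 1.
    Three starts spanning ratios 1e-3 to 10 guard against boundary minima.

    Raises
    ------
    IdentifiabilityError
        Fewer conditions than free ratios.
    FitFailureError
        No start converged.
    """
    free_ions = tuple(free_ions)
    fixed = dict(fixed or {})
    for ion in free_ions:
        ion_valence(ion)
    if reference in free_ions:
        raise GHKError(f"reference ion {reference!r} cannot be free (fixed at 1)")
    n_cond = len(conditions)
    if n_cond < len(free_ions):
        raise IdentifiabilityError(
            f"{n_cond} condition(s) cannot identify {len(free_ions)} free ratio(s); "
            "need at least as many conditions as free ratios"
        )

    measured = np.array([c.e_rev_mV for c in conditions.conditions])
    sds = [c.sd_mV for c in conditions.conditions]
    ns = [c.n for c in conditions.conditions]
    if all(s is not None and s > 0 for s in sds):
        w = np.array([(n or 1) / s**2 for s, n in zip(sds, ns)])
    else:
        w = np.ones(n_cond)
    sqrt_w = np.sqrt(w)

    def resid(lr: np.ndarray) -> np.ndarray:
        return sqrt_w * (_model_reversals(lr, free_ions, fixed, reference, conditions) - measured)

    starts = [math.log(r) for r in (1e-3, 0.3, 10.0)]
    best = None
    for s in starts:
        x0 = np.full(len(free_ions), s)
        try:
            res = least_squares(
                resid,
                x0,
                bounds=(-30.0, 10.0),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:  # singular models at extreme starts
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        diag = "" if best is None else f" (last status: {best.message})"
        raise FitFailureError("permeability-ratio optimization failed to converge" + diag)

    # linearized covariance of log-ratios: s^2 (J^T J)^{-1} on weighted residuals
    J = best.jac
    dof = max(n_cond - len(free_ions), 1)
    s2 = 2 * best.cost / dof
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.full((len(free_ions), len(free_ions)), np.nan)

    ratios = dict(fixed)
    ratios[reference] = 1.0
    for ion, lr in zip(free_ions, best.x):
        ratios[ion] = math.exp(lr)
    return PermeabilityRatioFit(
        perms=PermeabilitySet(ratios, reference=reference),
        free_ions=free_ions,
        log_ratio_cov=cov,
        residuals_mV=resid(best.x) / sqrt_w,
        cost=float(best.cost),
        converged=bool(best.success),
        message=str(best.message),
    )
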