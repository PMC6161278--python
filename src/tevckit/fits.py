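"""Nonlinear least-squares estimators with confidence intervals.

Two fitters:

* :func:`fit_activation_exponential` — mono-exponential current relaxation
  I(t) = A exp(-t/tau) + Iinf after a voltage step.
* :func:`fit_boltzmann` — modified Boltzmann open-probability curve
  P(V) = (Pmax - Pmin)/(1 + exp(zd F (V - V0.5)/RT)) + Pmin.

Both use analytic Jacobians, data-driven initialization, and five jittered
restarts (seeded) before declaring non-convergence.  95% confidence
intervals come from the linearized covariance s^2 (J^T J)^-1 with the
t-quantile by default; a seeded residual bootstrap is available.  Degenerate
inputs (flat signals) yield flagged results rather than exceptions so that
cohort pipelines keep running.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .gating import BoltzmannParams, ExpRelaxation, boltzmann_open_probability
from .ghk import Environment, FitFailureError, IdentifiabilityError

__all__ = [
    "ExpFitResult",
    "BoltzmannFit",
    "fit_activation_exponential",
    "fit_boltzmann",
]

_TIGHT = dict(xtol=1e-15, ftol=1e-15, gtol=1e-15)


def _linearized_ci(theta, jac, resid, alpha=0.05):
    """(lo, hi) per parameter from s^2 (J^T J)^-1 with the t-quantile.

    Returns (ci array, se array, singular flag).
    """
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    JtJ = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        singular = False
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        singular = True
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = stats.t.ppf(1 - alpha / 2, dof)
    ci = np.column_stack([theta - tq * se, theta + tq * se])
    return ci, se, singular


@dataclass
class ExpFitResult:
    """Mono-exponential fit: point estimate, 95% CIs, diagnostics."""

    params: ExpRelaxation
    ci: dict[str, tuple[float, float]]
    rmse: float
    converged: bool
    non_identifiable: bool
    boundary_warning: bool
    message: str
    ci_method: str = "linearized"


@dataclass
class BoltzmannFit:
    """Modified-Boltzmann fit: point estimate, 95% CIs, diagnostics."""

    params: BoltzmannParams
    ci: dict[str, tuple[float, float]]
    residuals: np.ndarray
    rmse: float
    converged: bool
    non_identifiable: bool  # zd CI spans 0
    degenerate: bool
    message: str
    ci_method: str = "linearized"
    fixed_p_max: bool = False


def _exp_model(theta, t):
    a, log_tau, iinf = theta
    return a * np.exp(-t / np.exp(log_tau)) + iinf


def _exp_jac(theta, t):
    a, log_tau, iinf = theta
    tau = np.exp(log_tau)
    e = np.exp(-t / tau)
    return np.column_stack([e, a * e * (t / tau), np.ones_like(t)])


def fit_activation_exponential(
    t_s: np.ndarray,
    i_uA: np.ndarray,
    seed: int = 0,
    alpha: float = 0.05,
) -> ExpFitResult:
    """Fit I(t) = A exp(-t/tau) + Iinf to a post-onset sweep segment.

    The caller supplies the segment (starting after the capacitive onset;
    a 10 ms offset is the pipeline default).  Time is re-referenced to the
    first sample, so A is the decaying amplitude at segment start.
    Initialization: Iinf from the last 10% of samples, A from the first
    sample, tau from the e-fold crossing time (grid fallback).  tau is
    optimized in log-space to enforce positivity.
    """
    t = np.asarray(t_s, dtype=float)
    i = np.asarray(i_uA, dtype=float)
    if t.shape != i.shape or t.ndim != 1:
        raise ValueError("t and I must be 1-D arrays of equal length")
    if len(t) < 10:
        raise ValueError(f"need >= 10 samples, got {len(t)}")
    order = np.argsort(t)
    t = t[order] - t[order][0]
    i = i[order]
    span = t[-1]

    n_tail = max(1, len(t) // 10)
    iinf0 = float(i[-n_tail:].mean())
    a0 = float(i[0] - iinf0)
    scale = max(abs(a0), abs(iinf0), 1e-12)

    # flat signal: no decaying component to estimate
    if abs(a0) < 1e-10 * scale or np.ptp(i) == 0.0:
        a_hat = float(i[0] - i.mean())
        return ExpFitResult(
            params=ExpRelaxation(amplitude=a_hat, steady=float(i.mean()), tau=span or 1.0),
            ci={"amplitude": (np.nan, np.nan), "steady": (np.nan, np.nan), "tau": (np.nan, np.nan)},
            rmse=float(np.sqrt(np.mean((i - i.mean()) ** 2))),
            converged=True,
            non_identifiable=True,
            boundary_warning=False,
            message="flat segment: amplitude ~ 0, tau not identifiable",
        )

    # e-fold crossing of |I - Iinf|
    target = abs(a0) / np.e
    dev = np.abs(i - iinf0)
    below = np.flatnonzero(dev <= target)
    tau0 = float(t[below[0]]) if below.size and below[0] > 0 else span / 3
    tau_grid = [tau0] + [span * f for f in (0.05, 0.2, 0.5)]

    rng = np.random.default_rng(seed)
    best = None
    starts = []
    for tg in tau_grid:
        starts.append(np.array([a0, np.log(max(tg, 1e-6)), iinf0]))
    for _ in range(5):
        jit = rng.normal(1.0, 0.2, size=3)
        starts.append(np.array([a0 * jit[0], np.log(max(tau0, 1e-6)) + jit[1] - 1.0, iinf0 * jit[2]]))
    for x0 in starts:
        try:
            res = least_squares(
                lambda th: _exp_model(th, t) - i, x0, jac=lambda th: _exp_jac(th, t), **_TIGHT
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitFailureError(
            "exponential fit failed after multi-start"
            + ("" if best is None else f" (last: {best.message})")
        )

    a, log_tau, iinf = best.x
    tau = float(np.exp(log_tau))
    resid = _exp_model(best.x, t) - i
    ci_raw, se, singular = _linearized_ci(best.x, _exp_jac(best.x, t), resid, alpha)
    # delta method: CI of tau from CI of log(tau)
    ci = {
        "amplitude": (float(ci_raw[0, 0]), float(ci_raw[0, 1])),
        "tau": (float(np.exp(ci_raw[1, 0])), float(np.exp(ci_raw[1, 1]))),
        "steady": (float(ci_raw[2, 0]), float(ci_raw[2, 1])),
    }
    boundary = tau > 100 * span or tau < 1e-5 * span
    return ExpFitResult(
        params=ExpRelaxation(amplitude=float(a), steady=float(iinf), tau=tau),
        ci=ci,
        rmse=float(np.sqrt(np.mean(resid**2))),
        converged=bool(best.success),
        non_identifiable=singular,
        boundary_warning=boundary,
        message=str(best.message) + ("; tau near search boundary" if boundary else ""),
    )


def _boltz_model(theta, v, vt, fixed_pmax):
    zd, vhalf, pmax, pmin = _boltz_unpack(theta, fixed_pmax)
    return (pmax - pmin) / (1.0 + np.exp(zd * (v - vhalf) / vt)) + pmin


def _boltz_unpack(theta, fixed_pmax):
    if fixed_pmax is None:
        return theta[0], theta[1], theta[2], theta[3]
    return theta[0], theta[1], fixed_pmax, theta[2]


def _boltz_jac(theta, v, vt, fixed_pmax):
    zd, vhalf, pmax, pmin = _boltz_unpack(theta, fixed_pmax)
    x = zd * (v - vhalf) / vt
    e = np.exp(x)
    denom = (1.0 + e) ** 2
    d_zd = -(pmax - pmin) * e / denom * (v - vhalf) / vt
    d_vhalf = (pmax - pmin) * e / denom * zd / vt
    d_pmax = 1.0 / (1.0 + e)
    d_pmin = 1.0 - d_pmax
    if fixed_pmax is None:
        return np.column_stack([d_zd, d_vhalf, d_pmax, d_pmin])
    return np.column_stack([d_zd, d_vhalf, d_pmin])


def fit_boltzmann(
    voltages_mV: np.ndarray,
    p_o: np.ndarray,
    fix_p_max: bool = False,
    env: Environment | None = None,
    ci_method: str = "linearized",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BoltzmannFit:
    """Fit the modified Boltzmann curve to (V, Po) points.

    Free parameters (zd, V0.5, Pmax, Pmin); ``fix_p_max`` pins Pmax = 1 as
    normalized open-probability data imply.  Initialization: Pmax <- max Po,
    Pmin <- min Po, V0.5 <- voltage nearest the mid-range Po, zd <- 0.01.
    ``ci_method``: "linearized" (default) or "bootstrap" (residual
    resampling, ``n_boot`` replicates, seeded).
    """
    env = env or Environment()
    v = np.asarray(voltages_mV, dtype=float)
    p = np.asarray(p_o, dtype=float)
    if v.shape != p.shape or v.ndim != 1:
        raise ValueError("voltages and Po must be 1-D arrays of equal length")
    n_params = 3 if fix_p_max else 4
    if len(np.unique(v)) < n_params:
        raise IdentifiabilityError(
            f"need >= {n_params} distinct voltages for {n_params} free parameters, "
            f"got {len(np.unique(v))}"
        )
    vt = env.thermal_voltage_mV
    fixed_pmax = 1.0 if fix_p_max else None

    pmax0 = float(p.max())
    pmin0 = float(p.min())
    mid = (pmax0 + pmin0) / 2
    vhalf0 = float(v[np.argmin(np.abs(p - mid))])
    zd0 = 0.01

    degenerate_flat = np.ptp(p) < 1e-12

    def pack(zd, vhalf, pmin, pmax=None):
        if fixed_pmax is None:
            return np.array([zd, vhalf, pmax if pmax is not None else pmax0, pmin])
        return np.array([zd, vhalf, pmin])

    rng = np.random.default_rng(seed)
    starts = [pack(zd0, vhalf0, pmin0)]
    if fixed_pmax is None:
        starts.append(pack(zd0, vhalf0, pmin0 - 0.3, pmax0 + 0.3))
    for _ in range(5):
        starts.append(
            pack(
                zd0 * np.exp(rng.normal(0, 1)),
                vhalf0 + rng.normal(0, 0.25) * (v.max() - v.min()),
                pmin0 + rng.normal(0, 0.1),
                pmax0 + rng.normal(0, 0.1),
            )
        )

    lo = [0.0, -1e4, -1.0] if fixed_pmax is not None else [0.0, -1e4, -1.0, -1.0]
    hi = [50.0, 1e4, 2.0] if fixed_pmax is not None else [50.0, 1e4, 2.0, 2.0]
    if fixed_pmax is None:
        lo = [0.0, -1e4, -1.0, -1.0]
        hi = [50.0, 1e4, 2.0, 2.0]

    def resid_fn(th):
        return _boltz_model(th, v, vt, fixed_pmax) - p

    best = None
    for x0 in starts:
        x0c = np.clip(x0, lo, hi)
        try:
            res = least_squares(
                resid_fn,
                x0c,
                jac=lambda th: _boltz_jac(th, v, vt, fixed_pmax),
                bounds=(lo, hi),
                **_TIGHT,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("Boltzmann fit failed in every start")

    zd, vhalf, pmax, pmin = _boltz_unpack(best.x, fixed_pmax)
    resid = resid_fn(best.x)
    jac = _boltz_jac(best.x, v, vt, fixed_pmax)
    names = ["z_delta", "v_half", "p_min"] if fix_p_max else ["z_delta", "v_half", "p_max", "p_min"]

    if ci_method == "bootstrap":
        fitted = _boltz_model(best.x, v, vt, fixed_pmax)
        centered = resid - resid.mean()
        draws = np.empty((n_boot, len(best.x)))
        brng = np.random.default_rng(seed + 1)
        for b in range(n_boot):
            pb = fitted + brng.choice(centered, size=len(centered), replace=True)
            try:
                rb = least_squares(
                    lambda th: _boltz_model(th, v, vt, fixed_pmax) - pb,
                    best.x,
                    jac=lambda th: _boltz_jac(th, v, vt, fixed_pmax),
                    bounds=(lo, hi),
                    xtol=1e-10,
                    ftol=1e-10,
                )
                draws[b] = rb.x
            except Exception:
                draws[b] = np.nan
        ci_arr = np.nanpercentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0).T
        singular = False
    else:
        ci_arr, se, singular = _linearized_ci(best.x, jac, resid, alpha)

    ci = {nm: (float(ci_arr[k, 0]), float(ci_arr[k, 1])) for k, nm in enumerate(names)}
    if fix_p_max:
        ci["p_max"] = (1.0, 1.0)
    zd_ci = ci["z_delta"]
    non_ident = degenerate_flat or singular or not np.isfinite(zd_ci[0]) or zd_ci[0] <= 0.0 <= zd_ci[1]

    # clamp tiny numerical excursions so the params object validates
    params = BoltzmannParams(
        z_delta=max(float(zd), 0.0),
        v_half=float(vhalf),
        p_max=float(np.clip(max(pmax, pmin), 0.0, 1.0)),
        p_min=float(np.clip(min(pmin, pmax), 0.0, 1.0)),
    )
    return BoltzmannFit(
        params=params,
        ci=ci,
        residuals=resid,
        rmse=float(np.sqrt(np.mean(resid**2))),
        converged=bool(best.success),
        non_identifiable=bool(non_ident),
        degenerate=bool(degenerate_flat or singular),
        message=str(best.message),
        ci_method=ci_method,
        fixed_p_max=fix_p_max,
    )
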