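"""Group comparisons: per-voltage Student's t-tests and Dunnett's
many-to-one multiple-comparison procedure.

Dunnett critical values are obtained by a seeded Monte-Carlo approximation of
the null distribution of max_i |t_i| under equal-variance normality, where
t_i compares treatment i against the shared control using the pooled mean
square error across all groups.  The draw count (default 1e5) is
configurable; p-values are the Monte-Carlo tail fractions of the same null
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "student_t_test",
    "dunnett_test",
    "dunnett_critical_value",
]


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_value: float
    significant: bool
    alpha: float
    voltage_mV: float | None = None
    method: str = "t-test"


def student_t_test(
    a: np.ndarray,
    b: np.ndarray,
    pooled: bool = True,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    voltage_mV: float | None = None,
) -> ComparisonResult:
    """Two-tailed two-sample t-test (classical pooled-variance Student by
    default; Welch with ``pooled=False``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"each sample needs n >= 2, got {len(a)} and {len(b)}")
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = len(a) + len(b) - 2
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        denom = va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        df = (va + vb) ** 2 / denom if denom > 0 else len(a) + len(b) - 2
    # identical samples: define t = 0, p = 1 (scipy returns nan for 0/0)
    if np.isnan(t):
        t, p = 0.0, 1.0
    return ComparisonResult(
        group_a=labels[0],
        group_b=labels[1],
        statistic=float(t),
        df=float(df),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
        voltage_mV=voltage_mV,
        method="student-t" if pooled else "welch-t",
    )


def _dunnett_null_maxabs(
    n_control: int, n_treat: tuple[int, ...], n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo sample of max_i |t_i| under the global null.

    All groups standard normal; t_i uses the pooled MSE over the k+1 groups
    with df = N - (k + 1).
    """
    k = len(n_treat)
    sizes = (n_control,) + tuple(n_treat)
    N = sum(sizes)
    df = N - (k + 1)
    # group means and within-group sums of squares, vectorized over draws
    means = np.empty((n_draws, k + 1))
    ss = np.zeros(n_draws)
    for j, n in enumerate(sizes):
        x = rng.standard_normal((n_draws, n))
        m = x.mean(axis=1)
        means[:, j] = m
        ss += ((x - m[:, None]) ** 2).sum(axis=1)
    mse = ss / df
    tstats = np.empty((n_draws, k))
    for i, n in enumerate(n_treat):
        se = np.sqrt(mse * (1.0 / n + 1.0 / n_control))
        tstats[:, i] = (means[:, i + 1] - means[:, 0]) / se
    return np.abs(tstats).max(axis=1)


def dunnett_critical_value(
    n_control: int,
    n_treat: tuple[int, ...],
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 12345,
) -> float:
    """Two-sided Dunnett critical value for max_i |t_i| by seeded Monte Carlo."""
    rng = np.random.default_rng(seed)
    null = _dunnett_null_maxabs(n_control, tuple(n_treat), n_draws, rng)
    return float(np.quantile(null, 1.0 - alpha))


def dunnett_test(
    control: np.ndarray,
    treatments: list[np.ndarray],
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 12345,
    labels: list[str] | None = None,
    voltage_mV: float | None = None,
    null_sample: np.ndarray | None = None,
) -> list[ComparisonResult]:
    """Dunnett's many-to-one comparisons against a shared control.

    Each treatment i is compared with the control via
    t_i = (mean_i - mean_0)/sqrt(MSE (1/n_i + 1/n_0)), MSE pooled over all
    groups.  Significance and adjusted p-values refer to the Monte-Carlo
    null distribution of max_i |t_i| (family-wise control at ``alpha``).
    ``null_sample`` lets callers reuse one precomputed null sample (e.g. for
    many voltages with identical group sizes).
    """
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(t, dtype=float) for t in treatments]
    if len(treatments) < 1:
        raise ValueError("need at least one treatment group")
    if len(control) < 2 or any(len(t) < 2 for t in treatments):
        raise ValueError("every group needs n >= 2")
    labels = labels or [f"treatment_{i + 1}" for i in range(len(treatments))]

    k = len(treatments)
    groups = [control] + treatments
    N = sum(len(g) for g in groups)
    df = N - (k + 1)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df

    if null_sample is None:
        rng = np.random.default_rng(seed)
        null = _dunnett_null_maxabs(len(control), tuple(len(t) for t in treatments), n_draws, rng)
    else:
        null = np.asarray(null_sample, dtype=float)
    crit = float(np.quantile(null, 1.0 - alpha))

    out = []
    for lbl, tgrp in zip(labels, treatments):
        se = np.sqrt(mse * (1.0 / len(tgrp) + 1.0 / len(control)))
        t = (tgrp.mean() - control.mean()) / se if se > 0 else 0.0
        p_adj = float((null >= abs(t)).mean())
        out.append(
            ComparisonResult(
                group_a="control",
                group_b=lbl,
                statistic=float(t),
                df=float(df),
                p_value=p_adj,
                significant=bool(abs(t) > crit),
                alpha=alpha,
                voltage_mV=voltage_mV,
                method="dunnett-mc",
            )
        )
    return out
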