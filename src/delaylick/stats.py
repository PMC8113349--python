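"""Shared resampling and classical tests.

Every test returns a :class:`TestResult` that serializes to JSON, so that
downstream modules (behavior comparisons, selectivity, photometry, slice
electrophysiology) report statistics in a uniform way.  Resampling tests are
seed-reproducible and use add-one smoothing, ``p = (k + 1) / (n + 1)``, so a
finite number of resamples never yields p = 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bootstrap_p",
    "permutation_p",
    "chi_squared_2x2",
    "rm_anova2",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Observed test statistic.
    p_value : float
        Two-sided p-value in [0, 1] unless ``tails == "one"``.
    method : str
        Human-readable label of the procedure.
    n_resamples : int or None
        Number of resamples for bootstrap/permutation tests, None for
        closed-form tests.
    tails : str
        "two" (default) or "one".
    seed : int or None
        Seed used for the resampling stream, for reproducibility.
    extra : dict
        Method-specific extras (df, exact-enumeration flag, ...).
    """

    statistic: float
    p_value: float
    method: str
    n_resamples: int | None = None
    tails: str = "two"
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float)


def _smooth_p(k: int, n: int) -> float:
    return (k + 1) / (n + 1)


def bootstrap_p(
    values_by_unit: Sequence[float] | np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n: int = 5000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided bootstrap test that a per-unit statistic differs from zero.

    Units (sessions, mice, session-pairs) are resampled with replacement
    ``n`` times; the p-value is twice the smaller tail probability of the
    resampled statistic's sign, with add-one smoothing.  Resamples on which
    the statistic is undefined (NaN) are redrawn and counted in
    ``extra["n_redrawn"]``.
    """
    values = np.asarray(values_by_unit, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D array with at least 2 units")
    rng = np.random.default_rng(seed)
    stat_obs = float(statistic(values))
    m = values.size
    boot = np.empty(n)
    n_redrawn = 0
    for i in range(n):
        while True:
            s = float(statistic(values[rng.integers(0, m, size=m)]))
            if not math.isnan(s):
                break
            n_redrawn += 1
        boot[i] = s
    k_lo = int(np.sum(boot <= 0))
    k_hi = int(np.sum(boot >= 0))
    p = min(1.0, 2.0 * min(_smooth_p(k_lo, n), _smooth_p(k_hi, n)))
    return TestResult(
        statistic=stat_obs,
        p_value=p,
        method="bootstrap (unit resampling, sign of statistic)",
        n_resamples=n,
        seed=seed,
        extra={"n_units": m, "n_redrawn": n_redrawn},
    )


def _mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a) - np.mean(b))


def permutation_p(
    group_a: Sequence[float] | np.ndarray,
    group_b: Sequence[float] | np.ndarray,
    statistic: Callable[[np.ndarray, np.ndarray], float] = _mean_difference,
    n: int = 5000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided permutation test on two independent groups.

    Labels are shuffled ``n`` times (or all label assignments are enumerated
    exactly when there are no more than ``n`` of them); the p-value is the
    fraction of shuffles with ``|stat*| >= |stat_obs|``.  Monte-Carlo p-values
    use add-one smoothing; exact enumeration reports the exact fraction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    na, ntot = a.size, a.size + b.size
    stat_obs = float(statistic(a, b))

    n_exact = math.comb(ntot, na)
    if n_exact <= n:
        k = 0
        idx_all = np.arange(ntot)
        for idx_a in combinations(range(ntot), na):
            mask = np.zeros(ntot, dtype=bool)
            mask[list(idx_a)] = True
            s = statistic(pooled[mask], pooled[~mask])
            if abs(s) >= abs(stat_obs) - 1e-12:
                k += 1
        return TestResult(
            statistic=stat_obs,
            p_value=k / n_exact,
            method="permutation (exact enumeration)",
            n_resamples=n_exact,
            seed=seed,
            extra={"exact": True},
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n):
        perm = rng.permutation(ntot)
        s = statistic(pooled[perm[:na]], pooled[perm[na:]])
        if abs(s) >= abs(stat_obs) - 1e-12:
            count += 1
    return TestResult(
        statistic=stat_obs,
        p_value=min(1.0, _smooth_p(count, n)),
        method="permutation (label shuffling)",
        n_resamples=n,
        seed=seed,
        extra={"exact": False},
    )


def chi_squared_2x2(table: Sequence[Sequence[int]] | np.ndarray,
                    correction: bool = False) -> TestResult:
    """Pearson chi-squared test on a 2x2 contingency table.

    Continuity correction is off by default.  df = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.round(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = sps.chi2_contingency(t, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="chi-squared 2x2"
        + (" (Yates corrected)" if correction else " (uncorrected)"),
        extra={"df": 1, "table": t.tolist()},
    )


def rm_anova2(cell_means: np.ndarray) -> dict[str, TestResult]:
    """Two-way repeated-measures ANOVA on per-cell subject means.

    Parameters
    ----------
    cell_means : ndarray, shape (subjects, levels_A, levels_B)
        One mean per subject and design cell; the design must be complete
        (no NaN) and balanced by construction of the array.

    Returns
    -------
    dict
        Keys ``"A"``, ``"B"``, ``"AxB"``; each effect is tested against its
        own effect-by-subject interaction mean square (univariate
        within-subject decomposition, no sphericity correction).
    """
    y = np.asarray(cell_means, dtype=float)
    if y.ndim != 3:
        raise ValueError("cell_means must be subjects x A x B")
    if np.any(np.isnan(y)):
        raise ValueError("missing design cells; no imputation is performed")
    s, a, b = y.shape
    if s < 2 or a < 2 or b < 2:
        raise ValueError("need >=2 subjects and >=2 levels per factor")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means
    m_a = y.mean(axis=(0, 2))          # factor-A level means
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)              # subject x A
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = s * b * np.sum((m_a - grand) ** 2)
    ss_b = s * a * np.sum((m_b - grand) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_sab = np.sum(resid ** 2)

    def _f(ss_eff, df_eff, ss_err, df_err, label):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            f, p = np.inf, 0.0
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df_eff, df_err))
        return TestResult(
            statistic=float(f),
            p_value=p,
            method=f"repeated-measures two-way ANOVA, effect {label}",
            extra={"df": [df_eff, df_err], "ss_effect": float(ss_eff),
                   "ss_error": float(ss_err)},
        )

    return {
        "A": _f(ss_a, a - 1, ss_sa, (a - 1) * (s - 1), "A"),
        "B": _f(ss_b, b - 1, ss_sb, (b - 1) * (s - 1), "B"),
        "AxB": _f(ss_ab, (a - 1) * (b - 1), ss_sab,
                  (a - 1) * (b - 1) * (s - 1), "AxB"),
    }
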