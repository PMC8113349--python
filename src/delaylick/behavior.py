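"""Psychometric fitting and session-level behavioral metrics.

The psychometric model is the 4-parameter sigmoid

    P(lick right) = y0 + a / (1 + exp(-(x - x0) / b))

with x the normalized log click rate, x0 the inflection point, b the slope
scale, y0 the lower asymptote and a + y0 the upper asymptote.  Fitting is
bounded least squares on per-rate choice proportions with 5 random restarts;
probabilistic bounds (y0, a in [0, 1]) keep the fitted curve a valid
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import validate_trials
from .stats import TestResult
from .synth import psychometric_curve

__all__ = ["PsychometricFit", "SessionMetrics", "fit_psychometric",
           "session_metrics", "compare_conditions", "DELAY_BINS"]

#: Delay bins for accuracy/violation/RT-by-delay curves: 4 equal-width bins
#: over the 0.3-1.5 s delay range.
DELAY_BINS = np.linspace(0.3, 1.5, 5)

N_STARTS = 5


@dataclass
class PsychometricFit:
    x0: float
    b: float
    y0: float
    a: float
    rss: float
    rates: np.ndarray
    p_right: np.ndarray
    n_trials_per_rate: np.ndarray
    converged: bool = True
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return psychometric_curve(x, self.x0, self.b, self.y0, self.a)


@dataclass
class SessionMetrics:
    accuracy: float          # over scored (correct/error) trials; NaN if none
    violation_rate: float
    miss_rate: float
    median_rt: float         # seconds, over correct trials
    n_trials: int
    by_delay: pd.DataFrame   # per-delay-bin accuracy, violation rate, median RT


def _empirical_proportions(trials: pd.DataFrame):
    scored = trials[trials["outcome"].isin(["correct", "error"])]
    g = scored.groupby("log_rate_norm")["choice"]
    x = np.array(sorted(g.groups))
    p = np.array([(g.get_group(k) == "right").mean() for k in x])
    n = np.array([len(g.get_group(k)) for k in x])
    return x, p, n


def _fit_once(x, p, w, start, bounds):
    def resid(theta):
        return np.sqrt(w) * (psychometric_curve(x, *theta) - p)
    return least_squares(resid, start, bounds=bounds, method="trf")


def fit_psychometric(trials: pd.DataFrame | None,
                     level: str = "pooled",
                     proportions: tuple | None = None
                     ) -> "PsychometricFit | dict":
    """Fit the 4-parameter sigmoid to choice proportions.

    ``level`` selects pooling: "pooled" (all trials), "animal" or "session"
    (returns a dict keyed by id).  Violation and miss trials are excluded.
    Proportions are weighted by trial counts.  Summary data can be fit
    directly by passing ``proportions = (x, p_right, n_per_rate)`` instead
    of a trial table.  Non-convergence or a fit pinned at the parameter
    bounds is flagged on the returned object rather than raised.
    """
    if proportions is not None:
        x, p, n = (np.asarray(v, dtype=float) for v in proportions)
    else:
        validate_trials(trials)
        if level == "animal":
            return {k: fit_psychometric(g, "pooled")
                    for k, g in trials.groupby("subject_id")}
        if level == "session":
            return {k: fit_psychometric(g, "pooled")
                    for k, g in trials.groupby("session_id")}
        if level != "pooled":
            raise ValueError("level must be 'pooled', 'animal' or 'session'")
        x, p, n = _empirical_proportions(trials)
    if len(x) < 2:
        raise ValueError("need >=2 distinct click rates with scored choices")
    w = n / n.sum()

    span = x.max() - x.min()
    lo = np.array([x.min() - span, 1e-3, 0.0, 0.0])
    hi = np.array([x.max() + span, 10.0 * span, 1.0, 1.0])
    rng = np.random.default_rng(0)
    starts = [np.array([0.0, 0.25 * span, 0.05, 0.9])]
    starts += [rng.uniform(lo, hi) for _ in range(N_STARTS - 1)]

    best, best_rss = None, np.inf
    any_ok = False
    for s0 in starts:
        try:
            res = _fit_once(x, p, w, np.clip(s0, lo, hi), (lo, hi))
        except Exception:
            continue
        any_ok = any_ok or res.success
        rss = float(2.0 * res.cost)
        if res.success and rss < best_rss:
            best, best_rss = res, rss
    notes = []
    if best is None:
        best = _fit_once(x, p, w, starts[0], (lo, hi))
        best_rss = float(2.0 * best.cost)
        notes.append("no start converged; reporting best attempt")

    x0, b, y0, a = best.x
    degenerate = bool(y0 > 0.95 or a < 0.05 or a + y0 > 1.0 + 1e-6
                      or y0 + a < 0.05)
    if degenerate:
        notes.append("fit at probability boundary (one-sided responder?)")
    return PsychometricFit(
        x0=float(x0), b=float(b), y0=float(y0), a=float(a), rss=best_rss,
        rates=x, p_right=p, n_trials_per_rate=n,
        converged=bool(any_ok), degenerate=degenerate, notes=notes)


def session_metrics(trials: pd.DataFrame) -> SessionMetrics:
    """Accuracy / violation / miss rates and median RT for one table.

    Accuracy is computed over scored trials only (violations and misses are
    excluded from the denominator); violation and miss rates are fractions
    of all trials; median RT uses correct trials.  Per-delay-bin breakdowns
    use :data:`DELAY_BINS`.
    """
    validate_trials(trials)
    n = len(trials)
    out = trials["outcome"]
    scored = trials[out.isin(["correct", "error"])]
    acc = float((scored["outcome"] == "correct").mean()) if len(scored) else np.nan
    med_rt = float(trials.loc[out == "correct", "rt"].median())

    rows = []
    bins = pd.cut(trials["delay"], DELAY_BINS, include_lowest=True)
    for iv, g in trials.groupby(bins, observed=False):
        gs = g[g["outcome"].isin(["correct", "error"])]
        rows.append({
            "delay_bin": iv,
            "accuracy": float((gs["outcome"] == "correct").mean())
            if len(gs) else np.nan,
            "violation_rate": float((g["outcome"] == "violation").mean())
            if len(g) else np.nan,
            "median_rt": float(g.loc[g["outcome"] == "correct", "rt"].median()),
            "n": len(g),
        })
    return SessionMetrics(
        accuracy=acc,
        violation_rate=float((out == "violation").mean()),
        miss_rate=float((out == "miss").mean()),
        median_rt=med_rt,
        n_trials=n,
        by_delay=pd.DataFrame(rows),
    )


def compare_conditions(a: pd.DataFrame, b: pd.DataFrame,
                       n_resamples: int = 5000,
                       seed: int | None = None) -> dict:
    """Paired comparison of two conditions (e.g. CNO vs saline sessions).

    Sessions are paired by ``session_id``; per pair the difference in error
    rate, violation rate and miss rate (means) and in RT (medians) is
    computed, then a two-sided sign-flip permutation test across pairs gives
    a p-value per metric.  Unpairable sessions raise with the orphan list.
    """
    sa, sb = set(a["session_id"]), set(b["session_id"])
    if sa != sb:
        raise ValueError(f"unpairable sessions: {sorted(sa ^ sb)}")

    deltas = {"error_rate": [], "violation_rate": [], "miss_rate": [],
              "median_rt": []}
    for sid in sorted(sa):
        ma = session_metrics(a[a["session_id"] == sid])
        mb = session_metrics(b[b["session_id"] == sid])
        deltas["error_rate"].append((1 - ma.accuracy) - (1 - mb.accuracy))
        deltas["violation_rate"].append(ma.violation_rate - mb.violation_rate)
        deltas["miss_rate"].append(ma.miss_rate - mb.miss_rate)
        deltas["median_rt"].append(ma.median_rt - mb.median_rt)

    rng = np.random.default_rng(seed)
    results: dict[str, TestResult] = {}
    for name, d in deltas.items():
        d = np.asarray(d, float)
        if np.any(np.isnan(d)):
            warnings.warn(f"NaN deltas dropped for {name}")
            d = d[~np.isnan(d)]
        obs = float(np.mean(d))
        m = len(d)
        if m <= 20:
            # exact sign-flip enumeration
            signs = np.array(np.meshgrid(
                *[[-1, 1]] * m, indexing="ij")).reshape(m, -1)
            null = (signs * d[:, None]).mean(axis=0)
            p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
            nres = null.size
        else:
            flips = rng.choice([-1.0, 1.0], size=(n_resamples, m))
            null = (flips * d[None, :]).mean(axis=1)
            k = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
            p = min(1.0, (k + 1) / (n_resamples + 1))
            nres = n_resamples
        results[name] = TestResult(
            statistic=obs, p_value=p,
            method="paired sign-flip permutation", n_resamples=nres,
            seed=seed, extra={"deltas": d.tolist()})
    return results
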