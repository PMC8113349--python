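"""Detection and characterization of optogenetically evoked EPSPs.

A transient is "significant" when the depolarization within 50 ms of a
light pulse exceeds 3 standard deviations of the 1-s pre-stimulation
baseline.  Responsiveness uses the trial-averaged 10-pulse train trace
(cells with strictly more than 40% significant transients are responsive);
reliability is the per-sweep significant-response probability on
single-pulse sweeps; latency (first threshold crossing) and amplitude
(maximum depolarization within 50 ms) are measured on the mean single-pulse
trace.  Only depolarizing deflections count — hyperpolarizing responses are
reported separately and never flagged as transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import SliceSweepSet
from .stats import TestResult, chi_squared_2x2, permutation_p

__all__ = ["CellResponse", "classify_responsive", "characterize_response",
           "compare_groups"]

RESPONSE_WINDOW_MS = 50.0
THRESHOLD_SD = 3.0
RESPONSIVE_FRAC = 0.40
BASELINE_S = 1.0


@dataclass
class CellResponse:
    responsive: bool | None = None
    reliability: float = np.nan
    latency_ms: float = np.nan
    amplitude_mv: float = np.nan
    transient_flags: np.ndarray | None = None   # per pulse (train protocol)
    sweep_flags: np.ndarray | None = None       # per sweep (single protocol)
    hyperpolarizing: bool = False
    cell_type: str = ""
    notes: list[str] = field(default_factory=list)


def _baseline_stats(trace: np.ndarray, sample_rate: float,
                    first_stim_s: float) -> tuple[float, float]:
    n0 = int(round((first_stim_s - BASELINE_S) * sample_rate))
    n1 = int(round(first_stim_s * sample_rate))
    if n1 - n0 < int(BASELINE_S * sample_rate) - 1:
        raise ValueError("baseline shorter than 1 s before stimulation")
    base = trace[n0:n1]
    return float(base.mean()), float(base.std(ddof=1))


def _pulse_significant(trace: np.ndarray, sample_rate: float, t_pulse: float,
                       mean: float, sd: float) -> tuple[bool, bool]:
    """(depolarizing transient?, hyperpolarizing deflection?) for one pulse."""
    i0 = int(round(t_pulse * sample_rate))
    i1 = int(round((t_pulse + RESPONSE_WINDOW_MS / 1e3) * sample_rate))
    seg = trace[i0:i1] - mean
    thr = THRESHOLD_SD * sd
    return bool(seg.max() > thr), bool(-seg.min() > thr)


def classify_responsive(sweeps: SliceSweepSet) -> CellResponse:
    """Responsiveness from the trial-averaged 10-pulse train trace."""
    if sweeps.stim_mode != "train10":
        raise ValueError("classification requires the 10-pulse train protocol")
    mean_trace = sweeps.vm.mean(axis=0)
    mu, sd = _baseline_stats(mean_trace, sweeps.sample_rate,
                             sweeps.stim_times[0])
    flags, hyper = [], []
    for t in sweeps.stim_times:
        dep, hyp = _pulse_significant(mean_trace, sweeps.sample_rate, t, mu, sd)
        flags.append(dep)
        hyper.append(hyp)
    flags = np.array(flags)
    frac = flags.mean()
    return CellResponse(
        responsive=bool(frac > RESPONSIVE_FRAC),
        transient_flags=flags,
        hyperpolarizing=bool(np.any(hyper)),
        cell_type=sweeps.cell_type,
        notes=[f"{int(flags.sum())}/{flags.size} significant transients"])


def characterize_response(sweeps: SliceSweepSet,
                          result: CellResponse | None = None) -> CellResponse:
    """Reliability, latency and amplitude from single-pulse sweeps.

    Reliability = fraction of individually significant sweeps (per-sweep
    baseline s.d.).  Latency and amplitude are measured on the mean trace:
    latency is the time from pulse onset to the first crossing of 3 s.d.
    of the mean-trace baseline; amplitude is the maximum depolarization
    above baseline within 50 ms.  A mean trace that never crosses
    threshold leaves the latency NaN with a note.
    """
    if sweeps.stim_mode != "single":
        raise ValueError("characterization requires single-pulse sweeps")
    if sweeps.vm.shape[0] < 5:
        warnings.warn("fewer than 5 single-pulse sweeps")
    res = result or CellResponse(cell_type=sweeps.cell_type)
    sr = sweeps.sample_rate
    t0 = float(sweeps.stim_times[0])

    per_sweep = []
    for s in range(sweeps.vm.shape[0]):
        mu, sd = _baseline_stats(sweeps.vm[s], sr, t0)
        dep, _ = _pulse_significant(sweeps.vm[s], sr, t0, mu, sd)
        per_sweep.append(dep)
    res.sweep_flags = np.array(per_sweep)
    res.reliability = float(res.sweep_flags.mean())

    mean_trace = sweeps.vm.mean(axis=0)
    mu, sd = _baseline_stats(mean_trace, sr, t0)
    i0 = int(round(t0 * sr))
    i1 = int(round((t0 + RESPONSE_WINDOW_MS / 1e3) * sr))
    seg = mean_trace[i0:i1] - mu
    res.amplitude_mv = float(max(seg.max(), 0.0))
    above = np.flatnonzero(seg > THRESHOLD_SD * sd)
    if above.size:
        res.latency_ms = float(above[0] / sr * 1e3)
    else:
        res.latency_ms = np.nan
        res.notes.append("mean trace never crossed threshold; latency undefined")
    return res


def compare_groups(cells_a: list[CellResponse], cells_b: list[CellResponse],
                   n_shuffles: int = 5000,
                   seed: int | None = None) -> dict:
    """Between-group tests on responsiveness and response metrics.

    Responsive proportions are compared with an uncorrected chi-squared
    test; latency, reliability and amplitude with two-sided 5000-shuffle
    permutation tests on the group mean difference (responsive cells with
    a defined metric only).  A metric missing in every cell of a group is
    skipped with a warning.
    """
    if not cells_a or not cells_b:
        raise ValueError("both groups must be non-empty")
    out: dict = {}
    tab = np.array([
        [sum(bool(c.responsive) for c in cells_a),
         sum(not c.responsive for c in cells_a)],
        [sum(bool(c.responsive) for c in cells_b),
         sum(not c.responsive for c in cells_b)],
    ])
    if np.any(tab.sum(axis=0) == 0):
        # every cell responsive (or none): the proportions are identical
        # and the chi-squared statistic degenerates to 0
        out["responsive_chi2"] = TestResult(
            statistic=0.0, p_value=1.0,
            method="chi-squared 2x2 (degenerate margin)",
            extra={"table": tab.tolist()})
    else:
        out["responsive_chi2"] = chi_squared_2x2(tab)
    out["responsive_counts"] = tab

    for metric in ("latency_ms", "reliability", "amplitude_mv"):
        va = np.array([getattr(c, metric) for c in cells_a
                       if c.responsive and not np.isnan(getattr(c, metric))])
        vb = np.array([getattr(c, metric) for c in cells_b
                       if c.responsive and not np.isnan(getattr(c, metric))])
        if va.size == 0 or vb.size == 0:
            warnings.warn(f"{metric}: missing in one group, test skipped")
            continue
        out[metric] = permutation_p(va, vb, n=n_shuffles, seed=seed)
    return out
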