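"""ΔF/F preprocessing and trial/epoch structuring of fluorescence traces.

Pipeline: (1) slow-drift correction by subtracting a rolling low percentile
(8th percentile over a 400-frame centered window for two-photon data; the
photometry stage reuses the same primitive with a 1000-frame window and the
5th percentile); (2) ΔF/F = (F - F0)/F0 with F0 the mode of the corrected
trace over the session, estimated as the center of the tallest
Freedman-Diaconis histogram bin; (3) per-trial subtraction of the pre-sound
baseline; (4) epoch averaging into sound / delay / response / lick windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochResponse, EventTimes, FluorescenceMatrix
from .synth import EPOCHS, SOUND_DURATION_S

__all__ = ["correct_slow_drift", "compute_dff", "trace_mode",
           "epoch_average", "preprocess_session"]

log = logging.getLogger(__name__)

DELAY_WINDOW_S = 0.5          # final 500 ms before the go cue
PRE_SOUND_BASELINE_S = 0.5


def correct_slow_drift(trace: np.ndarray, window_frames: int = 400,
                       percentile: float = 8.0) -> np.ndarray:
    """Subtract a rolling percentile from a 1-D (or frames x ROIs) trace.

    The window is centered on each frame; at the edges it is truncated to
    the available frames (no reflection — no look-ahead is fabricated).
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    t = np.asarray(trace, dtype=float)
    if t.ndim == 2:
        return np.column_stack([
            correct_slow_drift(t[:, j], window_frames, percentile)
            for j in range(t.shape[1])])
    n = t.shape[0]
    if n < 2:
        raise ValueError("trace must have at least 2 frames")

    half_lo = window_frames // 2
    half_hi = window_frames - half_lo
    base = np.empty(n)
    interior = slice(half_lo, max(half_lo, n - half_hi + 1))
    if n >= window_frames:
        from numpy.lib.stride_tricks import sliding_window_view
        windows = sliding_window_view(t, window_frames)
        base[interior] = np.percentile(windows, percentile, axis=1)
        edge_idx = [i for i in range(n)
                    if not (interior.start <= i < interior.stop)]
    else:
        edge_idx = range(n)
    for i in edge_idx:
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi)
        base[i] = np.percentile(t[lo:hi], percentile)
    return t - base


def trace_mode(trace: np.ndarray) -> float:
    """Mode of a continuous trace: center of the tallest histogram bin.

    Bin width follows the Freedman-Diaconis rule; a degenerate IQR falls
    back to numpy's automatic binning, and a constant trace returns its
    value directly.
    """
    t = np.asarray(trace, dtype=float).ravel()
    if t.max() == t.min():
        return float(t[0])
    vals, counts = np.unique(t, return_counts=True)
    if counts.max() > max(1, 0.05 * t.size):
        # heavily repeated value (quantized trace): exact mode
        return float(vals[np.argmax(counts)])
    iqr = np.subtract(*np.percentile(t, [75, 25]))
    if iqr <= 0:
        counts, edges = np.histogram(t, bins="auto")
    else:
        width = 2.0 * iqr / len(t) ** (1.0 / 3.0)
        nbins = max(1, int(np.ceil((t.max() - t.min()) / width)))
        counts, edges = np.histogram(t, bins=nbins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def compute_dff(corrected: np.ndarray, roi_labels: list[str] | None = None
                ) -> np.ndarray:
    """ΔF/F = (F - F0)/F0 per ROI, with F0 the session-wide trace mode.

    ``corrected`` is a drift-corrected frames (x ROIs) array.  A
    nonpositive F0 is an error naming the offending ROI — it means the
    trace has no positive baseline to normalize by.
    """
    f = np.asarray(corrected, dtype=float)
    if f.ndim == 1:
        f = f[:, None]
        squeeze = True
    else:
        squeeze = False
    labels = roi_labels or [f"roi{j:03d}" for j in range(f.shape[1])]
    out = np.empty_like(f)
    for j in range(f.shape[1]):
        f0 = trace_mode(f[:, j])
        if f0 <= 0:
            raise ValueError(f"nonpositive F0 for ROI {labels[j]!r}")
        out[:, j] = (f[:, j] - f0) / f0
    return out[:, 0] if squeeze else out


@dataclass
class _EpochWindows:
    start: np.ndarray  # trials x epochs, seconds
    stop: np.ndarray


def _windows(ev: EventTimes, lick_window_s: float) -> _EpochWindows:
    start = np.column_stack([
        ev.sound_onset,
        ev.go_cue - DELAY_WINDOW_S,
        ev.go_cue,
        ev.first_lick,
    ])
    stop = np.column_stack([
        ev.sound_onset + SOUND_DURATION_S,
        ev.go_cue,
        ev.first_lick,
        ev.first_lick + lick_window_s,
    ])
    return _EpochWindows(start, stop)


def epoch_average(dff: np.ndarray, events: EventTimes, trials: pd.DataFrame,
                  frame_rate: float, lick_window_s: float = 1.0,
                  exclude_short_delay: bool = False) -> EpochResponse:
    """Average ΔF/F per trial into the four behavioral epochs.

    Windows: sound = the 0.5-s stimulus; delay = the final 500 ms before
    the go cue; response = go cue to first lick; lick = ``lick_window_s``
    after the first lick.  Before averaging, the mean pre-sound baseline of
    each trial is subtracted from that trial's frames.  Only scored trials
    (correct/error, with a defined first lick and a nonzero response
    window) are kept; exclusion counts are logged and returned in
    ``flags``.  Trials with delay < 500 ms have a delay window overlapping
    the stimulus tail; they are flagged, and dropped if
    ``exclude_short_delay``.
    """
    d = np.atleast_2d(np.asarray(dff, float))
    if d.shape[0] == len(trials) and d.shape[0] != events.n_trials:
        raise ValueError("dff must be frames x ROIs for the whole session")
    if events.n_trials != len(trials):
        raise ValueError("event times do not match the trial table")

    win = _windows(events, lick_window_s)
    scored = trials["outcome"].isin(["correct", "error"]).to_numpy()
    has_events = ~np.isnan(win.start).any(axis=1) & ~np.isnan(win.stop).any(axis=1)
    nonzero_resp = np.where(np.isnan(events.first_lick), False,
                            events.first_lick > events.go_cue)
    keep = scored & has_events & nonzero_resp
    short_delay = trials["delay"].to_numpy() < DELAY_WINDOW_S
    if exclude_short_delay:
        keep &= ~short_delay
    n_drop = int(len(trials) - keep.sum())
    if n_drop:
        log.info("epoch_average: excluded %d/%d trials (unscored, missing "
                 "events, or zero-length response)", n_drop, len(trials))
    if keep.sum() == 0:
        raise ValueError("no usable trials after exclusions")

    idx = np.flatnonzero(keep)
    n_frames = d.shape[0]
    out = np.full((len(idx), d.shape[1], len(EPOCHS)), np.nan)
    for row, i in enumerate(idx):
        b0 = int(max(0, round((events.sound_onset[i] - PRE_SOUND_BASELINE_S)
                              * frame_rate)))
        b1 = int(round(events.sound_onset[i] * frame_rate))
        baseline = d[b0:b1].mean(axis=0) if b1 > b0 else 0.0
        for j in range(len(EPOCHS)):
            f0 = int(round(win.start[i, j] * frame_rate))
            f1 = int(round(win.stop[i, j] * frame_rate))
            f0, f1 = max(0, f0), min(n_frames, f1)
            if f1 > f0:
                out[row, :, j] = d[f0:f1].mean(axis=0) - baseline
    return EpochResponse(
        dff=out, epochs=list(EPOCHS),
        trials=trials.iloc[idx].reset_index(drop=True),
        flags={"n_excluded": n_drop,
               "n_short_delay": int((short_delay & keep).sum()),
               "short_delay_excluded": exclude_short_delay})


def preprocess_session(fm: FluorescenceMatrix, trials: pd.DataFrame,
                       window_frames: int = 400, percentile: float = 8.0,
                       lick_window_s: float = 1.0) -> EpochResponse:
    """Full imaging preprocessing: drift correction → ΔF/F → epoch means."""
    corrected = correct_slow_drift(fm.f, window_frames, percentile)
    dff = compute_dff(corrected, fm.roi_labels)
    return epoch_average(dff, fm.events, trials, fm.frame_rate, lick_window_s)
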