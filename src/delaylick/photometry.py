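"""Dual-channel photometry correction and cell-type choice-coding metrics.

Motion correction exploits the calcium-insensitive 410-nm (isosbestic)
channel: both channels are slow-drift corrected (rolling 5th percentile
over 1000 frames, ~50 s at 20 Hz), the 410 trace is regressed onto the 470
trace and the fitted artifact component (mean-preserved) is subtracted from
the 470 signal.  ΔF/F then follows the imaging pipeline (mode-based F0,
per-trial pre-sound baseline subtraction).  Choice coding is summarized as
an AUC time course in 150-ms centered bins and as early (sound-period) and
late (1-1.5 s after delay onset) epoch AUCs, oriented contra = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import PhotometrySession
from .imaging import compute_dff, correct_slow_drift
from .selectivity import roc_auc
from .stats import TestResult, chi_squared_2x2, permutation_p
from .synth import SOUND_DURATION_S

__all__ = ["PhotometryResult", "motion_correct", "session_dff",
           "timecourse_auc", "early_late_auc", "early_late_consistency"]

SLOW_WINDOW_FRAMES = 1000
SLOW_PERCENTILE = 5.0
SMOOTH_FRAMES = 3
BIN_S = 0.15
LATE_EPOCH_S = (1.0, 1.5)   # after delay onset


@dataclass
class PhotometryResult:
    session_id: str
    cell_type: str
    early_auc: float
    late_auc: float
    consistent: bool | None = None
    tie: bool = False
    auc_timecourse: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def motion_correct(session: PhotometrySession) -> np.ndarray:
    """Remove the shared motion artifact from the 470 channel.

    Both channels are slow-corrected, then the 410 channel is linearly
    transformed (OLS) to fit the 470 channel and the fitted trace is
    subtracted; the subtraction is mean-preserving so the corrected trace
    keeps the positive baseline needed for ΔF/F.  A zero-variance 410
    channel skips the regression with a warning.
    """
    s470 = correct_slow_drift(session.f470, SLOW_WINDOW_FRAMES, SLOW_PERCENTILE)
    s410 = correct_slow_drift(session.f410, SLOW_WINDOW_FRAMES, SLOW_PERCENTILE)
    if np.std(s410) == 0:
        warnings.warn("zero-variance 410 channel; regression skipped")
        return s470
    slope, intercept = np.polyfit(s410, s470, 1)
    fitted = slope * s410 + intercept
    return s470 - (fitted - fitted.mean())


def session_dff(session: PhotometrySession) -> np.ndarray:
    """Motion-corrected ΔF/F trace for one photometry session."""
    corrected = motion_correct(session)
    return compute_dff(corrected)


def _trial_baseline_subtract(dff: np.ndarray, session: PhotometrySession,
                             aligned: np.ndarray, idx: np.ndarray) -> np.ndarray:
    fr = session.frame_rate
    for row, i in enumerate(idx):
        b0 = int(max(0, round((session.events.sound_onset[i] - 0.5) * fr)))
        b1 = int(round(session.events.sound_onset[i] * fr))
        if b1 > b0:
            aligned[row] -= dff[b0:b1].mean()
    return aligned


def timecourse_auc(session: PhotometrySession, trials: pd.DataFrame,
                   bin_s: float = BIN_S, align: str = "delay_onset",
                   window_s: tuple[float, float] = (-0.5, 3.0),
                   correct_only: bool = True) -> pd.DataFrame:
    """Choice AUC (contra vs ipsi) per 150-ms bin around an alignment event.

    Trial traces are smoothed with 3-frame overlapping bins, aligned to
    delay onset or to the first lick, baseline-subtracted (pre-sound mean),
    and the across-trial AUC is computed per bin.  In delay-onset alignment
    the samples after each trial's delay offset (go cue) are masked for
    that trial, so short-delay trials never contribute post-delay activity.
    """
    if align not in ("delay_onset", "first_lick"):
        raise ValueError("align must be 'delay_onset' or 'first_lick'")
    fr = session.frame_rate
    dff = session_dff(session)
    dff = np.convolve(dff, np.ones(SMOOTH_FRAMES) / SMOOTH_FRAMES, mode="same")

    contra = "right" if session.side == "left" else "left"
    ipsi = "left" if session.side == "left" else "right"
    keep = trials["choice"].isin([contra, ipsi]).to_numpy()
    if correct_only:
        keep &= (trials["outcome"] == "correct").to_numpy()
    idx = np.flatnonzero(keep)
    is_contra = (trials["choice"].to_numpy()[idx] == contra)
    if is_contra.sum() < 5 or (~is_contra).sum() < 5:
        warnings.warn("fewer than 5 trials per side; AUC will be noisy")

    ev = session.events
    d_on = ev.sound_onset + SOUND_DURATION_S
    anchor = d_on if align == "delay_onset" else ev.first_lick
    t0, t1 = window_s
    n_samp = int(round((t1 - t0) * fr))
    aligned = np.full((idx.size, n_samp), np.nan)
    for row, i in enumerate(idx):
        if np.isnan(anchor[i]):
            continue
        f0 = int(round((anchor[i] + t0) * fr))
        seg = dff[max(0, f0):f0 + n_samp]
        aligned[row, :seg.size] = seg
        if align == "delay_onset":
            # mask frames after this trial's delay offset (the go cue)
            cut = int(round((ev.go_cue[i] - (anchor[i] + t0)) * fr))
            if cut < n_samp:
                aligned[row, max(cut, 0):] = np.nan
    aligned = _trial_baseline_subtract(dff, session, aligned, idx)

    frames_per_bin = max(1, int(round(bin_s * fr)))
    n_bins = n_samp // frames_per_bin
    times = t0 + (np.arange(n_bins) + 0.5) * frames_per_bin / fr
    aucs = np.full(n_bins, np.nan)
    n_used = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(
                aligned[:, b * frames_per_bin:(b + 1) * frames_per_bin], axis=1)
        ok = ~np.isnan(vals)
        if (is_contra & ok).sum() >= 2 and (~is_contra & ok).sum() >= 2:
            aucs[b] = roc_auc(vals[is_contra & ok], vals[~is_contra & ok])
            n_used[b] = int(ok.sum())
    return pd.DataFrame({"time_s": times, "auc": aucs, "n_trials": n_used})


def early_late_auc(session: PhotometrySession, trials: pd.DataFrame,
                   session_id: str = "") -> PhotometryResult:
    """Early (sound period) and late (1-1.5 s after delay onset) choice AUC.

    Correct trials only; contra = 1 orientation.  Only trials whose delay
    covers at least the start of the late window contribute to the late
    AUC; if no trial reaches the late window the late AUC is NaN and the
    session is flagged.
    """
    fr = session.frame_rate
    dff = session_dff(session)
    ev = session.events
    d_on = ev.sound_onset + SOUND_DURATION_S

    contra = "right" if session.side == "left" else "left"
    keep = (trials["outcome"] == "correct").to_numpy()
    idx = np.flatnonzero(keep)
    is_contra = trials["choice"].to_numpy()[idx] == contra

    def _epoch_mean(i, t_start, t_stop):
        f0 = int(round(t_start * fr))
        f1 = int(round(t_stop * fr))
        if f1 <= f0:
            return np.nan
        b0 = int(max(0, round((ev.sound_onset[i] - 0.5) * fr)))
        b1 = int(round(ev.sound_onset[i] * fr))
        base = dff[b0:b1].mean() if b1 > b0 else 0.0
        return dff[f0:f1].mean() - base

    early = np.array([_epoch_mean(i, ev.sound_onset[i],
                                  ev.sound_onset[i] + SOUND_DURATION_S)
                      for i in idx])
    late = np.full(idx.size, np.nan)
    for row, i in enumerate(idx):
        l0 = d_on[i] + LATE_EPOCH_S[0]
        l1 = min(d_on[i] + LATE_EPOCH_S[1], ev.go_cue[i])
        if l1 > l0 + 1e-9:
            late[row] = _epoch_mean(i, l0, l1)

    notes = []
    ok_e = ~np.isnan(early)
    e_auc = (roc_auc(early[ok_e & is_contra], early[ok_e & ~is_contra])
             if (ok_e & is_contra).sum() and (ok_e & ~is_contra).sum()
             else np.nan)
    ok_l = ~np.isnan(late)
    if (ok_l & is_contra).sum() >= 2 and (ok_l & ~is_contra).sum() >= 2:
        l_auc = roc_auc(late[ok_l & is_contra], late[ok_l & ~is_contra])
    else:
        l_auc = np.nan
        notes.append("no trials with delay reaching the late epoch")
    return PhotometryResult(session_id=session_id, cell_type=session.cell_type,
                            early_auc=float(e_auc), late_auc=float(l_auc),
                            notes=notes)


def early_late_consistency(results: list[PhotometryResult],
                           n_shuffles: int = 5000,
                           seed: int | None = None) -> dict:
    """Consistency of early/late choice preference, compared by cell type.

    A session is "consistent" iff its early and late AUC lie on the same
    side of 0.5 (a value exactly at 0.5 is classified inconsistent and
    flagged as a tie).  Between the two cell types the consistent
    proportions are compared by an uncorrected 2x2 chi-squared test, and
    the spread of early AUC values by a two-sample variance F-test plus a
    permutation test on the absolute variance difference (the two readings
    of a between-type variance comparison; both are reported).
    """
    rows = []
    for r in results:
        if np.isnan(r.late_auc) or np.isnan(r.early_auc):
            continue
        tie = (r.early_auc == 0.5) or (r.late_auc == 0.5)
        consistent = ((r.early_auc - 0.5) * (r.late_auc - 0.5)) > 0
        if tie:
            warnings.warn(f"session {r.session_id}: AUC exactly 0.5, "
                          "classified inconsistent by tie rule")
        r.consistent, r.tie = bool(consistent), tie
        rows.append({"session_id": r.session_id, "cell_type": r.cell_type,
                     "early_auc": r.early_auc, "late_auc": r.late_auc,
                     "consistent": bool(consistent), "tie": tie})
    table = pd.DataFrame(rows)
    types = sorted(table["cell_type"].unique())
    out: dict = {"table": table}
    if len(types) != 2:
        return out
    a, b = (table[table["cell_type"] == t] for t in types)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 sessions per cell type")

    counts = np.array([
        [int(a["consistent"].sum()), int((~a["consistent"]).sum())],
        [int(b["consistent"].sum()), int((~b["consistent"]).sum())],
    ])
    out["consistency_chi2"] = chi_squared_2x2(counts)
    out["counts"] = counts

    va, vb = a["early_auc"].to_numpy(), b["early_auc"].to_numpy()
    f = np.var(va, ddof=1) / np.var(vb, ddof=1)
    dfa, dfb = len(va) - 1, len(vb) - 1
    p_f = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    out["variance_f_test"] = TestResult(
        statistic=float(f), p_value=float(min(1.0, p_f)),
        method="two-sample variance F-test (early AUC)",
        extra={"df": [dfa, dfb]})
    out["variance_permutation"] = permutation_p(
        va, vb,
        statistic=lambda x, y: np.var(x, ddof=1) - np.var(y, ddof=1),
        n=n_shuffles, seed=seed)
    return out
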