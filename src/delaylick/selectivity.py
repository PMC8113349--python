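"""Single-ROI ROC selectivity and permutation significance.

The selectivity statistic is the area under the ROC curve between the two
trial groups, computed rank-based with half credit for ties, so it equals
the Mann-Whitney U statistic divided by ``n_a * n_b`` and the pairwise
probability P(a > b) + 0.5 P(a = b).  Significance comes from a trial-label
permutation null (1000 shuffles, 99% CI by default); an ROI is "selective"
if its AUC falls outside the null CI in *any* behavioral epoch.  AUC is
oriented by the caller's label vector (by convention True = contralateral
choice, so 1 means contralateral preference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EpochResponse, VideoTracks
from .stats import TestResult, bootstrap_p

__all__ = ["roc_auc", "SelectivityResult", "permutation_significance",
           "epoch_distribution_compare", "movement_divergence_time",
           "shuffled_auc_bounds"]


def roc_auc(responses_a: np.ndarray, responses_b: np.ndarray) -> float:
    """AUC = P(a > b) + 0.5 P(a = b) via the rank-sum statistic."""
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[:a.size].sum()
    u = r_a - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _auc_from_ranks(ranks: np.ndarray, mask_a: np.ndarray) -> float:
    na = int(mask_a.sum())
    nb = ranks.size - na
    return float((ranks[mask_a].sum() - na * (na + 1) / 2.0) / (na * nb))


def shuffled_auc_bounds(responses: np.ndarray, labels: np.ndarray,
                        n_shuffles: int, ci: float,
                        rng: np.random.Generator) -> tuple[float, float, float, np.ndarray]:
    """Observed AUC plus permutation-null CI bounds and p-value.

    Shuffled AUCs are computed by permuting the label vector; because the
    response ranks do not change under label permutation, each shuffle is a
    single masked rank sum (vectorized over shuffles).
    """
    ranks = sps.rankdata(responses)
    auc = _auc_from_ranks(ranks, labels)
    na = int(labels.sum())
    perm = np.tile(labels, (n_shuffles, 1))
    perm = rng.permuted(perm, axis=1)
    sums = perm @ ranks
    nb = labels.size - na
    null = (sums - na * (na + 1) / 2.0) / (na * nb)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(null, [alpha, 100.0 - alpha])
    p = (np.sum(np.abs(null - 0.5) >= abs(auc - 0.5) - 1e-12) + 1) / (n_shuffles + 1)
    return auc, float(lo), float(hi), null


@dataclass
class SelectivityResult:
    """Per-ROI, per-epoch AUC with permutation-null bounds."""

    auc: np.ndarray          # rois x epochs
    null_lo: np.ndarray
    null_hi: np.ndarray
    p_value: np.ndarray      # two-sided permutation p per roi x epoch
    significant: np.ndarray  # rois x epochs bool (outside the null CI)
    selective: np.ndarray    # per ROI: significant in ANY epoch
    epochs: list[str]
    mode: str = "choice"
    skipped_rois: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.auc.shape[0]):
            for j, ep in enumerate(self.epochs):
                rows.append({"roi": r, "epoch": ep, "auc": self.auc[r, j],
                             "null_lo": self.null_lo[r, j],
                             "null_hi": self.null_hi[r, j],
                             "p_value": self.p_value[r, j],
                             "selective": bool(self.selective[r])})
        return pd.DataFrame(rows)


def permutation_significance(
    epoch_responses: EpochResponse | np.ndarray,
    labels: np.ndarray | None = None,
    n_shuffles: int = 1000,
    ci: float = 99.0,
    mode: str = "choice",
    seed: int | None = None,
    epochs: list[str] | None = None,
) -> SelectivityResult:
    """Label-permutation significance of per-ROI epoch AUC values.

    ``epoch_responses`` is either an :class:`EpochResponse` (labels derived
    from its trial table: choice == "right" for ``mode="choice"``,
    category == "high" for ``mode="sensory"``; correct and error trials are
    both included) or a raw (trials, rois, epochs) array with an explicit
    boolean ``labels`` vector.  Each ROI draws its own shuffle stream from
    a per-ROI seed spawned from ``seed`` so results are reproducible under
    parallel or per-ROI execution.  ROIs with fewer than 2 trials in either
    class are skipped.
    """
    if isinstance(epoch_responses, EpochResponse):
        resp = epoch_responses.dff
        epochs = epoch_responses.epochs
        t = epoch_responses.trials
        labels = ((t["choice"] == "right") if mode == "choice"
                  else (t["category"] == "high")).to_numpy()
    else:
        resp = np.asarray(epoch_responses, dtype=float)
        if labels is None:
            raise ValueError("labels required for a raw response array")
        labels = np.asarray(labels, dtype=bool)
    if resp.ndim == 2:
        resp = resp[:, :, None]
    n_trials, n_rois, n_epochs = resp.shape
    epochs = epochs or [f"epoch{j}" for j in range(n_epochs)]
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives a coarse null CI")

    roi_seeds = np.random.SeedSequence(seed).spawn(n_rois)
    auc = np.full((n_rois, n_epochs), np.nan)
    lo = np.full_like(auc, np.nan)
    hi = np.full_like(auc, np.nan)
    pv = np.full_like(auc, np.nan)
    skipped = []
    for r in range(n_rois):
        rng = np.random.default_rng(roi_seeds[r])
        for j in range(n_epochs):
            x = resp[:, r, j]
            ok = ~np.isnan(x)
            lab = labels[ok]
            if lab.sum() < 2 or (~lab).sum() < 2:
                if j == 0:
                    skipped.append(r)
                continue
            auc[r, j], lo[r, j], hi[r, j], null = shuffled_auc_bounds(
                x[ok], lab, n_shuffles, ci, rng)
            pv[r, j] = (np.sum(np.abs(null - 0.5) >= abs(auc[r, j] - 0.5)
                               - 1e-12) + 1) / (n_shuffles + 1)
    sig = (auc < lo) | (auc > hi)
    sig &= ~np.isnan(auc)
    selective = np.any(np.nan_to_num(sig), axis=1)
    return SelectivityResult(auc=auc, null_lo=lo, null_hi=hi, p_value=pv,
                             significant=sig, selective=selective,
                             epochs=list(epochs), mode=mode,
                             skipped_rois=skipped)


def epoch_distribution_compare(auc_by_epoch: np.ndarray,
                               epochs: list[str],
                               pairs: list[tuple[str, str]] | None = None,
                               n_shuffles: int = 5000,
                               seed: int | None = None) -> dict:
    """Compare AUC distributions between behavioral epochs.

    ``auc_by_epoch`` is (rois, epochs).  For each epoch pair a two-sided
    paired permutation test on the mean AUC difference is run (each ROI's
    pair of values is swapped with probability 1/2 per shuffle), and a
    Gaussian (mu, sigma) is fit to each epoch's AUC distribution for
    display.  Consecutive-epoch pairs are tested by default.
    """
    A = np.asarray(auc_by_epoch, dtype=float)
    if A.shape[1] != len(epochs) or len(epochs) < 2:
        raise ValueError("need a (rois, >=2 epochs) AUC matrix")
    if A.shape[0] < 10:
        warnings.warn("fewer than 10 ROIs: permutation p is low powered")
    pairs = pairs or list(zip(epochs[:-1], epochs[1:]))
    rng = np.random.default_rng(seed)

    gauss = {ep: tuple(map(float, sps.norm.fit(A[~np.isnan(A[:, j]), j])))
             for j, ep in enumerate(epochs)}
    results = {}
    for ea, eb in pairs:
        ja, jb = epochs.index(ea), epochs.index(eb)
        ok = ~np.isnan(A[:, ja]) & ~np.isnan(A[:, jb])
        d = A[ok, ja] - A[ok, jb]
        obs = float(np.mean(d))
        flips = rng.choice([-1.0, 1.0], size=(n_shuffles, d.size))
        null = (flips * d[None, :]).mean(axis=1)
        k = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
        results[(ea, eb)] = TestResult(
            statistic=obs, p_value=min(1.0, (k + 1) / (n_shuffles + 1)),
            method="paired permutation on mean AUC difference",
            n_resamples=n_shuffles, seed=seed,
            extra={"n_rois": int(d.size)})
    return {"tests": results, "gaussian_fits": gauss}


def movement_divergence_time(
    sessions: list[tuple[VideoTracks, pd.DataFrame]],
    item: str = "tongue",
    side: str = "left",
    bin_frames: int = 2,
    likelihood_min: float = 0.1,
    window_s: float = 2.5,
    n_shuffles: int = 1000,
    ci: float = 99.0,
    alpha: float = 0.01,
    n_boot: int = 5000,
    consecutive_bins: int = 2,
    seed: int | None = None,
) -> dict:
    """Earliest time at which tracked movement separates ipsi vs contra.

    Per session the item's coordinate is baseline-subtracted by its
    session-wide mean (Δpixel) with frames at tracking likelihood <=
    ``likelihood_min`` discarded, trials are aligned to delay onset, and a
    per-bin (``bin_frames`` video frames) ipsi-vs-contra AUC with a
    1000-shuffle null CI is computed.  Across sessions, the per-bin mean
    ipsi - contra Δpixel difference is bootstrap-tested against 0; the
    divergence time is the start of the earliest run of
    ``consecutive_bins`` bins with p < ``alpha`` (NaN if none) — requiring
    a sustained run guards against single-bin sign coincidences, which are
    common when few sessions enter the bootstrap.
    """
    if len(sessions) < 2:
        raise ValueError("need >=2 sessions for the across-session bootstrap")
    rng = np.random.default_rng(seed)
    contra = "right" if side == "left" else "left"

    per_session_diff = []
    per_session_auc = []
    n_bins = None
    for tracks, trials in sessions:
        x = np.asarray(tracks.x[item], dtype=float)
        lk = np.asarray(tracks.likelihood[item], dtype=float)
        good = lk > likelihood_min
        if not good.any():
            raise ValueError("no frames survive the likelihood filter")
        dpix = np.where(good, x - x[good].mean(), np.nan)
        fr = tracks.frame_rate
        ev = tracks.events
        d_on = ev.sound_onset + 0.5
        frames_per_trial = int(window_s * fr)
        n_bins = frames_per_trial // bin_frames

        ipsi = (trials["choice"] == side).to_numpy()
        con = (trials["choice"] == contra).to_numpy()
        use = ipsi | con
        mat = np.full((int(use.sum()), n_bins), np.nan)
        lab = []
        row = 0
        for i in np.flatnonzero(use):
            f0 = int(round(d_on[i] * fr))
            seg = dpix[f0:f0 + frames_per_trial]
            if seg.size < frames_per_trial:
                seg = np.pad(seg, (0, frames_per_trial - seg.size),
                             constant_values=np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mat[row] = np.nanmean(
                    seg[:n_bins * bin_frames].reshape(n_bins, bin_frames),
                    axis=1)
            lab.append(bool(ipsi[i]))
            row += 1
        lab = np.array(lab)

        auc_series = np.full(n_bins, np.nan)
        sig_series = np.zeros(n_bins, dtype=bool)
        for jb in range(n_bins):
            col = mat[:, jb]
            ok = ~np.isnan(col)
            lj = lab[ok]
            if lj.sum() < 2 or (~lj).sum() < 2:
                continue
            a, lo, hi, _ = shuffled_auc_bounds(col[ok], lj, n_shuffles, ci,
                                               rng)
            auc_series[jb] = a
            sig_series[jb] = (a < lo) or (a > hi)
        per_session_auc.append((auc_series, sig_series))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            diff = np.nanmean(mat[lab], axis=0) - np.nanmean(mat[~lab], axis=0)
        per_session_diff.append(diff)

    D = np.vstack(per_session_diff)  # sessions x bins
    p_bins = np.full(n_bins, np.nan)
    for jb in range(n_bins):
        col = D[:, jb]
        col = col[~np.isnan(col)]
        if col.size < 2:
            continue
        p_bins[jb] = bootstrap_p(col, n=n_boot,
                                 seed=int(rng.integers(2**31))).p_value
    sig = p_bins < alpha
    bin_s = bin_frames / sessions[0][0].frame_rate
    run = np.convolve(sig.astype(int), np.ones(consecutive_bins), "valid")
    first = np.flatnonzero(run >= consecutive_bins)
    return {
        "divergence_time_s": float(first[0] * bin_s) if first.size else np.nan,
        "bin_s": bin_s,
        "p_per_bin": p_bins,
        "mean_diff_per_bin": np.nanmean(D, axis=0),
        "per_session_auc": per_session_auc,
        "times_s": np.arange(n_bins) * bin_s,
    }
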