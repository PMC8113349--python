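"""Synthetic-data generators for every modality the pipeline consumes.

The generators emulate a head-fixed delayed-response licking experiment:
mice hear a click train whose rate (6 log-spaced values, 20-125 clicks/s)
cues a left or right lick, hold the choice over a uniform 0.3-1.5 s delay,
and respond after a go cue within a 3-s window.  Every generator draws from
``numpy.random.default_rng(seed)`` and is bit-reproducible for a fixed seed,
and stores its ground truth so downstream estimators can be validated.

Selectivity is injected on *event amplitudes*, upstream of the fluorescence
model, so the ΔF/F preprocessing is genuinely exercised: per-trial epoch
amplitudes are drawn from two equal-variance Gaussians whose separation is
chosen so the generating-distribution AUC equals the requested target,
``delta = sqrt(2) * sd * Phi^-1(AUC)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .containers import (
    CLICK_RATES,
    DELAY_RANGE_S,
    RESPONSE_WINDOW_S,
    EventTimes,
    FluorescenceMatrix,
    PhotometrySession,
    SliceSweepSet,
    VideoTracks,
    normalize_log_rate,
    validate_trials,
)

__all__ = [
    "gen_behavior",
    "gen_population",
    "gen_photometry",
    "gen_slice",
    "gen_video",
    "session_clock",
    "auc_separation",
    "EPOCHS",
]

#: Ordered behavioral epochs used across the imaging analyses.
EPOCHS = ["sound", "delay", "response", "lick"]

SOUND_DURATION_S = 0.5

DEFAULT_PSYCHOMETRIC = {"x0": 0.0, "b": 0.25, "y0": 0.05, "a": 0.90}
#: RT model: intercept - delay_slope * delay + N(0, noise_sd), in seconds.
#: With these defaults mean RT falls from ~0.57 s at the shortest delay to
#: ~0.45 s at the longest, the magnitude seen in trained mice.
DEFAULT_RT_MODEL = {"intercept": 0.60, "delay_slope": 0.10, "noise_sd": 0.12}
#: Violation hazard: logistic in delay, p = v_max * sigmoid((d - mid)/scale).
DEFAULT_VIOLATION = {"v_max": 0.30, "midpoint": 1.2, "scale": 0.35}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


def psychometric_curve(x: np.ndarray, x0: float, b: float, y0: float,
                       a: float) -> np.ndarray:
    """4-parameter sigmoid, P(lick right) = y0 + a / (1 + exp(-(x-x0)/b))."""
    return y0 + a * _sigmoid((np.asarray(x, dtype=float) - x0) / b)


def auc_separation(target_auc: float, sd: float) -> float:
    """Mean separation of two equal-variance Gaussians with a given AUC."""
    if not 0.0 <= target_auc <= 1.0:
        raise ValueError("AUC target must lie in [0, 1]")
    return float(np.sqrt(2.0) * sd * norm.ppf(target_auc))


def gen_behavior(
    n_trials: int = 500,
    psychometric: dict | None = None,
    delay_range: tuple[float, float] = DELAY_RANGE_S,
    violation_hazard: dict | None = None,
    miss_prob: float = 0.02,
    rt_model: dict | None = None,
    manipulation: str = "none",
    manip_frac: float = 0.3,
    manip_epochs: tuple[str, ...] = ("iti", "stimulus", "delay", "response"),
    manip_region: str = "none",
    hemisphere: str = "left",
    effects: dict | None = None,
    subject_id: str = "m01",
    session_id: str = "s01",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one behavioral session as a trial table.

    Choices follow the 4-parameter sigmoid of the normalized log click rate
    (the category boundary, 50 clicks/s, maps to 0).  Perturbation effects
    are applied on the logit scale: ``effects[(epoch, region)]`` may contain
    ``bias_shift`` (added to the choice logit; positive = more rightward)
    and ``slope_factor`` (multiplies the stimulus slope).  RT decreases
    linearly with delay plus Gaussian noise, truncated at 0 and at the 3-s
    response window (beyond which the trial becomes a miss); the violation
    hazard is logistic in delay.

    For ``manipulation`` in {"laser"} a random ``manip_frac`` of trials is
    perturbed with epochs drawn from ``manip_epochs``; for {"cno",
    "saline"} the label applies to the whole session (epoch "none").
    """
    psychometric = dict(DEFAULT_PSYCHOMETRIC, **(psychometric or {}))
    rt_model = dict(DEFAULT_RT_MODEL, **(rt_model or {}))
    violation_hazard = dict(DEFAULT_VIOLATION, **(violation_hazard or {}))
    if not (0.0 <= miss_prob <= 1.0 and 0.0 <= manip_frac <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if not (0 < delay_range[0] <= delay_range[1]):
        raise ValueError("delay_range must be positive and ordered")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    effects = effects or {}

    rng = np.random.default_rng(seed)
    rates = rng.choice(CLICK_RATES, size=n_trials)
    x = normalize_log_rate(rates)
    delay = rng.uniform(delay_range[0], delay_range[1], size=n_trials)

    # perturbation assignment
    epoch = np.array(["none"] * n_trials, dtype=object)
    region = np.array(["none"] * n_trials, dtype=object)
    manip = np.array(["none"] * n_trials, dtype=object)
    if manipulation == "laser":
        hit = rng.random(n_trials) < manip_frac
        epoch[hit] = rng.choice(manip_epochs, size=int(hit.sum()))
        region[hit] = manip_region
        manip[hit] = "laser"
    elif manipulation in ("cno", "saline"):
        manip[:] = manipulation
        region[:] = manip_region
    elif manipulation != "none":
        raise ValueError(f"unknown manipulation {manipulation!r}")

    x0, b, y0, a = (psychometric[k] for k in ("x0", "b", "y0", "a"))
    slope = np.full(n_trials, 1.0 / b)
    bias = np.zeros(n_trials)
    for i in range(n_trials):
        eff = effects.get((epoch[i], region[i]))
        if eff:
            slope[i] *= eff.get("slope_factor", 1.0)
            bias[i] += eff.get("bias_shift", 0.0)
    p_right = y0 + a * _sigmoid((x - x0) * slope + bias)

    choice_right = rng.random(n_trials) < p_right
    category = np.where(rates > 50.0, "high", "low")
    correct = (category == "high") == choice_right

    p_viol = violation_hazard["v_max"] * _sigmoid(
        (delay - violation_hazard["midpoint"]) / violation_hazard["scale"])
    violated = rng.random(n_trials) < p_viol
    missed = (~violated) & (rng.random(n_trials) < miss_prob)

    rt = (rt_model["intercept"] - rt_model["delay_slope"] * delay
          + rng.normal(0.0, rt_model["noise_sd"], size=n_trials))
    rt = np.clip(rt, 0.0, None)
    missed |= (~violated) & (rt > RESPONSE_WINDOW_S)

    outcome = np.where(violated, "violation",
                       np.where(missed, "miss",
                                np.where(correct, "correct", "error")))
    choice = np.where(outcome == "violation", "none",
                      np.where(outcome == "miss", "none",
                               np.where(choice_right, "right", "left")))
    rt = np.where(np.isin(outcome, ["correct", "error"]), rt, np.nan)

    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "subject_id": subject_id,
        "session_id": session_id,
        "click_rate": rates,
        "log_rate_norm": x,
        "category": category,
        "delay": delay,
        "choice": choice,
        "outcome": outcome,
        "rt": rt,
        "manipulation": manip,
        "manip_epoch": epoch,
        "manip_region": region,
        "hemisphere": hemisphere,
    })
    return validate_trials(trials)


def session_clock(trials: pd.DataFrame, seed: int | None = None) -> EventTimes:
    """Lay trials out on a continuous session clock.

    Sound onsets are spaced by the trial duration plus a uniform 2.5-3.5 s
    inter-trial interval; the go cue follows sound offset by the trial's
    delay; the first lick follows the go cue by the trial's RT (NaN for
    violation and miss trials).
    """
    rng = np.random.default_rng(seed)
    n = len(trials)
    delay = trials["delay"].to_numpy(float)
    rt = trials["rt"].to_numpy(float)
    scored = np.isin(trials["outcome"].to_numpy(), ["correct", "error"])
    resp = np.where(scored, rt, 1.0)
    iti = rng.uniform(2.5, 3.5, size=n)
    dur = SOUND_DURATION_S + delay + resp + iti
    sound = np.concatenate([[2.0], 2.0 + np.cumsum(dur[:-1])])
    go = sound + SOUND_DURATION_S + delay
    lick = np.where(scored, go + rt, np.nan)
    return EventTimes(sound, go, lick)


def _double_exp_kernel(frame_rate: float, tau_rise: float, tau_decay: float,
                       length_s: float = 8.0) -> np.ndarray:
    """Double-exponential indicator kernel, normalized to unit sum so a
    sustained unit drive converges to a unit plateau."""
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("kernel time constants must be positive")
    t = np.arange(0.0, length_s, 1.0 / frame_rate)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    s = k.sum()
    return k / s if s > 0 else k


def _epoch_drive_windows(ev: EventTimes, lick_window_s: float = 1.0
                         ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    # each epoch drives activity over its own analysis window, so the
    # injected amplitude dominates the epoch-averaged response
    return {
        "sound": (ev.sound_onset, ev.sound_onset + SOUND_DURATION_S),
        "delay": (ev.go_cue - 0.5, ev.go_cue),
        "response": (ev.go_cue, ev.first_lick),
        "lick": (ev.first_lick, ev.first_lick + lick_window_s),
    }


def _epoch_amplitudes(rng, labels_pos: np.ndarray, target_auc: float,
                      base: float, sd: float) -> np.ndarray:
    """Per-trial amplitudes from two Gaussians realizing a target AUC."""
    delta = auc_separation(target_auc, sd)
    mu = base + np.where(labels_pos, +0.5 * delta, -0.5 * delta)
    return np.clip(rng.normal(mu, sd), 0.0, None)


def gen_population(
    trials: pd.DataFrame,
    n_rois: int = 40,
    frame_rate: float = 30.0,
    kernel: dict | None = None,
    epoch_auc_targets: dict | np.ndarray | float = 0.5,
    amp_base: float | dict = 1.0,
    amp_sd: float = 0.3,
    noise_sd: float = 2.0,
    drift_amp: float = 0.05,
    baseline: float = 100.0,
    gain: float = 30.0,
    seed: int | None = None,
) -> FluorescenceMatrix:
    """Simulate an imaging session (frames x ROIs raw fluorescence).

    Each ROI is driven, within each behavioral epoch's analysis window, at
    a per-trial amplitude that differs between left and right choices so
    that the AUC of the generating amplitude distributions equals the
    requested target (oriented as right-vs-left: target > 0.5 means larger
    responses on right-choice trials).  ``epoch_auc_targets`` may be a scalar, a dict
    ``epoch -> scalar or per-ROI array``, or an (n_rois, 4) array ordered as
    :data:`EPOCHS`.  Amplitude trains are convolved with a double-exponential
    indicator kernel and placed on a multiplicative slow drift plus additive
    Gaussian noise around a positive baseline.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    kernel = dict({"tau_rise": 0.2, "tau_decay": 1.5}, **(kernel or {}))
    rng = np.random.default_rng(seed)

    targets = np.full((n_rois, len(EPOCHS)), 0.5)
    if np.isscalar(epoch_auc_targets):
        targets[:] = float(epoch_auc_targets)
    elif isinstance(epoch_auc_targets, dict):
        for ep, val in epoch_auc_targets.items():
            targets[:, EPOCHS.index(ep)] = val
    else:
        targets = np.broadcast_to(
            np.asarray(epoch_auc_targets, float), targets.shape).copy()
    if np.any(targets < 0) or np.any(targets > 1):
        raise ValueError("AUC targets must lie in [0, 1]")

    ev = session_clock(trials, seed=rng.integers(2**31))
    windows = _epoch_drive_windows(ev)
    scored = np.isin(trials["outcome"].to_numpy(), ["correct", "error"])
    is_right = (trials["choice"].to_numpy() == "right")

    t_end = np.nanmax([ev.go_cue.max() + 4.0,
                       np.nanmax(ev.first_lick) + 4.0])
    n_frames = int(np.ceil(t_end * frame_rate))
    k = _double_exp_kernel(frame_rate, **kernel)

    drive = np.zeros((n_frames, n_rois))
    truth_amps = {}
    for j, ep in enumerate(EPOCHS):
        t_on, t_off = windows[ep]
        use = scored if ep in ("response", "lick") else np.ones(len(trials), bool)
        use = use & ~np.isnan(t_on) & ~np.isnan(t_off)
        idx = np.flatnonzero(use)
        base_j = amp_base[ep] if isinstance(amp_base, dict) else amp_base
        amps = np.empty((idx.size, n_rois))
        for r in range(n_rois):
            amps[:, r] = _epoch_amplitudes(
                rng, is_right[idx], targets[r, j], base_j, amp_sd)
        if base_j == 0 and targets[:, j].max() == 0.5 == targets[:, j].min():
            amps[:] = 0.0
        for row, i in enumerate(idx):
            f0 = max(0, int(round(t_on[i] * frame_rate)))
            f1 = min(n_frames, int(round(t_off[i] * frame_rate)))
            if f1 > f0:
                drive[f0:f1] += amps[row]
        truth_amps[ep] = amps

    sig = np.empty_like(drive)
    for r in range(n_rois):
        sig[:, r] = np.convolve(drive[:, r], k)[:n_frames]

    tt = np.arange(n_frames) / frame_rate
    drift = np.ones((n_frames, n_rois))
    if drift_amp > 0:
        period = rng.uniform(80.0, 160.0, size=n_rois)
        phase = rng.uniform(0, 2 * np.pi, size=n_rois)
        drift += drift_amp * np.sin(
            2 * np.pi * tt[:, None] / period[None, :] + phase[None, :])
    f = baseline * drift + gain * sig + rng.normal(0, noise_sd, sig.shape)
    f = np.clip(f, 1e-3, None)

    return FluorescenceMatrix(
        f=f, frame_rate=frame_rate, events=ev,
        ground_truth={"epoch_auc_targets": targets, "epochs": list(EPOCHS),
                      "amplitudes": truth_amps},
    )


def gen_photometry(
    trials: pd.DataFrame,
    early_auc: float = 0.7,
    late_auc: float = 0.7,
    artifact: dict | None = None,
    drift_amp: float = 1.0,
    noise_sd: float = 0.5,
    frame_rate: float = 20.0,
    side: str = "left",
    cell_type: str = "excitatory",
    amp_base: float = 3.0,
    amp_sd: float = 1.0,
    seed: int | None = None,
) -> PhotometrySession:
    """Simulate a dual-channel photometry session.

    The 470-nm channel carries a choice signal: a boxcar over the sound
    window whose per-trial amplitude realizes ``early_auc``, and a boxcar
    over 1-1.5 s after delay onset (clipped at the go cue) realizing
    ``late_auc`` — both oriented contra-vs-ipsi relative to ``side``.  A
    shared low-pass motion artifact is injected into both channels with
    different gains; the isosbestic 410-nm channel carries artifact, drift
    and noise but no signal.  The artifact trace is kept as ground truth.
    """
    artifact = dict({"amplitude": 3.0, "timescale": 1.0}, **(artifact or {}))
    rng = np.random.default_rng(seed)
    ev = session_clock(trials, seed=rng.integers(2**31))
    t_end = ev.go_cue.max() + 5.0
    n_frames = int(np.ceil(t_end * frame_rate))
    tt = np.arange(n_frames) / frame_rate

    contra = "right" if side == "left" else "left"
    is_contra = trials["choice"].to_numpy() == contra
    scored = np.isin(trials["outcome"].to_numpy(), ["correct", "error"])

    amp_early = _epoch_amplitudes(rng, is_contra, early_auc, amp_base, amp_sd)
    amp_late = _epoch_amplitudes(rng, is_contra, late_auc, amp_base, amp_sd)

    signal = np.zeros(n_frames)
    d_on = ev.sound_onset + SOUND_DURATION_S
    for i in range(len(trials)):
        if not scored[i]:
            continue
        s0, s1 = ev.sound_onset[i], ev.sound_onset[i] + SOUND_DURATION_S
        signal[int(s0 * frame_rate):int(s1 * frame_rate)] += amp_early[i]
        l0 = d_on[i] + 1.0
        l1 = min(d_on[i] + 1.5, ev.go_cue[i])
        if l1 > l0:
            signal[int(l0 * frame_rate):int(l1 * frame_rate)] += amp_late[i]
    # mild causal smoothing so window edges are not perfectly sharp
    smooth = np.exp(-np.arange(0, 0.6, 1 / frame_rate) / 0.15)
    signal = np.convolve(signal, smooth / smooth.sum())[:n_frames]

    if artifact["amplitude"] > 0:
        raw = rng.normal(0, 1, n_frames)
        w = int(max(1, artifact["timescale"] * frame_rate))
        art = np.convolve(raw, np.ones(w) / np.sqrt(w), mode="same")
        art *= artifact["amplitude"]
    else:
        art = np.zeros(n_frames)

    drift = drift_amp * np.sin(2 * np.pi * tt / 120.0 + rng.uniform(0, 2 * np.pi))
    f470 = 100.0 + signal + 1.0 * art + drift + rng.normal(0, noise_sd, n_frames)
    f410 = 100.0 + 0.8 * art + drift + rng.normal(0, noise_sd, n_frames)

    return PhotometrySession(
        f470=np.clip(f470, 1e-3, None), f410=np.clip(f410, 1e-3, None),
        frame_rate=frame_rate, events=ev, side=side, cell_type=cell_type,
        ground_truth={"artifact": art, "early_auc": early_auc,
                      "late_auc": late_auc},
    )


def _epsp_kernel(sample_rate: float, tau_rise_ms: float = 2.0,
                 tau_decay_ms: float = 25.0) -> np.ndarray:
    t = np.arange(0.0, 0.15, 1.0 / sample_rate)
    k = (np.exp(-t / (tau_decay_ms / 1e3))
         - np.exp(-t / (tau_rise_ms / 1e3)))
    return k / k.max()


def gen_slice(
    n_cells: int = 10,
    responsive_frac: float = 0.7,
    latency_ms: float = 5.0,
    jitter_ms: float = 0.0,
    amplitude_mv: float = 5.0,
    reliability: float = 0.9,
    noise_sd: float = 0.4,
    sample_rate: float = 10_000.0,
    n_train_sweeps: int = 5,
    n_single_sweeps: int = 20,
    cell_type: str = "excitatory",
    seed: int | None = None,
) -> list[dict]:
    """Simulate whole-cell recordings around optogenetic stimulation.

    Each cell gets a 10-pulse 10-Hz train protocol and a single-pulse
    protocol, each with >=1 s of pre-stimulation baseline.  Responsive cells
    (a ``responsive_frac`` Bernoulli draw) emit an EPSP-shaped depolarization
    after each pulse with probability ``reliability``; non-responsive cells
    emit noise only.  Returns one dict per cell with keys ``train``,
    ``single`` (both :class:`SliceSweepSet`) and ``ground_truth``.
    """
    if not (0 <= responsive_frac <= 1 and 0 <= reliability <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kern = _epsp_kernel(sample_rate)

    train_times = 1.0 + 0.1 * np.arange(10)
    single_times = np.array([1.0])
    n_train = int(2.2 * sample_rate)
    n_single = int(1.15 * sample_rate)

    def _membrane_noise(n_sweeps, n_samp, tau_ms=5.0):
        # white noise filtered by a membrane-like exponential so baseline
        # fluctuations are temporally correlated as in real Vm recordings
        w = rng.normal(0.0, 1.0, size=(n_sweeps, n_samp))
        k = np.exp(-np.arange(0, 5 * tau_ms / 1e3, 1 / sample_rate)
                   / (tau_ms / 1e3))
        k /= np.sqrt((k ** 2).sum())
        out = np.empty_like(w)
        for s in range(n_sweeps):
            out[s] = np.convolve(w[s], k)[:n_samp]
        return noise_sd * out

    def _sweeps(n_sweeps, n_samp, stim_times, responsive):
        vm = -65.0 + _membrane_noise(n_sweeps, n_samp)
        if responsive:
            for s in range(n_sweeps):
                for t0 in stim_times:
                    if rng.random() >= reliability:
                        continue
                    lat = (latency_ms + rng.normal(0, jitter_ms)
                           if jitter_ms > 0 else latency_ms)
                    i0 = int(round((t0 + lat / 1e3) * sample_rate))
                    seg = min(len(kern), n_samp - i0)
                    if seg > 0:
                        vm[s, i0:i0 + seg] += amplitude_mv * kern[:seg]
        return vm

    cells = []
    for c in range(n_cells):
        responsive = bool(rng.random() < responsive_frac)
        train = SliceSweepSet(
            vm=_sweeps(n_train_sweeps, n_train, train_times, responsive),
            sample_rate=sample_rate, stim_times=train_times,
            stim_mode="train10", cell_type=cell_type)
        single = SliceSweepSet(
            vm=_sweeps(n_single_sweeps, n_single, single_times, responsive),
            sample_rate=sample_rate, stim_times=single_times,
            stim_mode="single", cell_type=cell_type)
        cells.append({
            "train": train, "single": single,
            "ground_truth": {"responsive": responsive,
                             "latency_ms": latency_ms,
                             "amplitude_mv": amplitude_mv,
                             "reliability": reliability},
        })
    return cells


def gen_video(
    trials: pd.DataFrame,
    divergence_onset_s: float = 1.0,
    divergence_px: float = 8.0,
    likelihood_dropout_rate: float = 0.0,
    noise_px: float = 1.5,
    frame_rate: float = 24.0,
    side: str = "left",
    seed: int | None = None,
) -> VideoTracks:
    """Simulate keypoint tracks (tongue, nose) for one session.

    The tongue x-coordinate separates between ipsi- and contralateral
    trials (relative to ``side``) only from ``divergence_onset_s`` after
    delay onset until the end of the response, ramping in over 0.2 s; the
    nose never diverges.  A ``likelihood_dropout_rate`` fraction of frames
    gets tracking likelihood below 0.1 and should be filtered downstream.
    """
    if not 0 <= likelihood_dropout_rate <= 1:
        raise ValueError("dropout rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ev = session_clock(trials, seed=rng.integers(2**31))
    t_end = np.nanmax([ev.go_cue.max() + 4.0, np.nanmax(ev.first_lick) + 4.0])
    n_frames = int(np.ceil(t_end * frame_rate))
    tt = np.arange(n_frames) / frame_rate

    ipsi = trials["choice"].to_numpy() == side
    contra = trials["choice"].to_numpy() == ("right" if side == "left" else "left")
    d_on = ev.sound_onset + SOUND_DURATION_S
    resp_end = np.where(np.isnan(ev.first_lick), ev.go_cue + 1.0,
                        ev.first_lick + 1.0)

    tongue = rng.normal(0.0, noise_px, n_frames) + 160.0
    for i in range(len(trials)):
        if not (ipsi[i] or contra[i]):
            continue
        t0 = d_on[i] + divergence_onset_s
        t1 = resp_end[i]
        if t1 <= t0:
            continue
        m = (tt >= t0) & (tt < t1)
        ramp = np.clip((tt[m] - t0) / 0.2, 0.0, 1.0)
        tongue[m] += (divergence_px if ipsi[i] else -divergence_px) * ramp
    nose = rng.normal(0.0, noise_px, n_frames) + 200.0

    def _likelihood():
        lk = rng.uniform(0.85, 1.0, n_frames)
        drop = rng.random(n_frames) < likelihood_dropout_rate
        lk[drop] = rng.uniform(0.0, 0.1, int(drop.sum()))
        return lk

    return VideoTracks(
        x={"tongue": tongue, "nose": nose},
        y={"tongue": rng.normal(120.0, noise_px, n_frames),
           "nose": rng.normal(80.0, noise_px, n_frames)},
        likelihood={"tongue": _likelihood(), "nose": _likelihood()},
        frame_rate=frame_rate, events=ev,
        ground_truth={"divergence_onset_s": divergence_onset_s, "side": side},
    )
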