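"""Domain containers shared across the pipeline, plus CSV/HDF5 round-trips.

The trial table is a plain :class:`pandas.DataFrame` with a fixed column
contract (see :data:`TRIAL_COLUMNS`); trace-like modalities are lightweight
dataclasses wrapping numpy arrays.  Synthetic generators attach a
``ground_truth`` dict so downstream estimates can be checked against what was
injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: Column contract for the per-trial behavioral table.
TRIAL_COLUMNS = [
    "trial_id", "subject_id", "session_id", "click_rate", "log_rate_norm",
    "category", "delay", "choice", "outcome", "rt", "manipulation",
    "manip_epoch", "manip_region", "hemisphere",
]

CATEGORIES = ("low", "high")
CHOICES = ("left", "right", "none")
OUTCOMES = ("correct", "error", "violation", "miss")

#: Stimulus set: 6 log-spaced click rates, 20-125 clicks/s, category
#: boundary at 50 clicks/s (low rates rewarded left, high rates right).
CLICK_RATES = np.geomspace(20.0, 125.0, 6)
CATEGORY_BOUNDARY_HZ = 50.0
RESPONSE_WINDOW_S = 3.0
DELAY_RANGE_S = (0.3, 1.5)


def normalize_log_rate(click_rate: np.ndarray | float,
                       rates: np.ndarray = CLICK_RATES) -> np.ndarray | float:
    """Map log(click rate) affinely onto [-1, 1] over the stimulus set."""
    lo, hi = np.log(rates.min()), np.log(rates.max())
    return (2.0 * (np.log(click_rate) - lo) / (hi - lo)) - 1.0


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract; returns the table unchanged.

    Raises ``ValueError`` on a missing column or violated invariant
    (delay range, RT defined exactly for scored trials, violations have no
    choice, category consistent with click rate).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    d = trials["delay"].to_numpy(dtype=float)
    if np.any(d < DELAY_RANGE_S[0] - 1e-9) or np.any(d > DELAY_RANGE_S[1] + 1e-9):
        raise ValueError("delay outside [0.3, 1.5] s")
    scored = trials["outcome"].isin(["correct", "error"])
    rt = trials["rt"].to_numpy(dtype=float)
    if np.any(np.isnan(rt[scored.to_numpy()])):
        raise ValueError("scored trials must have an RT")
    if np.any(~np.isnan(rt[~scored.to_numpy()])):
        raise ValueError("violation/miss trials must have NaN RT")
    if (trials.loc[trials["outcome"] == "violation", "choice"] != "none").any():
        raise ValueError("violation trials must have choice == 'none'")
    want_high = trials["click_rate"] > CATEGORY_BOUNDARY_HZ
    if (want_high != (trials["category"] == "high")).any():
        raise ValueError("category inconsistent with click_rate")
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV and validate the contract."""
    t = pd.read_csv(path, na_values=["", "NA"])
    return validate_trials(t)


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials).to_csv(path, index=False)


@dataclass
class EventTimes:
    """Per-trial event times on the session clock (seconds)."""

    sound_onset: np.ndarray
    go_cue: np.ndarray
    first_lick: np.ndarray  # NaN for violation/miss trials

    def __post_init__(self) -> None:
        n = len(self.sound_onset)
        if len(self.go_cue) != n or len(self.first_lick) != n:
            raise ValueError("event arrays must share length")
        ok = self.go_cue > self.sound_onset
        lick = ~np.isnan(self.first_lick)
        ok &= np.where(lick, self.first_lick >= self.go_cue, True)
        if not np.all(ok):
            raise ValueError("event times must be monotone within trial")

    @property
    def n_trials(self) -> int:
        return len(self.sound_onset)


@dataclass
class FluorescenceMatrix:
    """Raw fluorescence, frames x ROIs, with the trial event clock."""

    f: np.ndarray
    frame_rate: float
    events: EventTimes
    roi_labels: list[str] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.any(self.f <= 0):
            raise ValueError("fluorescence must be strictly positive")
        if not self.roi_labels:
            self.roi_labels = [f"roi{i:03d}" for i in range(self.f.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.f.shape[0]

    @property
    def n_rois(self) -> int:
        return self.f.shape[1]


@dataclass
class PhotometrySession:
    """Dual-channel fiber photometry session (470 signal, 410 isosbestic)."""

    f470: np.ndarray
    f410: np.ndarray
    frame_rate: float
    events: EventTimes
    side: str = "left"
    cell_type: str = "excitatory"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f470 = np.asarray(self.f470, dtype=float)
        self.f410 = np.asarray(self.f410, dtype=float)
        if self.f470.shape != self.f410.shape:
            raise ValueError("channels must have equal length")
        if np.any(self.f470 <= 0) or np.any(self.f410 <= 0):
            raise ValueError("traces must be strictly positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class SliceSweepSet:
    """Current-clamp sweeps around optogenetic stimulation for one cell."""

    vm: np.ndarray              # sweeps x samples, mV
    sample_rate: float          # Hz
    stim_times: np.ndarray      # pulse onsets (s from sweep start), shared
    stim_mode: str              # "single" or "train10"
    cell_type: str = "excitatory"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vm = np.atleast_2d(np.asarray(self.vm, dtype=float))
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        dur = self.vm.shape[1] / self.sample_rate
        if np.any(self.stim_times < 0) or np.any(self.stim_times >= dur):
            raise ValueError("stim_times must fall inside the sweep")
        if self.stim_times.min() < 1.0 - 1e-9:
            raise ValueError("need >=1 s pre-stimulation baseline")
        if self.stim_mode not in ("single", "train10"):
            raise ValueError("stim_mode must be 'single' or 'train10'")


@dataclass
class VideoTracks:
    """Keypoint tracks from a 24-Hz behavior camera.

    ``x``/``y``/``likelihood`` are dicts item -> per-frame array; items are
    e.g. tongue, nose, paws, lick ports.
    """

    x: dict[str, np.ndarray]
    y: dict[str, np.ndarray]
    likelihood: dict[str, np.ndarray]
    frame_rate: float = 24.0
    events: EventTimes | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, lk in self.likelihood.items():
            lk = np.asarray(lk, dtype=float)
            if np.any(lk < 0) or np.any(lk > 1):
                raise ValueError(f"likelihood for {item!r} outside [0, 1]")


@dataclass
class EpochResponse:
    """Trial- and epoch-averaged ΔF/F with joined trial metadata.

    ``dff`` has shape (trials, ROIs, epochs); ``epochs`` is the ordered
    epoch name list; ``trials`` carries the matching rows of the behavioral
    table (scored trials only, in the same order as axis 0).
    """

    dff: np.ndarray
    epochs: list[str]
    trials: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dff.shape[0] != len(self.trials):
            raise ValueError("trial metadata does not match response matrix")
        if self.dff.shape[2] != len(self.epochs):
            raise ValueError("epoch axis does not match epoch names")


def _write_events(g: h5py.Group, ev: EventTimes) -> None:
    g.create_dataset("sound_onset", data=ev.sound_onset)
    g.create_dataset("go_cue", data=ev.go_cue)
    g.create_dataset("first_lick", data=ev.first_lick)


def _read_events(g: h5py.Group) -> EventTimes:
    return EventTimes(g["sound_onset"][:], g["go_cue"][:], g["first_lick"][:])


def write_fluorescence(fm: FluorescenceMatrix, path) -> None:
    """Write an imaging session to HDF5 (datasets /f, /events/*)."""
    with h5py.File(path, "w") as h:
        h.create_dataset("f", data=fm.f)
        h.attrs["frame_rate"] = fm.frame_rate
        h.attrs["roi_labels"] = np.array(fm.roi_labels, dtype="S")
        _write_events(h.create_group("events"), fm.events)


def read_fluorescence(path) -> FluorescenceMatrix:
    with h5py.File(path, "r") as h:
        return FluorescenceMatrix(
            f=h["f"][:],
            frame_rate=float(h.attrs["frame_rate"]),
            events=_read_events(h["events"]),
            roi_labels=[s.decode() if isinstance(s, bytes) else str(s)
                        for s in h.attrs["roi_labels"]],
        )


def write_photometry(ps: PhotometrySession, path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("f470", data=ps.f470)
        h.create_dataset("f410", data=ps.f410)
        h.attrs["frame_rate"] = ps.frame_rate
        h.attrs["side"] = ps.side
        h.attrs["cell_type"] = ps.cell_type
        _write_events(h.create_group("events"), ps.events)


def read_photometry(path) -> PhotometrySession:
    with h5py.File(path, "r") as h:
        return PhotometrySession(
            f470=h["f470"][:], f410=h["f410"][:],
            frame_rate=float(h.attrs["frame_rate"]),
            events=_read_events(h["events"]),
            side=str(h.attrs["side"]), cell_type=str(h.attrs["cell_type"]),
        )


def write_sweeps(ss: SliceSweepSet, path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("vm", data=ss.vm)
        h.create_dataset("stim_times", data=ss.stim_times)
        h.attrs["sample_rate"] = ss.sample_rate
        h.attrs["stim_mode"] = ss.stim_mode
        h.attrs["cell_type"] = ss.cell_type


def read_sweeps(path) -> SliceSweepSet:
    with h5py.File(path, "r") as h:
        return SliceSweepSet(
            vm=h["vm"][:], sample_rate=float(h.attrs["sample_rate"]),
            stim_times=h["stim_times"][:], stim_mode=str(h.attrs["stim_mode"]),
            cell_type=str(h.attrs["cell_type"]),
        )
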