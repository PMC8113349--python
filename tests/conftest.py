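import numpy as np
import pandas as pd
import pytest

from delaylick import synth
from delaylick.containers import EpochResponse


@pytest.fixture(scope="session")
def trials_small():
    """One deterministic 300-trial behavioral session."""
    return synth.gen_behavior(n_trials=300, seed=1234)


@pytest.fixture(scope="session")
def trials_large():
    """A 10,000-trial session for distributional checks."""
    return synth.gen_behavior(n_trials=10_000, seed=99)


def make_epoch_response(n_trials=120, n_rois=12, auc_by_epoch=(0.5,) * 4,
                        seed=0, subject="m0", session="s0"):
    """Epoch-response container with responses drawn directly from two
    Gaussians per epoch whose separation realizes the requested AUC
    (bypasses the fluorescence model; used where only the statistics of the
    epoch responses matter)."""
    rng = np.random.default_rng(seed)
    choice = np.where(rng.random(n_trials) < 0.5, "right", "left")
    is_right = choice == "right"
    dff = np.empty((n_trials, n_rois, len(auc_by_epoch)))
    for j, auc in enumerate(auc_by_epoch):
        delta = synth.auc_separation(auc, 1.0)
        mu = np.where(is_right, 0.5 * delta, -0.5 * delta)
        dff[:, :, j] = rng.normal(mu[:, None], 1.0, size=(n_trials, n_rois))
    delay = rng.uniform(0.3, 1.5, n_trials)
    rt = np.clip(0.6 - 0.1 * delay + rng.normal(0, 0.12, n_trials), 0.01, 2.4)
    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "subject_id": subject, "session_id": session,
        "click_rate": rng.choice([20.0, 125.0], n_trials),
        "log_rate_norm": 0.0, "category": "low", "delay": delay,
        "choice": choice, "outcome": "correct", "rt": rt,
        "manipulation": "none", "manip_epoch": "none",
        "manip_region": "none", "hemisphere": "left",
    })
    trials["category"] = np.where(trials["click_rate"] > 50, "high", "low")
    return EpochResponse(dff=dff, epochs=list(synth.EPOCHS), trials=trials)
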