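"""Generators: determinism, contract invariants, and known ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from delaylick import synth
from delaylick.containers import validate_trials
from delaylick.synth import psychometric_curve


class TestGenBehavior:
    def test_deterministic_for_fixed_seed(self):
        a = synth.gen_behavior(n_trials=200, seed=42)
        b = synth.gen_behavior(n_trials=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_contract_invariants_hold(self, trials_large):
        validate_trials(trials_large)  # raises on violation
        t = trials_large
        assert set(t["click_rate"].unique()) <= set(synth.CLICK_RATES)
        scored = t["outcome"].isin(["correct", "error"])
        assert t.loc[scored, "rt"].notna().all()
        assert t.loc[~scored, "rt"].isna().all()

    def test_step_function_limit(self):
        # nearly-vertical sigmoid without lapses: extreme rates are fully
        # determined
        t = synth.gen_behavior(
            n_trials=3000, psychometric={"x0": 0.0, "b": 1e-4, "y0": 0.0,
                                         "a": 1.0},
            miss_prob=0.0, violation_hazard={"v_max": 0.0}, seed=5)
        hi = t[t["click_rate"] > 124]
        lo = t[t["click_rate"] < 21]
        assert (hi["choice"] == "right").all()
        assert (lo["choice"] == "left").all()

    def test_choice_frequencies_match_sigmoid(self, trials_large):
        params = synth.DEFAULT_PSYCHOMETRIC
        scored = trials_large[trials_large["choice"].isin(["left", "right"])]
        for x, g in scored.groupby("log_rate_norm"):
            p_true = float(psychometric_curve(np.array([x]), **params)[0])
            n = len(g)
            p_emp = (g["choice"] == "right").mean()
            sd = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(p_emp - p_true) < 3 * sd + 1e-12

    def test_rt_decreases_with_delay(self, trials_large):
        t = trials_large[trials_large["outcome"] == "correct"]
        short = t[t["delay"] < 0.6]["rt"].mean()
        long = t[t["delay"] > 1.2]["rt"].mean()
        assert long < short

    def test_violation_hazard_increases_with_delay(self, trials_large):
        t = trials_large
        v_short = (t[t["delay"] < 0.6]["outcome"] == "violation").mean()
        v_long = (t[t["delay"] > 1.2]["outcome"] == "violation").mean()
        assert v_long > v_short

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_behavior(miss_prob=1.5)
        with pytest.raises(ValueError):
            synth.gen_behavior(n_trials=0)
        with pytest.raises(ValueError):
            synth.gen_behavior(delay_range=(0.0, 1.0))

    def test_logit_bias_shifts_choices(self):
        eff = {("delay", "m2"): {"bias_shift": 3.0}}
        t = synth.gen_behavior(n_trials=4000, manipulation="laser",
                               manip_region="m2", effects=eff, seed=6)
        scored = t[t["choice"].isin(["left", "right"])]
        p_manip = (scored[scored["manip_epoch"] == "delay"]["choice"]
                   == "right").mean()
        p_ctrl = (scored[scored["manipulation"] == "none"]["choice"]
                  == "right").mean()
        assert p_manip > p_ctrl + 0.1


class TestGenPopulation:
    def test_equal_targets_give_identical_distributions(self):
        trials = synth.gen_behavior(n_trials=100, seed=0)
        fm = synth.gen_population(trials, n_rois=3, epoch_auc_targets=0.5,
                                  seed=1)
        amps = fm.ground_truth["amplitudes"]["delay"]
        is_right = trials["choice"].to_numpy() == "right"
        # generating separation is exactly zero at target 0.5
        assert synth.auc_separation(0.5, 0.3) == 0.0
        # so amplitude means differ only by sampling noise
        diff = amps[is_right[:len(amps)]].mean() - amps[~is_right[:len(amps)]].mean()
        assert abs(diff) < 0.2

    def test_quiet_roi_is_constant(self):
        trials = synth.gen_behavior(n_trials=30, seed=2)
        fm = synth.gen_population(
            trials, n_rois=2, epoch_auc_targets=0.5,
            amp_base={"sound": 0.0, "delay": 0.0, "response": 0.0, "lick": 0.0},
            noise_sd=0.0, drift_amp=0.0, seed=3)
        assert np.ptp(fm.f) == pytest.approx(0.0)

    def test_deterministic_and_positive(self):
        trials = synth.gen_behavior(n_trials=40, seed=4)
        a = synth.gen_population(trials, n_rois=4, seed=5)
        b = synth.gen_population(trials, n_rois=4, seed=5)
        assert np.array_equal(a.f, b.f)
        assert (a.f > 0).all()

    def test_analytic_auc_of_generating_distributions(self):
        # Monte-Carlo AUC of the generating Gaussians matches the target
        rng = np.random.default_rng(6)
        for target in (0.6, 0.75, 0.9):
            delta = synth.auc_separation(target, 0.3)
            a = rng.normal(delta / 2, 0.3, 20000)
            b = rng.normal(-delta / 2, 0.3, 20000)
            emp = np.mean(a[:, None] > b[None, :1000])
            assert emp == pytest.approx(target, abs=0.01)
        assert synth.auc_separation(0.9, 0.3) == pytest.approx(
            np.sqrt(2) * 0.3 * norm.ppf(0.9))

    def test_bad_targets_rejected(self):
        trials = synth.gen_behavior(n_trials=20, seed=7)
        with pytest.raises(ValueError):
            synth.gen_population(trials, n_rois=0)
        with pytest.raises(ValueError):
            synth.gen_population(trials, n_rois=2, epoch_auc_targets=1.2)
        with pytest.raises(ValueError):
            synth.gen_population(trials, n_rois=2,
                                 kernel={"tau_rise": -1.0})


class TestGenPhotometry:
    def test_isosbestic_channel_has_no_signal(self):
        trials = synth.gen_behavior(n_trials=60, seed=8)
        ps = synth.gen_photometry(trials, early_auc=0.9, late_auc=0.9,
                                  artifact={"amplitude": 0.0}, drift_amp=0.0,
                                  noise_sd=0.1, seed=9)
        # f410 is baseline + noise only: no structure beyond noise scale
        assert ps.f410.std() < 0.2
        assert ps.f470.std() > 0.5  # the signal lives in the 470 channel

    def test_channels_equal_length_and_positive(self):
        trials = synth.gen_behavior(n_trials=40, seed=10)
        ps = synth.gen_photometry(trials, seed=11)
        assert ps.f470.shape == ps.f410.shape
        assert (ps.f470 > 0).all() and (ps.f410 > 0).all()

    def test_artifact_stored_and_shared(self):
        trials = synth.gen_behavior(n_trials=40, seed=12)
        ps = synth.gen_photometry(trials, amp_base=0.0, noise_sd=0.05,
                                  drift_amp=0.0,
                                  artifact={"amplitude": 5.0}, seed=13)
        art = ps.ground_truth["artifact"]
        assert np.corrcoef(ps.f470, art)[0, 1] > 0.95
        assert np.corrcoef(ps.f410, art)[0, 1] > 0.95


class TestGenSlice:
    def test_perfect_reliability_recovered(self):
        from delaylick import slice_ephys
        cells = synth.gen_slice(n_cells=3, responsive_frac=1.0,
                                reliability=1.0, amplitude_mv=8.0,
                                noise_sd=0.05, seed=14)
        for c in cells:
            r = slice_ephys.characterize_response(c["single"])
            assert r.reliability == 1.0

    def test_ground_truth_fields_present(self):
        cells = synth.gen_slice(n_cells=2, seed=15)
        for c in cells:
            assert set(c["ground_truth"]) == {"responsive", "latency_ms",
                                              "amplitude_mv", "reliability"}
            assert c["train"].stim_mode == "train10"
            assert len(c["train"].stim_times) == 10
            assert c["single"].stim_mode == "single"

    def test_baseline_precedes_stimulation(self):
        cells = synth.gen_slice(n_cells=1, seed=16)
        assert cells[0]["train"].stim_times[0] >= 1.0


class TestGenVideo:
    def test_divergence_absent_before_onset(self):
        trials = synth.gen_behavior(n_trials=80, seed=17)
        vt = synth.gen_video(trials, divergence_onset_s=1.0, seed=18)
        assert vt.ground_truth["divergence_onset_s"] == 1.0
        assert set(vt.x) == {"tongue", "nose"}
        for lk in vt.likelihood.values():
            assert (lk >= 0).all() and (lk <= 1).all()

    def test_dropout_rate_respected(self):
        trials = synth.gen_behavior(n_trials=40, seed=19)
        vt = synth.gen_video(trials, likelihood_dropout_rate=1.0, seed=20)
        assert (vt.likelihood["tongue"] <= 0.1).all()
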