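"""Evoked-EPSP detection: transient flags, latency/amplitude/reliability."""

import numpy as np
import pytest

from delaylick import slice_ephys, synth
from delaylick.containers import SliceSweepSet


def _epsp_sweeps(amplitude, n_sweeps=10, latency_ms=5.0, noise_sd=0.01,
                 n_pulses=1, sample_rate=10_000.0, seed=0,
                 respond_pulses=None):
    """Hand-built sweep set with EPSPs on selected pulses."""
    rng = np.random.default_rng(seed)
    if n_pulses == 1:
        stim = np.array([1.0])
        dur = 1.15
        mode = "single"
    else:
        stim = 1.0 + 0.1 * np.arange(n_pulses)
        dur = 2.2
        mode = "train10"
    n = int(dur * sample_rate)
    # kernel support kept under the 100-ms inter-pulse interval so an EPSP
    # never spills into the next pulse's detection window
    t = np.arange(0, 0.09, 1 / sample_rate)
    kern = np.exp(-t / 0.025) - np.exp(-t / 0.002)
    kern /= kern.max()
    if noise_sd > 0:
        # membrane-filtered noise, as in real Vm recordings (white noise
        # at 10 kHz would cross 3 s.d. by chance within any 50-ms window)
        nk = np.exp(-np.arange(0, 0.025, 1 / sample_rate) / 0.005)
        nk /= np.sqrt((nk ** 2).sum())
        vm = np.stack([
            -65.0 + noise_sd * np.convolve(rng.normal(size=n), nk)[:n]
            for _ in range(n_sweeps)])
    else:
        vm = np.full((n_sweeps, n), -65.0)
    respond = set(range(len(stim)) if respond_pulses is None else respond_pulses)
    for s in range(n_sweeps):
        for k, t0 in enumerate(stim):
            if k not in respond:
                continue
            i0 = int(round((t0 + latency_ms / 1e3) * sample_rate))
            seg = min(len(kern), n - i0)
            vm[s, i0:i0 + seg] += amplitude * kern[:seg]
    return SliceSweepSet(vm=vm, sample_rate=sample_rate, stim_times=stim,
                         stim_mode=mode)


class TestClassifyResponsive:
    def test_clear_responder_always_flagged(self):
        cells = synth.gen_slice(n_cells=5, responsive_frac=1.0,
                                reliability=1.0, amplitude_mv=4.0,
                                noise_sd=0.4, seed=0)
        for c in cells:
            assert slice_ephys.classify_responsive(c["train"]).responsive

    def test_noise_only_rarely_flagged(self):
        cells = synth.gen_slice(n_cells=100, responsive_frac=0.0, seed=1)
        fp = np.mean([slice_ephys.classify_responsive(c["train"]).responsive
                      for c in cells])
        assert fp <= 0.03

    def test_recovers_ground_truth_labels(self):
        cells = synth.gen_slice(n_cells=40, responsive_frac=0.5,
                                amplitude_mv=4.0, noise_sd=0.4,
                                n_train_sweeps=20, seed=2)
        errors = sum(
            slice_ephys.classify_responsive(c["train"]).responsive
            != c["ground_truth"]["responsive"] for c in cells)
        assert errors == 0

    def test_boundary_four_of_ten_not_responsive(self):
        sweeps = _epsp_sweeps(5.0, n_pulses=10, respond_pulses=range(4),
                              noise_sd=0.0, seed=3)
        res = slice_ephys.classify_responsive(sweeps)
        assert res.transient_flags.sum() == 4
        assert not res.responsive  # strictly more than 40% required

    def test_five_of_ten_is_responsive(self):
        sweeps = _epsp_sweeps(5.0, n_pulses=10, respond_pulses=range(5),
                              noise_sd=0.0, seed=4)
        assert slice_ephys.classify_responsive(sweeps).responsive

    def test_scale_invariance_of_detection(self):
        sweeps = _epsp_sweeps(2.0, n_pulses=10, noise_sd=0.2, seed=5)
        res1 = slice_ephys.classify_responsive(sweeps)
        scaled = SliceSweepSet(vm=(sweeps.vm + 65.0) * 7.0 - 65.0,
                               sample_rate=sweeps.sample_rate,
                               stim_times=sweeps.stim_times,
                               stim_mode=sweeps.stim_mode)
        res2 = slice_ephys.classify_responsive(scaled)
        assert np.array_equal(res1.transient_flags, res2.transient_flags)

    def test_single_pulse_protocol_rejected(self):
        sweeps = _epsp_sweeps(5.0, n_pulses=1, seed=6)
        with pytest.raises(ValueError):
            slice_ephys.classify_responsive(sweeps)


class TestCharacterizeResponse:
    def test_latency_within_one_sample(self):
        sweeps = _epsp_sweeps(8.0, n_sweeps=20, latency_ms=5.0,
                              noise_sd=0.2, seed=7)
        res = slice_ephys.characterize_response(sweeps)
        assert res.latency_ms == pytest.approx(5.0, abs=0.21)

    def test_amplitude_recovered(self):
        sweeps = _epsp_sweeps(8.0, n_sweeps=20, noise_sd=0.1, seed=8)
        res = slice_ephys.characterize_response(sweeps)
        assert res.amplitude_mv == pytest.approx(8.0, abs=0.5)

    def test_flat_sweeps_undefined_latency(self):
        sweeps = _epsp_sweeps(0.0, n_sweeps=6, noise_sd=0.0, seed=9)
        res = slice_ephys.characterize_response(sweeps)
        assert res.reliability == 0.0
        assert np.isnan(res.latency_ms)

    def test_reliability_matches_generating_probability(self):
        cells = synth.gen_slice(n_cells=6, responsive_frac=1.0,
                                reliability=0.7, amplitude_mv=6.0,
                                noise_sd=0.3, n_single_sweeps=40, seed=10)
        rel = [slice_ephys.characterize_response(c["single"]).reliability
               for c in cells]
        assert np.mean(rel) == pytest.approx(0.7, abs=0.1)

    def test_short_baseline_rejected(self):
        sweeps = _epsp_sweeps(5.0, seed=11)
        with pytest.raises(ValueError):
            bad = SliceSweepSet(vm=sweeps.vm[:, 5000:],
                                sample_rate=sweeps.sample_rate,
                                stim_times=np.array([0.5]),
                                stim_mode="single")
            slice_ephys.characterize_response(bad)


class TestCompareGroups:
    def _cells(self, n, n_resp, latency=5.0, amp=4.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            out.append(slice_ephys.CellResponse(
                responsive=i < n_resp,
                reliability=float(np.clip(rng.normal(0.8, 0.1), 0, 1)),
                latency_ms=float(rng.normal(latency, 0.5)),
                amplitude_mv=float(rng.normal(amp, 0.5))))
        return out

    def test_reported_proportions_not_significant(self):
        # 18/24 vs 28/44 responsive: chi-squared stays above 0.05
        out = slice_ephys.compare_groups(self._cells(24, 18, seed=1),
                                         self._cells(44, 28, seed=2),
                                         seed=3)
        assert out["responsive_chi2"].p_value > 0.05
        assert out["responsive_counts"].tolist() == [[18, 6], [28, 16]]

    def test_identical_groups_all_null(self):
        a = self._cells(15, 12, seed=4)
        out = slice_ephys.compare_groups(a, a, seed=5)
        assert out["responsive_chi2"].p_value == pytest.approx(1.0)
        for m in ("latency_ms", "reliability", "amplitude_mv"):
            assert out[m].p_value > 0.9

    def test_amplitude_shift_detected_with_power(self):
        hits, n_rep = 0, 40
        for rep in range(n_rep):
            a = self._cells(20, 20, amp=4.0, seed=100 + rep)
            b = self._cells(20, 20, amp=5.5, seed=200 + rep)  # 3 s.d. shift
            out = slice_ephys.compare_groups(a, b, n_shuffles=1000,
                                             seed=rep)
            if out["amplitude_mv"].p_value < 0.01:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_missing_metric_skipped_with_warning(self):
        a = self._cells(6, 0, seed=6)   # no responsive cells: metrics unused
        b = self._cells(6, 4, seed=7)
        with pytest.warns(UserWarning, match="skipped"):
            out = slice_ephys.compare_groups(a, b, seed=8)
        assert "latency_ms" not in out
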