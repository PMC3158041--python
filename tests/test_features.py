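"""Spike detection and feature extraction against constructed waveforms."""

import math

import numpy as np
import pytest

from cbmfit.features import (
    RAMP_FEATURES,
    STEP_FEATURES,
    SpikeTrain,
    accommodation_index,
    detect_spikes,
    extract_ramp_features,
    extract_step_features,
    sd_floor,
    summarize_repetitions,
    FeatureVector,
)
from cbmfit.model import VoltageTrace
from cbmfit.stimuli import make_ramp, make_step


def gaussian_bump_trace(spike_times_ms, dt=0.05, duration_ms=1000.0,
                        base=-70.0, peak=40.0, width_ms=0.5):
    """Synthetic trace with gaussian 'APs' at known times."""
    t = np.arange(0.0, duration_ms + dt / 2, dt)
    v = np.full_like(t, base)
    for ts in spike_times_ms:
        v += (peak - base) * np.exp(-(((t - ts) / width_ms) ** 2))
    return VoltageTrace(dt=dt, voltage=v)


def triangular_ap_trace(peak_time, dt=0.05, duration_ms=200.0, base=-60.0,
                        peak=40.0, rise_ms=1.0, fall_ms=1.0):
    t = np.arange(0.0, duration_ms + dt / 2, dt)
    up = base + (peak - base) * (t - (peak_time - rise_ms)) / rise_ms
    down = peak - (peak - base) * (t - peak_time) / fall_ms
    v = np.maximum(base, np.minimum(np.minimum(up, down), peak))
    return VoltageTrace(dt=dt, voltage=v)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        tr = VoltageTrace(dt=0.1, voltage=np.full(1000, -70.0))
        assert len(detect_spikes(tr)) == 0

    def test_three_bumps_at_known_times(self):
        times = [100.0, 300.0, 700.0]
        tr = gaussian_bump_trace(times)
        st = detect_spikes(tr, threshold=-20.0)
        assert len(st) == 3
        # threshold crossing precedes the peak by < 1 ms for these bumps
        assert np.all(np.abs(st.times - np.array(times)) < 1.0)

    def test_refractory_merges_close_crossings(self):
        dt = 0.05
        t = np.arange(0, 100, dt)
        v = np.full_like(t, -70.0)
        # two crossings 0.5 ms apart
        v[(t >= 50.0) & (t < 50.2)] = 0.0
        v[(t >= 50.5) & (t < 50.7)] = 0.0
        tr = VoltageTrace(dt=dt, voltage=v)
        assert len(detect_spikes(tr, refractory_ms=1.0)) == 1
        assert len(detect_spikes(tr, refractory_ms=0.1)) == 2

    def test_subsample_interpolation(self):
        # linear ramp through threshold: crossing time is exact
        dt = 0.1
        v = np.linspace(-70.0, 30.0, 1001)
        tr = VoltageTrace(dt=dt, voltage=v)
        st = detect_spikes(tr, threshold=-20.0)
        slope = (v[-1] - v[0]) / (1000 * dt)
        t_true = (-20.0 - v[0]) / slope
        assert st.times[0] == pytest.approx(t_true, abs=1e-9)


class TestAccommodationIndex:
    def test_periodic_train_is_zero(self):
        assert accommodation_index(np.full(9, 50.0)) == 0.0

    def test_antisymmetric_under_reversal_without_skip(self):
        isis = np.array([10.0, 12.0, 15.0, 13.0, 20.0])
        a = accommodation_index(isis, n_skip=0)
        b = accommodation_index(isis[::-1], n_skip=0)
        assert a == pytest.approx(-b)

    def test_lengthening_isis_positive(self):
        isis = np.linspace(20.0, 80.0, 12)
        assert accommodation_index(isis) > 0

    def test_too_few_spikes_undefined(self):
        assert math.isnan(accommodation_index(np.array([10.0])))


class TestStepFeatures:
    def test_six_features_and_latency(self):
        stim = make_step(150.0, onset_s=0.1, duration_s=0.8, tail_s=0.1)
        times = [153.0, 300.0, 500.0, 700.0]
        tr = gaussian_bump_trace(times, duration_ms=1000.0)
        fv = extract_step_features(tr, detect_spikes(tr), stim)
        assert fv.names == STEP_FEATURES
        assert fv["n_ap"] == 4.0
        assert fv["latency_first_ap"] == pytest.approx(53.0, abs=1.0)

    def test_triangular_halfwidth_analytic(self):
        """Triangular AP: width at half height follows from the geometry."""
        stim = make_step(150.0, onset_s=0.05, duration_s=0.1, tail_s=0.05)
        tr = triangular_ap_trace(peak_time=100.0)
        spikes = detect_spikes(tr, threshold=-20.0)
        fv = extract_step_features(tr, spikes, stim)
        # base = threshold (-20), peak 40 -> half level at +10;
        # flanks rise/fall (peak-base)=100 mV per 1 ms -> width = 2*(30/100)
        assert fv["ap_halfwidth"] == pytest.approx(0.6, abs=0.05)
        assert fv["ap_height_mean"] == pytest.approx(40.0, abs=0.5)

    def test_no_spikes_flags_undefined(self):
        stim = make_step(150.0, onset_s=0.1, duration_s=0.8, tail_s=0.1)
        tr = VoltageTrace(dt=0.05, voltage=np.full(20001, -70.0))
        fv = extract_step_features(tr, detect_spikes(tr), stim)
        assert fv["n_ap"] == 0.0
        for name in STEP_FEATURES[1:]:
            assert not fv.defined(name)

    def test_settle_prefix_invariance(self):
        """Prepending a resting prefix and shifting the window changes nothing."""
        stim = make_step(150.0, onset_s=0.1, duration_s=0.7, tail_s=0.1)
        times = [150.0, 400.0, 600.0]
        tr = gaussian_bump_trace(times, duration_ms=900.0)
        fv = extract_step_features(tr, detect_spikes(tr), stim)

        shift = 200.0
        stim2 = make_step(150.0, onset_s=0.3, duration_s=0.7, tail_s=0.1)
        tr2 = gaussian_bump_trace([t + shift for t in times], duration_ms=1100.0)
        fv2 = extract_step_features(tr2, detect_spikes(tr2), stim2)
        for name in STEP_FEATURES:
            if fv.defined(name):
                assert fv2[name] == pytest.approx(fv[name], abs=1e-6)

    def test_window_mismatch_raises(self):
        stim = make_step(150.0, onset_s=0.1, duration_s=2.0)
        tr = gaussian_bump_trace([100.0], duration_ms=500.0)
        with pytest.raises(ValueError, match="shorter than stimulus window"):
            extract_step_features(tr, detect_spikes(tr), stim)

    def test_wrong_kind_rejected(self):
        stim = make_ramp(150.0, rise_s=1.0)
        tr = gaussian_bump_trace([100.0])
        with pytest.raises(ValueError, match="expected a step"):
            extract_step_features(tr, detect_spikes(tr), stim)


class TestRampFeatures:
    def _ramp_with_heights(self, heights, dt=0.05):
        stim = make_ramp(200.0, rise_s=1.0, onset_s=0.0, dt_ms=dt)
        t = np.arange(0.0, 1000.0 + dt / 2, dt)
        v = np.full_like(t, -70.0)
        times = np.linspace(100.0, 900.0, len(heights))
        for ts, h in zip(times, heights):
            v += (h + 70.0) * np.exp(-(((t - ts) / 0.5) ** 2))
        return stim, VoltageTrace(dt=dt, voltage=v)

    def test_identical_heights_zero_slope(self):
        stim, tr = self._ramp_with_heights([40.0] * 5)
        fv = extract_ramp_features(tr, detect_spikes(tr), stim)
        assert fv.names == RAMP_FEATURES
        assert fv["ap_height_slope"] == pytest.approx(0.0, abs=1e-6)

    def test_linear_decline_recovered(self):
        heights = [40.0 - 2.0 * i for i in range(6)]
        stim, tr = self._ramp_with_heights(heights)
        fv = extract_ramp_features(tr, detect_spikes(tr), stim)
        assert fv["ap_height_slope"] == pytest.approx(-2.0, abs=0.05)

    def test_slope_matches_polyfit_oracle(self):
        rng = np.random.default_rng(0)
        heights = 35.0 + rng.normal(0, 3, 7)
        stim, tr = self._ramp_with_heights(list(heights))
        fv = extract_ramp_features(tr, detect_spikes(tr), stim)
        spikes = detect_spikes(tr)
        # oracle: ordinary least squares on measured peak heights
        from cbmfit.features import _ap_shape

        h, _, _ = _ap_shape(tr.voltage, tr.dt, spikes, 0.0, 1000.0)
        slope = np.polyfit(np.arange(len(h)), h, 1)[0]
        assert fv["ap_height_slope"] == pytest.approx(slope, rel=1e-9)

    def test_single_spike_slopes_undefined(self):
        stim, tr = self._ramp_with_heights([40.0])
        fv = extract_ramp_features(tr, detect_spikes(tr), stim)
        assert not fv.defined("ap_height_slope")
        assert not fv.defined("ahp_depth_slope")


class TestSummarize:
    def _fv(self, **vals):
        base = {n: math.nan for n in STEP_FEATURES}
        base.update(vals)
        return FeatureVector(base, kind="step")

    def test_hand_arithmetic(self):
        vecs = [self._fv(n_ap=v) for v in (10.0, 12.0, 14.0)]
        stats = summarize_repetitions(vecs)
        assert stats.mean["n_ap"] == 12.0
        assert stats.sd["n_ap"] == 2.0
        assert stats.n["n_ap"] == 3

    def test_identical_reps_hit_sd_floor(self):
        vecs = [self._fv(n_ap=7.0, ap_height_mean=35.0)] * 4
        stats = summarize_repetitions(vecs)
        assert stats.sd["n_ap"] == sd_floor("n_ap", 7.0)
        assert stats.sd["ap_height_mean"] == sd_floor("ap_height_mean", 35.0)

    def test_undefined_reps_excluded_with_count(self):
        vecs = [self._fv(n_ap=5.0, latency_first_ap=20.0),
                self._fv(n_ap=6.0),
                self._fv(n_ap=7.0, latency_first_ap=24.0)]
        stats = summarize_repetitions(vecs)
        assert stats.n["latency_first_ap"] == 2
        assert stats.n["n_ap"] == 3
        assert stats.usable("latency_first_ap")
        assert not stats.usable("accommodation_index")

    def test_single_rep_rejected(self):
        with pytest.raises(ValueError):
            summarize_repetitions([self._fv(n_ap=1.0)])

    def test_surrogate_sds_track_noise(self, desk_dataset):
        """Noisy repetitions yield spike-count spread above zero."""
        stats = desk_dataset.feature_targets("stepA")
        assert stats.sd["n_ap"] > 0
        assert stats.n["n_ap"] == 10


class TestConsistency:
    def test_n_ap_equals_windowed_spike_count(self, desk_dataset):
        stim = desk_dataset.battery["stepA"]
        tr = desk_dataset.traces["stepA"][0]
        spikes = detect_spikes(tr)
        fv = extract_step_features(tr, spikes, stim)
        t0 = stim.params["onset_s"] * 1e3
        t1 = t0 + stim.params["step_duration_s"] * 1e3
        assert fv["n_ap"] == len(spikes.restrict(t0, t1))
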