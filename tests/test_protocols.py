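"""Epoch maps, plasticity metrics, F-I curves, synaptic classification."""

import numpy as np
import pytest

import voltplace as vp
from voltplace.core import Trace
from voltplace.errors import AnalysisError
from voltplace.protocols import (
    EpochedSession,
    _window_bins,
    classify_evoked_spikes,
    window_signal_mean,
)
from voltplace.spikes import SpikeTrain
from voltplace.synthetic import _psp_kernel
from tests.test_spatial import constant_speed_behavior, make_map


class TestEpochMaps:
    def test_identical_firing_gives_similar_maps(self):
        beh = constant_speed_behavior(n_trials=12)
        rng = np.random.default_rng(0)
        spikes = SpikeTrain(np.flatnonzero(rng.random(len(beh)) < 0.004), 1000.0,
                            spike_height=1.0, noise_sigma=0.1)
        session = EpochedSession(["Pre"] * 6 + ["Post"] * 6, 90.0)
        maps = vp.epoch_maps(session, spikes, beh)
        a, b = maps["Pre"]["rate"], maps["Post"]["rate"]
        assert abs(a.mean_rate - b.mean_rate) < 1.0

    def test_silent_epoch_gives_zero_map(self):
        beh = constant_speed_behavior(n_trials=4)
        spikes = SpikeTrain(np.array([], int), 1000.0)
        session = EpochedSession(["Pre"] * 2 + ["Post"] * 2, 90.0)
        maps = vp.epoch_maps(session, spikes, beh)
        assert np.nansum(maps["Pre"]["rate"].rate) == 0.0


class TestAnticipatoryWindow:
    def test_uniform_map_returns_uniform_rate(self):
        assert vp.anticipatory_rate(make_map(np.full(80, 6.0)), 90.0) == pytest.approx(6.0)

    def test_window_bins_for_default_binning(self):
        # stim at 90 cm -> window [60, 80] cm -> bins 26..35 (2.25 cm bins)
        m = make_map(np.zeros(80))
        np.testing.assert_array_equal(_window_bins(m, 60.0, 80.0), np.arange(26, 36))

    def test_all_zero_map_gives_zero(self):
        assert vp.anticipatory_rate(make_map(np.zeros(80)), 90.0) == 0.0

    def test_window_outside_track_rejected(self):
        with pytest.raises(AnalysisError):
            vp.anticipatory_rate(make_map(np.zeros(80)), 20.0)

    def test_signal_window_mean(self):
        vals = np.zeros(80)
        vals[26:36] = 0.08
        m = vp.SignalMap(np.linspace(0, 180, 81), np.ones(80), vals, True, 180.0)
        assert window_signal_mean(m, 90.0) == pytest.approx(0.08)


class TestBackwardShift:
    def test_signed_subtraction(self):
        rate = np.zeros(80)
        rate[34] = 5.0  # bin center 77.625 cm
        assert vp.backward_shift(make_map(rate), 90.0) == pytest.approx(-12.375)

    def test_peak_at_stim_location(self):
        rate = np.zeros(80)
        rate[40] = 5.0  # center 91.125
        assert vp.backward_shift(make_map(rate), 91.125) == pytest.approx(0.0)

    def test_all_zero_undefined(self):
        assert np.isnan(vp.backward_shift(make_map(np.zeros(80)), 90.0))

    def test_tie_breaks_to_lowest_bin(self):
        rate = np.zeros(80)
        rate[[20, 30]] = 5.0
        shift = vp.backward_shift(make_map(rate), 90.0)
        assert shift == pytest.approx(make_map(rate).bin_centers[20] - 90.0)


class TestPairwiseCorrelation:
    def test_identical_and_inverted(self):
        rng = np.random.default_rng(1)
        m = make_map(rng.random(80) * 5)
        inv = make_map(6.0 - m.rate)
        out = dict(((i, j), r) for i, j, r in
                   vp.pairwise_map_correlation([m, m, inv]))
        assert out[(0, 1)] == pytest.approx(1.0)
        assert out[(0, 2)] == pytest.approx(-1.0)

    def test_constant_map_flagged_nan(self):
        m = make_map(np.random.default_rng(2).random(80))
        c = make_map(np.full(80, 2.0))
        (_, _, r), = vp.pairwise_map_correlation([m, c])[:1]
        assert np.isnan(r)

    def test_independent_maps_center_on_zero(self):
        rng = np.random.default_rng(3)
        maps = [make_map(rng.poisson(5, 80).astype(float)) for _ in range(21)]
        rs = [r for _, _, r in vp.pairwise_map_correlation(maps)]
        se = 1 / np.sqrt(80 - 1)
        assert abs(np.mean(rs)) < 3 * se / np.sqrt(len(rs))


class TestFI:
    def _exact_spikes(self, schedule, rates, fs=1000, win=500):
        idx = []
        for (onset, inten) in schedule:
            k = int(rates[inten] * win / fs)
            if k:
                idx.extend(onset + np.linspace(5, win - 5, k).astype(int))
        return SpikeTrain(np.array(sorted(idx)), fs, spike_height=1.0, noise_sigma=0.1)

    def test_exact_linear_rates_give_slope(self):
        schedule = [(1000 + 1000 * k, float(i)) for k, i in
                    enumerate([2, 4, 8, 16] * 5)]
        rates = {i: 2.0 * i for i in (2.0, 4.0, 8.0, 16.0)}
        spikes = self._exact_spikes(schedule, rates)
        curve = vp.fi_analysis(spikes, schedule, record_samples=25_000)
        assert curve.slope == pytest.approx(2.0, rel=0.02)
        assert curve.spontaneous_rate_hz == pytest.approx(0.0)

    def test_identical_sessions_ratio_one(self):
        schedule = [(1000 + 1000 * k, float(i)) for k, i in enumerate([5, 10] * 4)]
        rates = {5.0: 10.0, 10.0: 20.0}
        spikes = self._exact_spikes(schedule, rates)
        c = vp.fi_analysis(spikes, schedule, record_samples=10_000)
        assert vp.fi_slope_ratio(c, c) == pytest.approx(1.0)

    def test_single_intensity_rejected(self):
        spikes = SpikeTrain(np.array([100, 600]), 1000.0)
        with pytest.raises(AnalysisError):
            vp.fi_analysis(spikes, [(0, 5.0), (1000, 5.0)])

    def test_generator_gain_recovered(self):
        cfg = vp.SynthConfig(rng_seed=17)
        s = vp.simulate_session("fi", cfg, gain_hz_per_intensity=2.0)
        corrected, _ = vp.correct_photobleach(s.traces[0])
        spikes = vp.detect_spikes(corrected)
        curve = vp.fi_analysis(spikes, s.ground_truth.extra["schedule"],
                               record_samples=len(s.traces[0]))
        assert curve.slope == pytest.approx(2.0, rel=0.10)


class TestEvokedSpikes:
    def test_window_membership(self):
        spikes = SpikeTrain(np.array([1017, 2030, 2999]), 1000.0)
        out = classify_evoked_spikes(spikes, [1000, 2000, 3000])
        assert list(out.per_trial) == [True, False, False]
        assert out.latencies_ms[0] == pytest.approx(17.0)

    def test_boundary_is_inclusive(self):
        spikes = SpikeTrain(np.array([1026]), 1000.0)
        out = classify_evoked_spikes(spikes, [1000])
        assert out.per_trial[0]


class TestSynapticClassification:
    def _session(self, cell_type, seed):
        cfg = vp.SynthConfig(rng_seed=seed)
        s = vp.simulate_session("synaptic", cfg, cell_type=cell_type)
        corrected, _ = vp.correct_photobleach(s.traces[0])
        spikes = vp.detect_spikes(corrected)
        onsets = [e.onset_sample for e in s.stim_events]
        return s, corrected, spikes, onsets

    def test_rule_on_constructed_responses(self):
        # deterministic traces exercising each branch of the decision rule
        fs = 1000.0
        onsets = list(range(1000, 13_000, 1000))
        kern = _psp_kernel(4.0, 40.0, 0.1, fs)
        up = np.zeros(15_000)
        for o in onsets:
            up[o + 12:o + 12 + len(kern)] += kern
        quiet = SpikeTrain(np.array([200, 14_500]), fs, spike_height=1.0, noise_sigma=0.01)
        exc = vp.classify_synaptic_response(
            Trace(up, normalization="spike_height"), quiet, onsets)
        assert exc.label == "excitatory" and exc.auc > 0
        inh = vp.classify_synaptic_response(
            Trace(-up, normalization="spike_height"), quiet, onsets)
        assert inh.label == "inhibitory" and inh.auc < 0
        # >1 evoked spike forces excitatory even with negative AUC
        spiking = SpikeTrain(np.array([1010, 2012, 3015]), fs,
                             spike_height=1.0, noise_sigma=0.01)
        forced = vp.classify_synaptic_response(
            Trace(-up, normalization="spike_height"), spiking, onsets)
        assert forced.label == "excitatory"

    def test_generator_sessions_classified(self):
        s, tr, spikes, onsets = self._session("excitatory", 31)
        assert vp.classify_synaptic_response(tr, spikes, onsets).label == "excitatory"
        s, tr, spikes, onsets = self._session("inhibitory", 31)
        cls = vp.classify_synaptic_response(tr, spikes, onsets)
        gt_spikes = s.ground_truth.true_spike_times
        chance = sum(1 for o in onsets if np.any((gt_spikes > o) & (gt_spikes <= o + 26)))
        if chance <= 1:  # unambiguous under the stated rule
            assert cls.label == "inhibitory"
        assert cls.auc < 0

    def test_zero_trials_rejected(self):
        spikes = SpikeTrain(np.array([100]), 1000.0, spike_height=1.0, noise_sigma=0.1)
        with pytest.raises(AnalysisError):
            vp.classify_synaptic_response(Trace(np.zeros(2000)), spikes, [])


class TestSTASplit:
    def test_nonspiking_trials_reproduce_psp(self):
        fs = 1000.0
        onsets = list(range(1000, 9000, 1000))
        kern = _psp_kernel(4.0, 40.0, 0.124, fs)
        data = np.zeros(10_000)
        for o in onsets:
            data[o + 12:o + 12 + len(kern)] += kern
        quiet = SpikeTrain(np.array([100, 9900]), fs, spike_height=1.0, noise_sigma=0.01)
        sp, ns = vp.stimulus_triggered_average_split(
            Trace(data, normalization="spike_height"), quiet, onsets)
        assert sp is None
        post = ns.mean[ns.lags_ms >= 0]
        assert post.max() == pytest.approx(0.124, abs=1e-6)
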