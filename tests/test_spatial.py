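"""Rate/signal maps, spatial information, shuffle test, fields, QC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import voltplace as vp
from voltplace.core import BehaviorTrack, Trace
from voltplace.errors import AnalysisError
from voltplace.spatial import (
    RateMap,
    binned_rate_series,
    identify_place_fields,
    in_out_field_rates,
    smooth_with_missing,
)


def constant_speed_behavior(n_trials=5, speed=20.0, fs=1000.0, track=180.0, iti_s=1.0):
    """Deterministic behavior: constant-speed traversals with fixed ITIs."""
    n_run = int(track / speed * fs)
    n_iti = int(iti_s * fs)
    pos, vel, trial = [], [], []
    for k in range(n_trials):
        pos += [np.zeros(n_iti), np.arange(1, n_run + 1) * speed / fs]
        vel += [np.zeros(n_iti), np.full(n_run, speed)]
        trial.append(np.full(n_iti + n_run, k, int))
    pos = np.clip(np.concatenate(pos), 0, track)
    n = len(pos)
    z = np.zeros(n, bool)
    return BehaviorTrack(np.arange(n) / fs, pos, np.concatenate(vel),
                         np.concatenate(trial), z, z, z, track, fs)


def make_map(rate, occupancy=None, smoothed=True, track=180.0):
    rate = np.asarray(rate, float)
    n = len(rate)
    occ = np.ones(n) if occupancy is None else np.asarray(occupancy, float)
    edges = np.linspace(0, track, n + 1)
    return RateMap(edges, occ, rate * occ, rate, smoothed, track)


class TestRateMap:
    def test_rate_is_count_over_occupancy(self):
        beh = constant_speed_behavior(n_trials=1, speed=15.0)  # 2.25 cm bin -> 0.15 s
        # put 3 events in bin 10: positions [22.5, 24.75) -> samples 1500..1649 of the run
        run_start = 1000
        events = run_start + np.array([1510, 1570, 1630])
        m = vp.make_rate_map(events, beh, smooth=False)
        assert m.counts[10] == 3
        assert m.rate[10] == pytest.approx(3 / m.occupancy_s[10])

    def test_conservation_unsmoothed(self, place_session):
        beh, spikes = place_session["behavior"], place_session["spikes"]
        m = vp.make_rate_map(spikes, beh, smooth=False)
        keep = beh.velocity >= 5.0
        retained_events = np.count_nonzero(keep[spikes.indices])
        assert m.counts.sum() == retained_events
        assert m.occupancy_s.sum() == pytest.approx(keep.sum() / 1000.0)
        with np.errstate(invalid="ignore"):
            total = np.nansum(m.rate * m.occupancy_s)
        assert total == pytest.approx(retained_events)

    def test_uniform_poisson_rates_flat(self):
        beh = constant_speed_behavior(n_trials=60)
        rng = np.random.default_rng(8)
        r = 5.0
        events = np.flatnonzero(rng.random(len(beh)) < r / 1000.0)
        m = vp.make_rate_map(events, beh, smooth=False)
        se = np.sqrt(r / m.occupancy_s)
        dev = np.abs(m.rate - r) / se
        assert np.mean(dev < 3) >= 0.95 and dev.max() < 5

    def test_speed_filter_removes_slow_samples(self):
        beh = constant_speed_behavior(n_trials=2)
        m = vp.make_rate_map(np.array([], int), beh, smooth=False)
        # ITI samples (speed 0) carry no occupancy
        assert m.occupancy_s.sum() == pytest.approx((len(beh) - 2 * 1000) / 1000.0)
        with pytest.raises(AnalysisError):
            vp.make_rate_map(np.array([], int), beh, speed_min=50.0)

    def test_smoothing_preserves_mean(self, place_session):
        beh, spikes = place_session["behavior"], place_session["spikes"]
        raw = vp.make_rate_map(spikes, beh, smooth=False)
        sm = vp.make_rate_map(spikes, beh, smooth=True)
        assert np.nanmean(sm.rate) == pytest.approx(np.nanmean(raw.rate), rel=0.01)


class TestSignalMap:
    def test_constant_signal(self):
        beh = constant_speed_behavior(n_trials=2)
        m = vp.make_signal_map(Trace(np.full(len(beh), 3.3)), beh, smooth=False)
        np.testing.assert_allclose(m.values[np.isfinite(m.values)], 3.3)

    def test_monotone_signal_gives_monotone_map(self):
        beh = constant_speed_behavior(n_trials=2)
        m = vp.make_signal_map(Trace(beh.position / 180.0), beh, smooth=False)
        v = m.values[np.isfinite(m.values)]
        assert np.all(np.diff(v) > 0)

    def test_injected_ramp_peaks_at_field_center(self, dvm_session):
        ramp = vp.extract_ramp(dvm_session["removed_u"])
        m = vp.make_signal_map(ramp, dvm_session["behavior"])
        center = dvm_session["ground_truth"].field_center
        peak_cm = m.bin_centers[np.nanargmax(m.values)]
        assert abs(peak_cm - center) <= 2 * 2.25


class TestSpatialInformation:
    def test_uniform_map_zero_bits(self):
        assert vp.spatial_information(make_map(np.full(80, 3.0))) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_worked_examples(self):
        si1 = vp.spatial_information_from_arrays([0.5, 0.5], [2.0, 0.0])
        si2 = vp.spatial_information_from_arrays([0.25, 0.75], [4.0, 0.0])
        assert si1 == pytest.approx(1.0, abs=1e-12)
        assert si2 == pytest.approx(2.0, abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        rates = rng.random(20) * 5
        p = rng.random(20)
        p /= p.sum()
        a = vp.spatial_information_from_arrays(p, rates)
        b = vp.spatial_information_from_arrays(p, c * rates)
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)

    def test_zero_mean_rate_is_error(self):
        with pytest.raises(AnalysisError):
            vp.spatial_information_from_arrays([0.5, 0.5], [0.0, 0.0])


class TestPlaceCellTest:
    def test_strong_place_cell_detected(self):
        # in-field ~9.7 Hz vs out-of-field ~1.8 Hz regime
        hits = []
        for seed in range(5):
            cfg = vp.SynthConfig(n_trials=8, rng_seed=60 + seed)
            beh = vp.simulate_behavior(cfg)
            tr, gt = vp.simulate_voltage_trace(cfg, beh)
            corrected, _ = vp.correct_photobleach(tr)
            spikes = vp.detect_spikes(corrected)
            trials = binned_rate_series(spikes, beh)
            pc = vp.place_cell_test(trials, n_shuffles=500, seed=seed)
            hits.append(pc.is_place_cell)
        assert all(hits)

    def test_null_equal_to_observed_not_flagged(self):
        # constant-rate cell: shuffling changes nothing, SI null == observed
        beh = constant_speed_behavior(n_trials=6)
        spikes = np.arange(0, len(beh), 200)  # metronome firing
        trials = binned_rate_series(spikes, beh)
        # make the rate series literally constant within trials
        for t in trials:
            t["rate"][:] = 5.0
        pc = vp.place_cell_test(trials, n_shuffles=200, seed=0)
        assert not pc.is_place_cell
        assert pc.percentile == pytest.approx(0.0)

    def test_few_shuffles_warns(self):
        beh = constant_speed_behavior(n_trials=5)
        trials = binned_rate_series(np.arange(0, len(beh), 333), beh)
        with pytest.warns(UserWarning):
            vp.place_cell_test(trials, n_shuffles=50, seed=0)

    def test_shuffle_reproducibility(self, place_session):
        trials = binned_rate_series(place_session["spikes"], place_session["behavior"])
        a = vp.place_cell_test(trials, n_shuffles=300, seed=5)
        b = vp.place_cell_test(trials, n_shuffles=300, seed=5)
        np.testing.assert_array_equal(a.shuffle_si, b.shuffle_si)


class TestPlaceFields:
    def test_uniform_map_has_no_fields(self):
        assert identify_place_fields(make_map(np.full(80, 3.0))) == []

    def test_rectangular_bump_recovered_exactly(self):
        rate = np.full(80, 0.5)
        rate[30:36] = 10.0
        fields = identify_place_fields(make_map(rate))
        assert len(fields) == 1
        f = fields[0]
        assert (f.start_bin, f.end_bin) == (30, 35)
        assert f.in_rate == pytest.approx(10.0)
        assert f.out_rate == pytest.approx(0.5)

    def test_short_bump_rejected_by_length_rule(self):
        rate = np.zeros(80)
        rate[40:43] = 10.0
        assert identify_place_fields(make_map(rate)) == []

    def test_weak_bump_rejected_by_rate_rule(self):
        rate = np.full(80, 0.2)
        rate[30:40] = 1.0  # < 1.5 Hz in-field mean
        assert identify_place_fields(make_map(rate)) == []

    def test_two_fields_found_in_order_of_peak(self):
        rate = np.full(80, 0.2)
        rate[10:16] = 8.0
        rate[50:57] = 5.0
        fields = identify_place_fields(make_map(rate))
        assert [f.peak_bin for f in fields] == [10, 50]

    def test_unsmoothed_map_rejected(self):
        with pytest.raises(AnalysisError):
            identify_place_fields(make_map(np.ones(80), smoothed=False))

    def test_in_out_union_rates(self):
        rate = np.full(80, 1.0)
        rate[20:30] = 9.0
        m = make_map(rate)
        fields = identify_place_fields(m)
        in_r, out_r = in_out_field_rates(m, fields)
        assert in_r == pytest.approx(9.0)
        assert out_r == pytest.approx(1.0)


class TestQC:
    @pytest.mark.parametrize("n_trials, rate, included, reason", [
        (4, 2.0, False, "trials<5"),
        (10, 0.05, False, "rate<0.1Hz"),
        (6, 1.0, True, None),
    ])
    def test_inclusion_rules(self, n_trials, rate, included, reason):
        qc = vp.qc_status(n_trials, rate)
        assert qc.included == included
        if reason:
            assert reason in qc.reasons

    def test_batch_filter(self):
        out = vp.qc_filter_cells([(4, 2.0), (10, 1.0)])
        assert [q.included for q in out] == [False, True]


class TestSmoothing:
    def test_missing_bins_stay_missing(self):
        v = np.array([1.0, np.nan, 3.0, 4.0, np.nan, 6.0])
        out = smooth_with_missing(v)
        assert np.isnan(out[1]) and np.isnan(out[4])
        assert np.isfinite(out[[0, 2, 3, 5]]).all()

    def test_constant_preserved(self):
        out = smooth_with_missing(np.full(20, 2.5))
        np.testing.assert_allclose(out, 2.5)
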