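"""Slow-wave detector: half-wave candidates vs a sign-scan oracle, post-IED
exclusion, nearest-rank percentile gate, closed-form features and rates."""

import numpy as np
import pandas as pd
import pytest

from lowsuite.core import ChannelInfo, Event, EventTable, Recording
from lowsuite.sw import (
    amplitude_gate,
    candidate_halfwaves,
    corrected_lows_rate,
    detect_slow_waves,
    exclude_post_ied,
    nearest_rank_percentile,
    normalize_features,
    spatial_cooccurrence,
    sw_features,
    filter_sw,
)
from lowsuite.synth import synth_slow_wave

FS = 512.0


class TestCandidates:
    def test_pure_1p25hz_all_halfwaves_kept(self):
        t = np.arange(int(20 * FS)) / FS
        x = 100 * np.sin(2 * np.pi * 1.25 * t)
        c = candidate_halfwaves(x, FS)
        # every half-wave away from the filter edge transients lasts 0.4 s
        interior = c[(c["onset"] > 2.0) & (c["zc2"] < 18.0)]
        assert len(interior) >= 38
        assert np.allclose(interior["duration"], 0.4, atol=2 / FS)

    def test_3hz_halfwaves_too_short(self):
        t = np.arange(int(20 * FS)) / FS
        x = 100 * np.sin(2 * np.pi * 3 * t)
        assert len(candidate_halfwaves(x, FS)) == 0

    def test_zero_crossings_match_sign_scan_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(30 * FS))
        xf = filter_sw(x, FS)
        c = candidate_halfwaves(x, FS, filtered=xf)
        sign = np.where(xf >= 0, 1, -1)
        zc = [i + 1 for i in range(len(sign) - 1) if sign[i] != sign[i + 1]]
        zc_set = set(zc)
        for row in c.itertuples():
            assert int(round(row.onset * FS)) in zc_set
            assert int(round(row.zc2 * FS)) in zc_set

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            candidate_halfwaves(np.zeros(100), FS)


class TestPostIEDExclusion:
    def _cands(self, onsets):
        return pd.DataFrame(
            {"onset": onsets, "trough": np.asarray(onsets) + 0.2,
             "zc2": np.asarray(onsets) + 0.4, "amplitude": 50.0,
             "duration": 0.4, "polarity": 1})

    def test_within_horizon_dropped(self):
        out = exclude_post_ied(self._cands([10.5]), np.array([10.0]))
        assert len(out) == 0

    def test_beyond_horizon_kept(self):
        out = exclude_post_ied(self._cands([11.5]), np.array([10.0]))
        assert len(out) == 1

    def test_boundary_exactly_one_second_dropped(self):
        out = exclude_post_ied(self._cands([11.0]), np.array([10.0]))
        assert len(out) == 0

    def test_other_region_ieds_do_not_apply(self):
        # scoping is the caller's job: no same-region IEDs means nothing drops
        out = exclude_post_ied(self._cands([10.5]), np.array([]))
        assert len(out) == 1


class TestAmplitudeGate:
    def test_nearest_rank_oracle_distinct_amps(self):
        amps = np.arange(1.0, 1001.0)
        rng = np.random.default_rng(0)
        rng.shuffle(amps)
        c = pd.DataFrame(
            {"onset": np.arange(1000) * 2.0, "trough": np.arange(1000) * 2.0 + 0.2,
             "zc2": np.arange(1000) * 2.0 + 0.4, "amplitude": amps,
             "duration": 0.4, "polarity": 1})
        out = amplitude_gate(c)
        # nearest-rank 90th percentile of 1..1000 is 900; strictly greater -> 100
        assert len(out) == 100
        assert out["amplitude"].min() == 901.0

    def test_nearest_rank_definition(self):
        assert nearest_rank_percentile(np.arange(1.0, 11.0), 90) == 9.0
        assert nearest_rank_percentile(np.array([5.0]), 90) == 5.0

    def test_all_equal_amplitudes_none_retained(self):
        c = pd.DataFrame(
            {"onset": np.arange(20) * 2.0, "trough": np.arange(20) * 2.0 + 0.2,
             "zc2": np.arange(20) * 2.0 + 0.4, "amplitude": 7.0,
             "duration": 0.4, "polarity": 1})
        assert len(amplitude_gate(c)) == 0

    def test_small_group_skipped_with_warning(self, caplog):
        c = pd.DataFrame(
            {"onset": [1.0], "trough": [1.2], "zc2": [1.4], "amplitude": [10.0],
             "duration": [0.4], "polarity": [1]})
        with caplog.at_level("WARNING"):
            out = amplitude_gate(c)
        assert len(out) == 0 and "skipping" in caplog.text

    def test_polarities_gated_separately(self):
        n = 40
        c = pd.DataFrame(
            {"onset": np.arange(2 * n) * 2.0, "trough": np.arange(2 * n) * 2.0 + 0.2,
             "zc2": np.arange(2 * n) * 2.0 + 0.4,
             "amplitude": np.r_[np.arange(1, n + 1), -10 * np.arange(1, n + 1)],
             "duration": 0.4, "polarity": np.r_[np.ones(n), -np.ones(n)]})
        out = amplitude_gate(c)
        assert (out["polarity"] == 1).sum() == (out["polarity"] == -1).sum() == 4


class TestFeatures:
    def test_half_sine_closed_form(self):
        x = np.zeros(int(10 * FS))
        w = synth_slow_wave(0.5, 100.0, -1, FS)
        i0 = int(2.0 * FS)
        x[i0 : i0 + w.size] += w
        amp, slope, freq, t_ext = sw_features(2.0, 2.5, -1, x, FS)
        assert amp == pytest.approx(-100.0, rel=1e-3)
        assert slope == pytest.approx(-400.0, rel=0.01)
        assert freq == pytest.approx(1.0)
        assert t_ext == pytest.approx(2.25, abs=2 / FS)

    def test_median_duration_gives_1p3_hz(self):
        # the closed-form inversion: a 0.385 s half-wave is a 1.3 Hz oscillation
        assert 1.0 / (2 * 0.385) == pytest.approx(1.3, abs=0.002)

    def test_slope_scales_with_amplitude_freq_does_not(self):
        x = np.zeros(int(10 * FS))
        w = synth_slow_wave(0.5, 100.0, 1, FS)
        x[int(2 * FS) : int(2 * FS) + w.size] += w
        a1, s1, f1, _ = sw_features(2.0, 2.5, 1, x, FS)
        a2, s2, f2, _ = sw_features(2.0, 2.5, 1, 2 * x, FS)
        assert a2 == pytest.approx(2 * a1) and s2 == pytest.approx(2 * s1)
        assert f2 == f1

    def test_truncated_window_errors(self):
        with pytest.raises(ValueError, match="truncated"):
            sw_features(9.5, 9.9, 1, np.zeros(int(10 * FS)), FS)


class TestNormalization:
    def _table(self, amps, slopes):
        events = [
            Event("nSW", "c0", 10.0 * i, 10.0 * i + 0.2, 10.0 * i + 0.4,
                  amplitude_uV=a, slope_uV_per_s=s, freq_hz=1.25)
            for i, (a, s) in enumerate(zip(amps, slopes))
        ]
        return EventTable(events, 1000.0)

    def test_norms_and_sign_invariance(self):
        t1 = normalize_features(self._table([-50.0, -100.0], [-200.0, -400.0]))
        assert [e.norm_amplitude for e in t1] == [0.5, 1.0]
        assert [e.norm_slope for e in t1] == [0.5, 1.0]
        t2 = normalize_features(self._table([50.0, 100.0], [200.0, 400.0]))
        assert [e.norm_amplitude for e in t2] == [0.5, 1.0]

    def test_single_event_norm_one(self):
        t = normalize_features(self._table([-80.0], [-320.0]))
        assert t.events[0].norm_amplitude == 1.0


class TestRates:
    def test_corrected_rate_is_product(self):
        assert corrected_lows_rate(0.06, 0.01) == pytest.approx(6e-4)
        assert corrected_lows_rate(0.06, 0.0) == 0.0

    def test_commutes_with_electrode_averaging(self):
        sw = np.array([0.05, 0.07]); ied = np.array([0.01, 0.02])
        a = corrected_lows_rate(sw.mean(), ied.mean())
        b = np.mean([corrected_lows_rate(s, i) for s, i in zip(sw, ied)])
        # product of means vs mean of products differ by the covariance term
        assert a == pytest.approx(b - np.cov(sw, ied, bias=True)[0, 1])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            corrected_lows_rate(-0.1, 0.01)


class TestSpatialCooccurrence:
    def _table(self, times_by_channel, duration=1000.0):
        events = []
        for ch, times in times_by_channel.items():
            for t in times:
                events.append(Event("nSW", ch, t - 0.2, t, t + 0.2,
                                    amplitude_uV=100.0))
        return EventTable(events, duration)

    def _chans(self, n):
        return [ChannelInfo(f"c{i}", "hippocampus", i) for i in range(n)]

    def test_identical_waves_give_one(self):
        times = np.arange(10.0, 100.0, 10.0)
        t = self._table({"c0": times, "c1": times, "c2": times})
        assert spatial_cooccurrence(t, self._chans(3), "hippocampus") == 1.0

    def test_zero_window_gives_zero_for_distinct_times(self):
        t = self._table({"c0": [10.0, 20.0], "c1": [15.0, 25.0]})
        assert spatial_cooccurrence(t, self._chans(2), "hippocampus",
                                    window=0.0) == 0.0

    def test_independent_poisson_matches_coincidence_formula(self):
        rng = np.random.default_rng(0)
        rate, dur, w = 0.1, 20000.0, 0.1
        t = self._table(
            {f"c{i}": np.sort(rng.uniform(1, dur - 1, int(rate * dur)))
             for i in range(2)}, duration=dur)
        frac = spatial_cooccurrence(t, self._chans(2), "hippocampus", window=w)
        assert frac == pytest.approx(2 * w * rate, rel=0.35)

    def test_single_channel_region_is_nan(self):
        t = self._table({"c0": [10.0]})
        assert np.isnan(spatial_cooccurrence(t, self._chans(1), "hippocampus"))


class TestPipelineInvariants:
    def test_detected_waves_satisfy_event_invariants(self, small_dataset):
        ds = small_dataset
        from lowsuite.ied import detect_ieds

        ieds = detect_ieds(ds.recording)
        sws = detect_slow_waves(ds.recording, ieds)
        assert len(sws) > 0
        ied_by_region = np.sort(ieds.times())
        for e in sws:
            assert e.onset_s < e.trough_s < e.zc2_s
            assert 0.25 <= e.zc2_s - e.onset_s <= 1.0
            assert 0.5 <= e.freq_hz <= 2.0
            assert 0.0 <= e.norm_amplitude <= 1.0
            assert 0.0 <= e.norm_slope <= 1.0
            # joint invariant: no wave within 1 s after a detected discharge
            j = np.searchsorted(ied_by_region, e.onset_s)
            if j > 0:
                assert e.onset_s - ied_by_region[j - 1] > 1.0

    def test_planted_high_amplitude_waves_mostly_retained(self, small_dataset):
        ds = small_dataset
        from lowsuite.ied import detect_ieds

        sws = detect_slow_waves(ds.recording, detect_ieds(ds.recording))
        truth = ds.truth.of_kind("nSW", "pSW")
        det = {lab: np.sort(sws.on_channel(lab).times())
               for lab in ds.recording.channel_labels()}
        hits = 0
        for e in truth:
            t = det[e.channel]
            j = np.searchsorted(t, e.trough_s)
            near = min([abs(t[k] - e.trough_s) for k in (j - 1, j)
                        if 0 <= k < t.size], default=np.inf)
            hits += near <= 0.1
        assert hits / len(truth) >= 0.9
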