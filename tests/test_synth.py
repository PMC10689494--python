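"""Generator: spectral shape, kernel shapes, planted modulations and
determinism, each checked against independent oracles."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from lowsuite import SynthConfig, generate_dataset
from lowsuite.synth import (
    BackgroundConfig,
    IEDConfig,
    SWConfig,
    TrialsConfig,
    generate_background,
    generate_hg_carrier,
    generate_spike_trains,
    generate_trials,
    synth_ied,
    synth_slow_wave,
)

FS = 512.0


class TestBackground:
    def test_rms_within_5_percent(self):
        x = generate_background(60.0, FS, 1.0, 10.0, seed=0)
        assert x.std() == pytest.approx(10.0, rel=0.05)

    def test_white_noise_flat_welch_spectrum(self):
        x = generate_background(120.0, FS, 0.0, 1.0, seed=1, highpass_hz=0.0)
        f, p = sps.welch(x, fs=FS, nperseg=2048)
        sel = (f > 5) & (f < 200)
        # flat: band means across octaves agree within Welch scatter
        lo = p[(f > 5) & (f < 50)].mean()
        hi = p[(f > 100) & (f < 200)].mean()
        assert lo == pytest.approx(hi, rel=0.1)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_loglog_spectral_slope(self, alpha):
        x = generate_background(240.0, FS, alpha, 1.0, seed=2)
        f, p = sps.welch(x, fs=FS, nperseg=4096)
        sel = (f > 2) & (f < 100)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-alpha, abs=0.15)

    def test_seeded_determinism(self):
        a = generate_background(10.0, FS, 1.0, 5.0, seed=7)
        b = generate_background(10.0, FS, 1.0, 5.0, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            generate_background(10.0, FS, 3.0, 5.0, seed=0)


class TestSlowWaveKernel:
    def test_half_sine_closed_form(self):
        w = synth_slow_wave(0.4, 100.0, -1, FS)
        assert w.min() == pytest.approx(-100.0, rel=1e-3)
        assert np.argmin(w) == pytest.approx(0.2 * FS, abs=1)
        assert w.size == pytest.approx(0.4 * FS, abs=1)
        # exactly one sign over the support
        assert (w[1:-1] < 0).all()

    def test_planted_frequency(self):
        # a 0.4 s half-wave is half a 1.25 Hz cycle
        assert 1.0 / (2 * 0.4) == pytest.approx(1.25)

    def test_duration_bounds_enforced(self):
        with pytest.raises(ValueError):
            synth_slow_wave(0.2, 100.0, 1, FS)

    def test_candidate_stage_round_trip(self):
        from lowsuite.sw import candidate_halfwaves

        rng = np.random.default_rng(5)
        x = generate_background(30.0, FS, 1.0, 5.0, seed=6)
        w = synth_slow_wave(0.4, 300.0, -1, FS)
        i0 = int(10.0 * FS)
        x[i0 : i0 + w.size] += w
        cands = candidate_halfwaves(x, FS)
        near = cands[np.abs(cands["trough"] - 10.2) < 0.1]
        assert len(near) == 1
        # the 0.5-4 Hz band-pass shortens the half-wave slightly (edge lobes
        # pull the zero crossings inward); the wave must stay duration-valid
        assert 0.3 <= near["duration"].iloc[0] <= 0.45
        assert -320.0 < near["amplitude"].iloc[0] < -180.0


class TestIEDKernel:
    def test_band_concentration_vs_background(self):
        from lowsuite.ied import bandpass, envelope

        wave, peak = synth_ied(FS, 100.0)
        bg = generate_background(4.0, FS, 1.0, wave.std(), seed=3)
        padded = np.zeros(bg.size)
        padded[1000 : 1000 + wave.size] = wave
        env_ied = envelope(bandpass(padded, FS, 20, 80)).max()
        env_bg = envelope(bandpass(bg, FS, 20, 80)).mean()
        assert env_ied >= 4 * env_bg

    def test_afterwave_zero_gives_pure_sharp(self):
        wave, peak = synth_ied(FS, 100.0, 0.04, afterwave_amplitude_uV=0.0)
        assert wave.size == 2 * peak + 1
        assert np.abs(wave).max() == pytest.approx(100.0)

    def test_sharp_width_bound(self):
        with pytest.raises(ValueError):
            synth_ied(FS, 100.0, 0.2)

    def test_detected_at_8x_background(self):
        from lowsuite.ied import detect_ied_channel

        rng_bg = generate_background(60.0, FS, 1.0, 20.0, seed=4)
        wave, peak = synth_ied(FS, 160.0, 0.04, 40.0, 0.5)
        x = rng_bg.copy()
        i0 = int(30.0 * FS) - peak
        x[i0 : i0 + wave.size] += wave
        cands = detect_ied_channel(x, FS)
        assert len(cands) == 1
        assert cands[0][0] == pytest.approx(30.0, abs=0.02)


class TestHGCarrier:
    def test_full_suppression_silences_spans(self):
        spans = [(2.0, 2.5), (5.0, 5.6)]
        x = generate_hg_carrier(10.0, FS, (45, 130), 5.0, spans, [],
                                np.random.default_rng(0), downstate_suppression=1.0)
        for a, b in spans:
            seg = x[int(a * FS) : int(b * FS)]
            assert np.abs(seg).max() == 0.0

    def test_half_suppression_quarters_power(self):
        from lowsuite.spectral import multitaper_band_power

        rng = np.random.default_rng(1)
        spans = [(t, t + 0.4) for t in np.arange(2.0, 118.0, 2.0)]
        x = generate_hg_carrier(120.0, FS, (45, 130), 5.0, spans, [], rng,
                                downstate_suppression=0.5)
        inside = np.concatenate(
            [x[int((a + 0.05) * FS) : int((b - 0.05) * FS)] for a, b in spans])
        n_in = inside.size
        outside = np.concatenate(
            [x[int((b + 0.3) * FS) : int((b + 0.3) * FS) + 100] for a, b in spans])
        ratio = inside.var() / outside.var()
        assert ratio == pytest.approx(0.25, abs=0.05)

    def test_positive_ramp_detectable_by_regression(self):
        rng = np.random.default_rng(2)
        ied_times = np.arange(40.0, 600.0, 40.0)
        x = generate_hg_carrier(600.0, FS, (45, 130), 5.0, [], ied_times, rng,
                                preied_ramp=0.05, preied_window_s=30.0)
        # log power in 1 s windows vs time-to-IED
        logs, taus = [], []
        for t in ied_times:
            for tau in range(1, 25):
                seg = x[int((t - tau) * FS) : int((t - tau + 1) * FS)]
                logs.append(np.log(seg.var()))
                taus.append(-tau + 0.5)
        slope = np.polyfit(taus, logs, 1)[0]
        assert slope == pytest.approx(0.05, abs=0.015)


class TestSpikeTrains:
    def test_no_suppression_is_homogeneous_poisson(self):
        trains = generate_spike_trains(600.0, [], 1, (10.0, 10.0), 0.0, seed=0)
        isi = np.diff(trains[0].spike_times_s)
        # KS against the fitted exponential
        stat, p = stats.kstest(isi, "expon", args=(0, isi.mean()))
        assert p > 0.01

    def test_count_within_poisson_bound(self):
        trains = generate_spike_trains(600.0, [], 1, (10.0, 10.0), 0.0, seed=1)
        n = len(trains[0].spike_times_s)
        assert abs(n - 6000) < 3 * np.sqrt(6000)

    def test_full_suppression_empties_spans(self):
        spans = [(10.0, 10.5), (20.0, 20.4)]
        trains = generate_spike_trains(60.0, spans, 2, (20.0, 20.0), 1.0, seed=2)
        for tr in trains:
            for a, b in spans:
                assert not np.any((tr.spike_times_s >= a) & (tr.spike_times_s <= b))

    def test_partial_suppression_rate_ratio(self):
        spans = [(t, t + 0.5) for t in np.arange(1.0, 599.0, 2.0)]
        trains = generate_spike_trains(600.0, spans, 1, (20.0, 20.0), 0.3, seed=3)
        t = trains[0].spike_times_s
        in_count = sum(np.sum((t >= a) & (t < b)) for a, b in spans)
        in_time = sum(b - a for a, b in spans)
        out_rate = (t.size - in_count) / (600.0 - in_time)
        assert in_count / in_time / out_rate == pytest.approx(0.7, abs=0.07)


class TestTrials:
    def _mk(self, b, seed, n=120, lows_rate=0.3):
        cfg = TrialsConfig(n_encoding=0, n_retrieval=n, rt_slope_s2=b, rt_sd_s=0.2)
        rng = np.random.default_rng(seed)
        lows = np.sort(rng.uniform(0, 1500.0, int(1500 * lows_rate)))
        return generate_trials(cfg, lows, np.array([]), 1500.0, seed), lows

    @pytest.mark.parametrize("b", [0.0, 0.56])
    def test_slope_recovery(self, b):
        import statsmodels.api as sm

        trials, lows = self._mk(b, seed=4)
        rates = []
        for r in trials.itertuples():
            rates.append(np.sum((lows >= r.onset) & (lows < r.onset + r.duration))
                         / r.duration)
        ols = sm.OLS(trials["rt"], sm.add_constant(np.asarray(rates))).fit()
        est, se = ols.params.iloc[1], ols.bse.iloc[1]
        assert abs(est - b) < 2 * se

    def test_fixed_seed_reproducible(self):
        t1, _ = self._mk(0.5, seed=5)
        t2, _ = self._mk(0.5, seed=5)
        assert t1.equals(t2)

    def test_too_short_recording_errors(self):
        cfg = TrialsConfig()
        with pytest.raises(ValueError, match="too short"):
            generate_trials(cfg, np.array([]), np.array([]), 60.0, 0)


class TestFullDataset:
    def test_truth_counts_match_planted_rows(self, small_dataset):
        ds = small_dataset
        kinds = {e.kind for e in ds.truth}
        assert kinds == {"IED", "nSW", "pSW"}
        # every planted wave satisfies the event-type invariants
        for e in ds.truth.of_kind("nSW", "pSW"):
            assert e.onset_s < e.trough_s < e.zc2_s
            assert 0.25 <= e.zc2_s - e.onset_s <= 1.0
            assert 0.5 <= e.freq_hz <= 2.0

    def test_planted_sw_avoid_post_ied_second(self, small_dataset):
        ds = small_dataset
        ied = np.sort(ds.truth.of_kind("IED").times())
        for e in ds.truth.of_kind("nSW", "pSW"):
            j = np.searchsorted(ied, e.onset_s)
            if j > 0:
                assert e.onset_s - ied[j - 1] > 1.0

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        from lowsuite.core import write_events

        cfg = SynthConfig(duration_s=420.0, seed=42)
        for name in ("a", "b"):
            ds = generate_dataset(cfg)
            write_events(ds.truth, tmp_path / f"{name}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_planted_count_poisson_bound(self):
        cfg = SynthConfig(duration_s=1800.0, seed=9, n_channels=1,
                          sw=SWConfig(rate_per_s=0.06, p_train=0.0),
                          ied=IEDConfig(rate_per_s=0.0))
        ds = generate_dataset(cfg)
        n = len(ds.truth.of_kind("nSW", "pSW"))
        assert abs(n - 108) < 3 * np.sqrt(108)

    def test_invalid_config_lists_fields(self):
        with pytest.raises(ValueError, match="downstate_suppression"):
            SynthConfig(hg=__import__("lowsuite.synth", fromlist=["HGConfig"])
                        .HGConfig(downstate_suppression=1.5))
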