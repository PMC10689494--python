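"""Synthetic iEEG generator with planted ground truth.

Emulates the statistical structure every downstream stage assumes: a wake-like
LFP background (power-law broadband plus a fast-delta/low-theta band and an
alpha rhythm), isolated half-wave slow events of both polarities (optionally
3-half-wave trains), sharp interictal discharges with after-waves, a
high-gamma carrier suppressed inside slow-wave spans and ramping before
discharges, Poisson unit spiking suppressed at slow-wave troughs, and
encoding/retrieval trials whose reaction time depends linearly on the
within-trial slow-wave rate.

The default configuration is the committed calibrated wakefulness scenario:
its background spectral mixture is tuned (once) so that planted half-waves
make up ~10% of duration-valid 0.5-4 Hz candidates per channel and polarity,
i.e. they dominate the top amplitude decile that the percentile gate retains,
reproducing the detected-rate regime of awake hippocampal recordings
(~0.06 waves / s / electrode, ~0.01 discharges / s / electrode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import ChannelInfo, Event, EventTable, Recording, SpikeTrain

import pandas as pd


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class BackgroundConfig:
    """Wake LFP background. ``alpha`` is the power-law exponent of the
    broadband component; the theta and alpha-rhythm terms add band-limited
    noise (rms in uV) emulating wake hippocampal spectra."""

    alpha: float = 1.0
    rms_uV: float = 20.0
    highpass_hz: float = 0.15  # hardware-like acquisition high-pass
    theta_band: tuple[float, float] = (3.0, 6.0)
    theta_rms_uV: float = 17.5
    alpha_freq_hz: float = 9.7
    alpha_rms_uV: float = 6.0


@dataclass
class SWConfig:
    """Planted slow waves. ``rate_per_s`` counts wave *events* per channel;
    an event is a single half-wave or, with probability ``p_train``, a train
    of three alternating half-waves."""

    rate_per_s: float = 0.108
    amplitude_uV: tuple[float, float] = (150.0, 25.0)  # mean, sd
    half_duration_s: tuple[float, float] = (0.385, 0.08)  # mean, sd; trunc [0.25, 1]
    p_train: float = 0.1
    polarity_mix: float = 0.5  # probability a single event is positive-LFP (nSW)
    min_gap_s: float = 2.5  # dead time between events, keeps plants isolated
    amplitude_drift_per_s: float = 0.0  # fractional amplitude gain per s toward next IED
    slope_drift_per_s: float = 0.0  # extra fractional slope gain (duration shrink)


@dataclass
class IEDConfig:
    rate_per_s: float = 0.01
    amplitude_uV: float = 220.0  # sharp peak, ~8x the composite background rms
    sharp_width_s: float = 0.05
    afterwave_amplitude_uV: float = 40.0
    afterwave_duration_s: float = 0.5
    min_gap_s: float = 2.0


@dataclass
class HGConfig:
    band: tuple[float, float] = (45.0, 130.0)
    carrier_rms_uV: float = 5.0
    downstate_suppression: float = 0.5  # envelope factor (1 - s) inside SW spans
    preied_ramp: float = 0.015  # log(uV^2) per s build-up before each IED
    preied_window_s: float = 60.0
    delay_gain: float = 2e-3  # log(uV^2) per s of delay since last SW, at IEDs
    ied_window_s: float = 0.05


@dataclass
class UnitsConfig:
    n_units: int = 3
    base_rate_hz: tuple[float, float] = (3.0, 8.0)  # uniform range
    downstate_suppression: float = 0.3


@dataclass
class TrialsConfig:
    n_encoding: int = 27
    n_retrieval: int = 27
    encoding_duration_s: float = 6.0
    retrieval_duration_s: tuple[float, float] = (2.0, 6.0)  # uniform range
    rt_intercept_s: float = 1.5
    rt_slope_s2: float = 0.56  # s of extra RT per unit LoWS rate (s^-1)
    rt_sd_s: float = 0.3
    accuracy_base_p: float = 0.85
    accuracy_ied_weight: float = 5.0  # P(high) = clip(base - w * ied_rate, .05, .95)


@dataclass
class SynthConfig:
    duration_s: float = 3600.0
    fs: float = 512.0
    n_channels: int = 3
    regions: tuple[str, ...] = ()  # default: all hippocampus
    patient_id: str = "p0"
    seed: int = 0
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    sw: SWConfig = field(default_factory=SWConfig)
    ied: IEDConfig = field(default_factory=IEDConfig)
    hg: HGConfig = field(default_factory=HGConfig)
    units: UnitsConfig = field(default_factory=UnitsConfig)
    trials: TrialsConfig = field(default_factory=TrialsConfig)

    def __post_init__(self) -> None:
        errors = []
        if self.duration_s <= 0 or self.fs <= 0 or self.n_channels < 1:
            errors.append("duration_s, fs and n_channels must be positive")
        if not 0 <= self.background.alpha <= 2:
            errors.append("background.alpha must lie in [0, 2]")
        for name, rate in [("sw.rate_per_s", self.sw.rate_per_s),
                           ("ied.rate_per_s", self.ied.rate_per_s)]:
            if rate < 0:
                errors.append(f"{name} must be >= 0")
        for name, s in [("hg.downstate_suppression", self.hg.downstate_suppression),
                        ("units.downstate_suppression", self.units.downstate_suppression)]:
            if not 0 <= s <= 1:
                errors.append(f"{name} must lie in [0, 1]")
        if self.trials.rt_sd_s <= 0:
            errors.append("trials.rt_sd_s must be > 0")
        if errors:
            raise ValueError("invalid SynthConfig: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key, sub in [("background", BackgroundConfig), ("sw", SWConfig),
                         ("ied", IEDConfig), ("hg", HGConfig),
                         ("units", UnitsConfig), ("trials", TrialsConfig)]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d[key].items()})
        if "regions" in d and isinstance(d["regions"], list):
            d["regions"] = tuple(d["regions"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Elementary signal generators
# ---------------------------------------------------------------------------

def generate_background(
    duration_s: float,
    fs: float,
    alpha: float,
    rms: float,
    seed: int | np.random.Generator,
    highpass_hz: float = 0.15,
) -> np.ndarray:
    """One channel of 1/f^alpha noise at the requested rms (spectral synthesis)."""
    if not 0 <= alpha <= 2:
        raise ValueError("alpha must lie in [0, 2]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-alpha / 2.0)
    if highpass_hz > 0:
        shape[nz] *= f[nz] / np.sqrt(f[nz] ** 2 + highpass_hz**2)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def narrowband_noise(
    duration_s: float,
    fs: float,
    band: tuple[float, float],
    rms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise at the requested rms."""
    n = int(round(duration_s * fs))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def synth_slow_wave(
    half_duration_s: float, amplitude_uV: float, polarity: int, fs: float
) -> np.ndarray:
    """A single half-sine half-wave: two zero-crossings ``half_duration`` apart,
    signed peak ``polarity * |amplitude|`` at the midpoint."""
    if not 0.25 <= half_duration_s <= 1.0:
        raise ValueError("half_duration must lie in [0.25, 1] s")
    n = int(round(half_duration_s * fs))
    t = np.arange(n) / fs
    return np.sign(polarity) * abs(amplitude_uV) * np.sin(np.pi * t / half_duration_s)


def synth_ied(
    fs: float,
    amplitude_uV: float,
    sharp_width_s: float = 0.05,
    afterwave_amplitude_uV: float = 0.0,
    afterwave_duration_s: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Sharp biphasic transient (Ricker kernel, energy near 50 Hz) followed by
    a slow after-wave of opposite sign. Returns ``(waveform, peak_index)``."""
    if sharp_width_s > 0.1:
        raise ValueError("sharp_width must be <= 0.1 s")
    a = sharp_width_s / 8.0  # Ricker scale; support ~ +/- 4a
    half = int(round(4 * a * fs))
    t = np.arange(-half, half + 1) / fs
    sharp = (1 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))
    sharp = sharp / np.max(np.abs(sharp)) * amplitude_uV
    if afterwave_amplitude_uV > 0:
        n_aw = int(round(afterwave_duration_s * fs))
        taw = np.arange(n_aw) / fs
        aw = -np.sign(amplitude_uV) * afterwave_amplitude_uV * np.sin(
            np.pi * taw / afterwave_duration_s
        )
        wave = np.concatenate([sharp, aw])
    else:
        wave = sharp
    return wave, half


def generate_hg_carrier(
    duration_s: float,
    fs: float,
    band: tuple[float, float],
    rms: float,
    sw_spans: Sequence[tuple[float, float]],
    ied_times: Sequence[float],
    rng: np.random.Generator,
    downstate_suppression: float = 0.0,
    preied_ramp: float = 0.0,
    preied_window_s: float = 60.0,
    delay_gain: float = 0.0,
    sw_troughs: Sequence[float] = (),
    ied_window_s: float = 0.05,
) -> np.ndarray:
    """Band-limited high-gamma carrier with planted modulations.

    The envelope is multiplied by ``1 - suppression`` inside each slow-wave
    span; log-power ramps linearly up to each discharge over the
    ``preied_window_s`` preceding it; and the ``+/- ied_window_s`` around each
    discharge is scaled by ``exp(delay_gain * delay_since_last_SW)`` in power.
    """
    if band[1] >= fs / 2:
        raise ValueError("band must lie below Nyquist")
    n = int(round(duration_s * fs))
    x = narrowband_noise(duration_s, fs, band, rms, rng)
    gain = np.ones(n)
    for a, b in sw_spans:
        i, j = int(round(a * fs)), int(round(b * fs))
        gain[max(i, 0) : min(j, n)] *= 1.0 - downstate_suppression
    if preied_ramp != 0 and len(ied_times):
        t = np.arange(n) / fs
        tied = np.sort(np.asarray(ied_times, dtype=float))
        j = np.searchsorted(tied, t)  # next IED index
        tau = np.where(j < tied.size, tied[np.clip(j, 0, tied.size - 1)] - t, np.inf)
        excess = preied_ramp * np.clip(preied_window_s - tau, 0.0, None)
        gain *= np.exp(excess / 2.0)  # half in log-amplitude = full in log-power
    if delay_gain != 0 and len(ied_times) and len(sw_troughs):
        troughs = np.sort(np.asarray(sw_troughs, dtype=float))
        for tied in ied_times:
            k = np.searchsorted(troughs, tied)
            if k == 0:
                continue
            delay = tied - troughs[k - 1]
            i = max(int(round((tied - ied_window_s) * fs)), 0)
            j = min(int(round((tied + ied_window_s) * fs)), n)
            gain[i:j] *= np.exp(delay_gain * delay / 2.0)
    return x * gain


def generate_spike_trains(
    duration_s: float,
    sw_spans: Sequence[tuple[float, float]],
    n_units: int,
    base_rate_range: tuple[float, float],
    downstate_suppression: float,
    seed: int | np.random.Generator,
    patient_id: str = "p0",
) -> list[SpikeTrain]:
    """Inhomogeneous Poisson trains, thinned by ``1 - suppression`` inside
    slow-wave spans."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spans = np.asarray(sorted(sw_spans), dtype=float).reshape(-1, 2)
    trains = []
    for u in range(n_units):
        r0 = rng.uniform(*base_rate_range)
        if r0 <= 0:
            raise ValueError("base rates must be positive")
        n = rng.poisson(r0 * duration_s)
        t = np.sort(rng.uniform(0, duration_s, n))
        if spans.size and downstate_suppression > 0:
            j = np.searchsorted(spans[:, 0], t) - 1
            inside = (j >= 0) & (t <= spans[np.clip(j, 0, None), 1])
            keep = ~inside | (rng.random(t.size) >= downstate_suppression)
            t = t[keep]
        trains.append(SpikeTrain(f"u{u}", t, duration_s, patient_id))
    return trains


def generate_trials(
    cfg: TrialsConfig,
    lows_times: np.ndarray,
    ied_times: np.ndarray,
    duration_s: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Encoding/retrieval trial table with planted RT model.

    ``rt = a + b * (LoWS rate within the trial) + N(0, sd)`` for retrieval
    trials; accuracy is high with probability decreasing in the within-trial
    discharge rate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lows_times = np.sort(np.asarray(lows_times, dtype=float))
    ied_times = np.sort(np.asarray(ied_times, dtype=float))
    n_total = cfg.n_encoding + cfg.n_retrieval
    gap = 2.0
    rows = []
    t = 5.0
    order = ["encoding"] * cfg.n_encoding + ["retrieval"] * cfg.n_retrieval
    for phase in order:
        dur = (
            cfg.encoding_duration_s
            if phase == "encoding"
            else rng.uniform(*cfg.retrieval_duration_s)
        )
        if t + dur > duration_s - 5.0:
            raise ValueError(
                f"recording too short for {n_total} trials (need ~{t + dur + 5:.0f} s)"
            )
        sw_rate = np.searchsorted(lows_times, t + dur) - np.searchsorted(lows_times, t)
        sw_rate /= dur
        ied_rate = np.searchsorted(ied_times, t + dur) - np.searchsorted(ied_times, t)
        ied_rate /= dur
        rt = np.nan
        if phase == "retrieval":
            rt = cfg.rt_intercept_s + cfg.rt_slope_s2 * sw_rate + rng.normal(0, cfg.rt_sd_s)
            rt = max(rt, 0.05)
        p_high = np.clip(cfg.accuracy_base_p - cfg.accuracy_ied_weight * ied_rate, 0.05, 0.95)
        acc = "high" if rng.random() < p_high else "low"
        rows.append({"phase": phase, "onset": t, "duration": dur, "rt": rt, "accuracy": acc})
        t += dur + gap
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Event-time processes
# ---------------------------------------------------------------------------

def _renewal_times(
    rate: float, duration: float, dead_time: float, rng: np.random.Generator,
    t_margin: float = 5.0,
) -> np.ndarray:
    """Poisson-like renewal process with a hard dead time, matching ``rate``
    on average; events keep ``t_margin`` clear of both recording edges."""
    if rate <= 0:
        return np.array([])
    mean_gap = 1.0 / rate
    if mean_gap <= dead_time:
        raise ValueError("rate too high for the configured dead time")
    exp_scale = mean_gap - dead_time
    out = []
    t = t_margin + rng.exponential(exp_scale)
    while t < duration - t_margin:
        out.append(t)
        t += dead_time + rng.exponential(exp_scale)
    return np.array(out)


def _truncnorm(mean, sd, lo, hi, rng, size=None):
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = (x < lo) | (x > hi)
    return x


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SynthDataset:
    recording: Recording
    truth: EventTable  # planted IED / nSW / pSW events
    spikes: list[SpikeTrain]
    trials: pd.DataFrame
    config: SynthConfig


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Compose LFP = background + planted slow waves + discharges + HG carrier
    per channel, with ground truth tables.

    Slow-wave events are thinned so that none starts within 1 s after (or
    1.5 s before) a same-region discharge, so that planted truth matches the
    detector's exclusion semantics.
    """
    cfg = config
    rng_root = np.random.SeedSequence(cfg.seed)
    (ss_bg, ss_events, ss_hg, ss_units, ss_trials) = rng_root.spawn(5)
    n = int(round(cfg.duration_s * cfg.fs))
    fs = cfg.fs
    regions = cfg.regions or tuple(["hippocampus"] * cfg.n_channels)
    if len(regions) != cfg.n_channels:
        raise ValueError("regions must have one entry per channel")
    channels = [ChannelInfo(f"ch{i}", regions[i], i) for i in range(cfg.n_channels)]

    rng_ev = np.random.default_rng(ss_events)
    # discharges first: they veto subsequent slow waves in the same region
    ied_times = {
        ch.label: _renewal_times(cfg.ied.rate_per_s, cfg.duration_s,
                                 cfg.ied.min_gap_s, rng_ev)
        for ch in channels
    }
    region_ied = {
        r: np.sort(np.concatenate([ied_times[c.label] for c in channels if c.region == r]))
        if any(c.region == r for c in channels) else np.array([])
        for r in set(regions)
    }

    truth_events: list[Event] = []
    samples = np.empty((cfg.n_channels, n))
    bg_rng = np.random.default_rng(ss_bg)
    hg_rng = np.random.default_rng(ss_hg)
    sw_spans_by_channel: dict[str, list[tuple[float, float]]] = {}

    for ch in channels:
        x = generate_background(cfg.duration_s, fs, cfg.background.alpha,
                                cfg.background.rms_uV, bg_rng,
                                highpass_hz=cfg.background.highpass_hz)
        if cfg.background.theta_rms_uV > 0:
            x = x + narrowband_noise(cfg.duration_s, fs, cfg.background.theta_band,
                                     cfg.background.theta_rms_uV, bg_rng)
        if cfg.background.alpha_rms_uV > 0:
            f0 = cfg.background.alpha_freq_hz
            x = x + narrowband_noise(cfg.duration_s, fs, (f0 - 0.6, f0 + 0.6),
                                     cfg.background.alpha_rms_uV, bg_rng)

        # --- slow-wave events, vetoed near same-region discharges
        ev_times = _renewal_times(cfg.sw.rate_per_s, cfg.duration_s,
                                  cfg.sw.min_gap_s, rng_ev)
        veto = region_ied[ch.region]
        if veto.size:
            j = np.searchsorted(veto, ev_times)
            after = np.where(j > 0, ev_times - veto[np.clip(j - 1, 0, None)], np.inf)
            before = np.where(j < veto.size, veto[np.clip(j, 0, veto.size - 1)] - ev_times,
                              np.inf)
            ev_times = ev_times[(after > 1.0 + cfg.sw.min_gap_s) & (before > 1.5)]
        next_ied = np.full(ev_times.shape, np.inf)
        if veto.size:
            j = np.searchsorted(veto, ev_times)
            next_ied[j < veto.size] = veto[j[j < veto.size]]

        spans: list[tuple[float, float]] = []
        for t0, t_next in zip(ev_times, next_ied):
            n_half = 3 if rng_ev.random() < cfg.sw.p_train else 1
            pol = 1 if rng_ev.random() < cfg.sw.polarity_mix else -1
            t = t0
            for k in range(n_half):
                d = float(_truncnorm(*cfg.sw.half_duration_s, 0.25, 1.0, rng_ev))
                amp = float(_truncnorm(*cfg.sw.amplitude_uV,
                                       1.0, 10.0 * cfg.sw.amplitude_uV[0], rng_ev))
                if np.isfinite(t_next):
                    tti = max(t_next - t, 0.0)  # time to next discharge
                    amp *= max(1.0 + cfg.sw.amplitude_drift_per_s * (-tti), 0.05)
                    if cfg.sw.slope_drift_per_s:
                        d = float(np.clip(d / max(1.0 + cfg.sw.slope_drift_per_s * (-tti),
                                                  0.05), 0.25, 1.0))
                wave = synth_slow_wave(d, amp, pol, fs)
                i0 = int(round(t * fs))
                if i0 + wave.size > n:
                    break
                x[i0 : i0 + wave.size] += wave
                truth_events.append(
                    Event(
                        kind="nSW" if pol > 0 else "pSW",
                        channel=ch.label,
                        onset_s=t,
                        trough_s=t + d / 2.0,
                        zc2_s=t + d,
                        amplitude_uV=pol * amp,
                        slope_uV_per_s=pol * amp / (d / 2.0),
                        freq_hz=1.0 / (2.0 * d),
                    )
                )
                spans.append((t, t + d))
                t += d
                pol = -pol
        sw_spans_by_channel[ch.label] = spans

        # --- discharges
        troughs = np.sort([s[0] + (s[1] - s[0]) / 2 for s in spans])
        for tied in ied_times[ch.label]:
            amp = cfg.ied.amplitude_uV
            if cfg.hg.delay_gain:
                k = np.searchsorted(troughs, tied)
                if k > 0:
                    amp = amp * float(
                        np.exp(cfg.hg.delay_gain * (tied - troughs[k - 1]) / 2.0)
                    )
            wave, peak = synth_ied(fs, amp, cfg.ied.sharp_width_s,
                                   cfg.ied.afterwave_amplitude_uV,
                                   cfg.ied.afterwave_duration_s)
            i0 = int(round(tied * fs)) - peak
            if i0 < 0 or i0 + wave.size > n:
                continue
            x[i0 : i0 + wave.size] += wave
            truth_events.append(
                Event(kind="IED", channel=ch.label, onset_s=tied, trough_s=tied,
                      amplitude_uV=amp)
            )

        # --- high-gamma carrier
        if cfg.hg.carrier_rms_uV > 0:
            x = x + generate_hg_carrier(
                cfg.duration_s, fs, cfg.hg.band, cfg.hg.carrier_rms_uV,
                spans, ied_times[ch.label], hg_rng,
                downstate_suppression=cfg.hg.downstate_suppression,
                preied_ramp=cfg.hg.preied_ramp,
                preied_window_s=cfg.hg.preied_window_s,
                delay_gain=cfg.hg.delay_gain,
                sw_troughs=troughs,
                ied_window_s=cfg.hg.ied_window_s,
            )
        samples[ch.index] = x

    recording = Recording(samples=samples, fs=fs, channels=channels,
                          patient_id=cfg.patient_id)
    truth = EventTable(truth_events, cfg.duration_s, cfg.patient_id)

    # spikes follow the slow waves of the first channel (microwire site)
    first = channels[0].label
    spikes = generate_spike_trains(
        cfg.duration_s, sw_spans_by_channel[first], cfg.units.n_units,
        cfg.units.base_rate_hz, cfg.units.downstate_suppression,
        np.random.default_rng(ss_units), cfg.patient_id,
    )

    nsw_first = np.sort([e.trough_s for e in truth
                         if e.kind == "nSW" and e.channel == first])
    trials = generate_trials(cfg.trials, nsw_first, ied_times[first],
                             cfg.duration_s, np.random.default_rng(ss_trials))
    return SynthDataset(recording, truth, spikes, trials, cfg)
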