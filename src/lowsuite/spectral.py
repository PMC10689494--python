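"""Spectral estimation: Welch band power, event-locked multitaper high-gamma
power, Morlet time-frequency maps with baseline correction and t-statistic
conversion, control event times and alpha peak frequency.

Power is reported in variance units (uV^2): the band power of band-limited
noise of variance sigma^2 is ~sigma^2. Natural log is used wherever power is
log-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

logger = logging.getLogger(__name__)

HG_BAND = (45.0, 130.0)
#: Default multitaper half-bandwidth (Hz); wide because down-state windows
#: are short (<= 0.315 s).
HG_HALF_BANDWIDTH = 10.0


def welch_band_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    segment_s: float = 4.0,
    log: bool = True,
) -> float:
    """Mean Welch PSD over ``band`` (natural log by default).

    Hamming segments of ``segment_s`` with 50% overlap.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8 * fs:
        raise ValueError("welch_band_power requires >= 8 s of signal")
    if not 0 <= band[0] < band[1] <= fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist)")
    nper = int(round(segment_s * fs))
    f, p = sps.welch(x, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2)
    sel = (f >= band[0]) & (f <= band[1])
    power = float(p[sel].mean())
    return float(np.log(power)) if log else power


def welch_psd(
    x: np.ndarray, fs: float, segment_s: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    nper = int(round(segment_s * fs))
    return sps.welch(x, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2)


def multitaper_band_power(
    epochs: np.ndarray,
    fs: float,
    band: tuple[float, float] = HG_BAND,
    half_bandwidth: float = HG_HALF_BANDWIDTH,
) -> np.ndarray:
    """Per-epoch DPSS multitaper power integrated over ``band`` (uV^2)."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_t = epochs.shape[1]
    nw = max(n_t / fs * half_bandwidth, 1.0)
    k = max(int(2 * nw - 1), 1)
    tapers = sps.windows.dpss(n_t, nw, Kmax=k)  # each taper has unit energy
    if tapers.ndim == 1:
        tapers = tapers[None, :]
    spec = np.fft.rfft(epochs[:, None, :] * tapers[None, :, :], axis=-1)
    f = np.fft.rfftfreq(n_t, 1.0 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} has no frequency bins at this window length")
    # |FFT|^2 with unit-energy tapers estimates S(f) * fs (two-sided);
    # integrating one-sided over the band: sum 2 |FFT|^2 / n_t.
    psd = (np.abs(spec) ** 2).mean(axis=1)
    return 2.0 * psd[:, sel].sum(axis=1) / n_t


def hg_power(
    epochs: np.ndarray,
    fs: float,
    window: tuple[float, float],
    epoch_tmin: float | None = None,
    band: tuple[float, float] = HG_BAND,
    half_bandwidth: float = HG_HALF_BANDWIDTH,
) -> np.ndarray:
    """Multitaper high-gamma power of each epoch in a sub-window.

    ``window`` is in seconds relative to the event; ``epoch_tmin`` gives the
    time of the first epoch column (default: epochs centred on the event).
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_t = epochs.shape[1]
    if epoch_tmin is None:
        epoch_tmin = -n_t / fs / 2.0
    t0, t1 = window
    if t1 - t0 < 2.0 / band[0]:
        raise ValueError(f"window shorter than 2 cycles of {band[0]} Hz")
    i0 = int(round((t0 - epoch_tmin) * fs))
    i1 = int(round((t1 - epoch_tmin) * fs))
    if i0 < 0 or i1 > n_t:
        raise ValueError("window outside epoch")
    return multitaper_band_power(epochs[:, i0:i1], fs, band, half_bandwidth)


def baseline_correct(
    values: np.ndarray, baseline_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Relative change: per-event value / mean baseline value.

    Returns ``(normalized, kept_mask)``; events with non-positive baseline
    are dropped and logged.
    """
    values = np.asarray(values, dtype=float)
    baseline = np.asarray(baseline_values, dtype=float)
    keep = baseline > 0
    if not keep.all():
        logger.warning("baseline_correct: dropped %d events with zero baseline",
                       int((~keep).sum()))
    return values[keep] / baseline[keep], keep


@dataclass
class TFRMap:
    """Event-locked time-frequency decomposition.

    power : events x freqs x times, uV^2
    tstat : freqs x times one-sample t of log relative power across events
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    tstat: np.ndarray | None = None


def tfr_morlet(
    epochs: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
    epoch_tmin: float | None = None,
    baseline: tuple[tuple[float, float], tuple[float, float]] | None = (
        (-2.9, -0.2),
        (0.2, 2.9),
    ),
    compute_tstat: bool = True,
) -> TFRMap:
    """Seven-cycle Morlet power per event, optionally converted to a
    t-statistic map of log baseline-corrected power across events."""
    from mne.time_frequency import tfr_array_morlet

    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_ev, n_t = epochs.shape
    if freqs is None:
        freqs = np.geomspace(1.5, 130.0, 40)
    freqs = np.asarray(freqs, dtype=float)
    if epoch_tmin is None:
        epoch_tmin = -n_t / fs / 2.0
    times = epoch_tmin + np.arange(n_t) / fs
    min_len = int(np.ceil(n_cycles / freqs.min() * fs))
    pad = 0
    if n_t < min_len:
        pad = (min_len - n_t) // 2 + 1
        logger.warning("tfr_morlet: edge-padding epochs by %d samples", pad)
        epochs = np.pad(epochs, ((0, 0), (pad, pad)), mode="reflect")
    power = tfr_array_morlet(
        epochs[:, None, :], sfreq=fs, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=True,
    )[:, 0]
    if pad:
        power = power[:, :, pad : pad + n_t]
    tstat = None
    if compute_tstat:
        if n_ev < 2:
            raise ValueError("t-statistic undefined for < 2 events")
        if baseline is not None:
            base_mask = np.zeros(n_t, dtype=bool)
            for a, b in baseline:
                base_mask |= (times >= a) & (times <= b)
            if not base_mask.any():
                raise ValueError("baseline windows outside epoch")
            ref = power[:, :, base_mask].mean(axis=2, keepdims=True)
            if np.any(ref <= 0):
                raise ValueError("non-positive baseline power")
            rel = np.log(power / ref)
        else:
            rel = np.log(np.maximum(power, 1e-300))
        sd = rel.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero across-event variance; t-statistic undefined")
        tstat = rel.mean(axis=0) / (sd / np.sqrt(n_ev))
    return TFRMap(times=times, freqs=freqs, power=power, tstat=tstat)


def morlet_band_variance(tf: TFRMap, band: tuple[float, float]) -> float:
    """Band-integrated signal variance (uV^2) from a Morlet map.

    With MNE's wavelet normalization the frequency-integrated mean power
    divided by the sampling rate estimates the one-sided PSD integral, i.e.
    the variance of the band-limited signal (the wavelet gain and its noise
    bandwidth cancel exactly). Frequencies in ``tf.freqs`` must cover the
    band densely relative to the wavelet bandwidth (f / n_cycles).
    """
    sel = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    if sel.sum() < 2:
        raise ValueError("need >= 2 frequency samples inside the band")
    mean_p = tf.power.mean(axis=(0, 2))
    df_int = np.trapezoid(mean_p[sel], tf.freqs[sel])
    fs = 1.0 / (tf.times[1] - tf.times[0])
    return float(df_int / fs)


def control_event_times(
    duration_s: float,
    n: int,
    exclusions: Sequence[tuple[float, float]] = (),
    seed: int | np.random.Generator = 0,
    margin_s: float = 3.0,
) -> np.ndarray:
    """Uniform random time bins over admissible (non-excluded) time.

    ``exclusions`` are absolute-time intervals (e.g. +/-3 s around real
    events or artifact spans); ``margin_s`` keeps draws clear of the edges.
    """
    from .core import union_spans

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = margin_s, duration_s - margin_s
    if hi <= lo:
        raise ValueError("recording shorter than twice the margin")
    merged = union_spans([(max(a, lo), min(b, hi)) for a, b in exclusions])
    segs = []
    cur = lo
    for a, b in merged:
        if a > cur:
            segs.append((cur, a))
        cur = max(cur, b)
    if cur < hi:
        segs.append((cur, hi))
    lengths = np.array([b - a for a, b in segs])
    if lengths.sum() <= 0:
        raise ValueError("no admissible time left for control events")
    starts = np.array([a for a, _ in segs])
    u = rng.uniform(0, lengths.sum(), size=n)
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    k = np.searchsorted(edges, u, side="right") - 1
    return np.sort(starts[k] + (u - edges[k]))


def alpha_peak(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float] = (7.1, 12.0)
) -> float:
    """Frequency of the PSD maximum within the alpha band (first maximum on
    ties, grid-limited resolution)."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("PSD grid does not cover the alpha band")
    return float(freqs[sel][np.argmax(psd[sel])])
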