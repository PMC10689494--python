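"""Local wake slow wave (LoWS) detection and per-wave features.

A candidate is any half-wave of the 0.5-4 Hz zero-phase filtered LFP, i.e.
the span between two consecutive zero-crossings, with a duration of 0.25 to
1 s. Candidates whose onset falls within 1 s after an IED detected in the
same region are discarded, and only candidates whose absolute extremum
exceeds the 90th percentile (nearest-rank, strict) of the surviving
candidates on the same channel and polarity are retained.

Polarity naming: the down-state wave (nSW) carries a *positive* extracellular
LFP extremum under a common reference (hyperpolarized neurons), which is the
``nsw_positive_lfp=True`` default; the flag flips the mapping for data whose
display convention is inverted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import Event, EventTable, Recording
from .ied import bandpass

logger = logging.getLogger(__name__)

SW_BAND = (0.5, 4.0)
MIN_DURATION_S = 0.25
MAX_DURATION_S = 1.0
POST_IED_HORIZON_S = 1.0
AMPLITUDE_PERCENTILE = 90.0
MIN_GROUP_CANDIDATES = 10

_CAND_COLUMNS = ["onset", "trough", "zc2", "amplitude", "duration", "polarity"]


def filter_sw(x: np.ndarray, fs: float) -> np.ndarray:
    return bandpass(x, fs, *SW_BAND)


def candidate_halfwaves(
    x: np.ndarray, fs: float, filtered: np.ndarray | None = None
) -> pd.DataFrame:
    """All duration-valid half-waves of the 0.5-4 Hz filtered signal.

    Returns a frame with columns onset, trough, zc2 (s), amplitude (signed
    extremum, uV), duration (s) and polarity (+1/-1). Zero-crossing times are
    the first sample of the new sign.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    xf = filter_sw(x, fs) if filtered is None else filtered
    sign = np.where(xf >= 0, 1, -1)
    zc = np.flatnonzero(np.diff(sign) != 0) + 1  # first sample after crossing
    rows = []
    for a, b in zip(zc[:-1], zc[1:]):
        d = (b - a) / fs
        if not MIN_DURATION_S <= d <= MAX_DURATION_S:
            continue
        seg = xf[a:b]
        k = int(np.argmax(np.abs(seg)))
        rows.append(
            {
                "onset": a / fs,
                "trough": (a + k) / fs,
                "zc2": b / fs,
                "amplitude": float(seg[k]),
                "duration": d,
                "polarity": 1 if seg[k] >= 0 else -1,
            }
        )
    return pd.DataFrame(rows, columns=_CAND_COLUMNS)


def exclude_post_ied(
    candidates: pd.DataFrame,
    ied_times: np.ndarray,
    horizon: float = POST_IED_HORIZON_S,
) -> pd.DataFrame:
    """Drop candidates whose onset lies in ``(t_ied, t_ied + horizon]``.

    ``ied_times`` must already be scoped to the relevant region: a discharge
    on any contact of the same region vetoes the following second.
    """
    if candidates.empty or len(ied_times) == 0:
        return candidates
    t = np.sort(np.asarray(ied_times, dtype=float))
    onset = candidates["onset"].to_numpy()
    j = np.searchsorted(t, onset) - 1  # latest IED at or before onset
    prev = np.where(j >= 0, t[np.clip(j, 0, None)], -np.inf)
    drop = (onset > prev) & (onset <= prev + horizon)
    return candidates.loc[~drop].reset_index(drop=True)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ``ceil(p/100 * N)``-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty input")
    rank = int(np.ceil(percentile / 100.0 * v.size))
    return v[max(rank, 1) - 1]


def amplitude_gate(
    candidates: pd.DataFrame,
    percentile: float = AMPLITUDE_PERCENTILE,
    min_candidates: int = MIN_GROUP_CANDIDATES,
) -> pd.DataFrame:
    """Retain candidates strictly above the per-polarity amplitude percentile.

    The percentile of absolute extremum amplitude is computed separately for
    each polarity of one channel's candidates, keeping negative- and
    positive-wave detection symmetric. Groups with fewer than
    ``min_candidates`` entries are skipped with a warning.
    """
    kept = []
    for pol, grp in candidates.groupby("polarity"):
        if len(grp) < min_candidates:
            logger.warning(
                "amplitude_gate: only %d candidates for polarity %+d, skipping",
                len(grp), pol,
            )
            continue
        thresh = nearest_rank_percentile(np.abs(grp["amplitude"].to_numpy()), percentile)
        kept.append(grp[np.abs(grp["amplitude"]) > thresh])
    if not kept:
        return candidates.iloc[0:0]
    return pd.concat(kept).sort_values("trough").reset_index(drop=True)


def sw_features(
    onset_s: float, zc2_s: float, polarity: int, filtered: np.ndarray, fs: float
) -> tuple[float, float, float, float]:
    """Amplitude, slope, oscillatory frequency and extremum time of one wave.

    Amplitude is the polarity-matched extremum of the 0.5-4 Hz filtered
    signal in the 1 s window after onset; slope is amplitude over the
    post-onset extremum delay; frequency is ``1 / (2 (zc2 - onset))``.
    """
    i0 = int(round(onset_s * fs))
    i1 = int(round((onset_s + 1.0) * fs)) + 1
    if i1 > filtered.size:
        raise ValueError("feature window truncated by recording end")
    seg = filtered[i0 + 1 : i1]
    k = int(np.argmax(seg)) if polarity > 0 else int(np.argmin(seg))
    amplitude = float(seg[k])
    dt = (k + 1) / fs
    slope = amplitude / dt
    freq = 1.0 / (2.0 * (zc2_s - onset_s))
    return amplitude, slope, freq, onset_s + dt


def normalize_features(events: EventTable) -> EventTable:
    """Per-patient normalization of |amplitude| and |slope| to [0, 1]."""
    if len(events) == 0:
        return events
    amps = np.abs(events.times("amplitude_uV"))
    slopes = np.abs(events.times("slope_uV_per_s"))
    amax, smax = np.nanmax(amps), np.nanmax(slopes)
    out = []
    for e, a, s in zip(events, amps, slopes):
        out.append(
            Event(
                kind=e.kind, channel=e.channel, onset_s=e.onset_s,
                trough_s=e.trough_s, zc2_s=e.zc2_s, amplitude_uV=e.amplitude_uV,
                slope_uV_per_s=e.slope_uV_per_s, freq_hz=e.freq_hz,
                norm_amplitude=a / amax if amax > 0 else np.nan,
                norm_slope=s / smax if smax > 0 else np.nan,
            )
        )
    return events.with_events(out)


def detect_slow_waves(
    recording: Recording,
    ieds: EventTable | None = None,
    percentile: float = AMPLITUDE_PERCENTILE,
    post_ied_horizon: float = POST_IED_HORIZON_S,
    nsw_positive_lfp: bool = True,
) -> EventTable:
    """Full LoWS detection on every channel of a recording.

    Pipeline per channel: 0.5-4 Hz half-wave candidates -> same-region
    post-IED exclusion -> per-polarity percentile gate -> per-wave features
    -> per-patient feature normalization. Waves whose 1 s feature window
    leaves the recording are dropped and logged.
    """
    ied_by_region: dict[str, np.ndarray] = {}
    if ieds is not None:
        for region in {c.region for c in recording.channels}:
            labs = [c.label for c in recording.channels if c.region == region]
            t = [e.trough_s for e in ieds if e.channel in labs]
            ied_by_region[region] = np.array(sorted(t))
    events: list[Event] = []
    n_trunc = 0
    for ch in recording.channels:
        xf = filter_sw(recording.samples[ch.index], recording.fs)
        cands = candidate_halfwaves(recording.samples[ch.index], recording.fs, filtered=xf)
        cands = exclude_post_ied(
            cands, ied_by_region.get(ch.region, np.array([])), horizon=post_ied_horizon
        )
        gated = amplitude_gate(cands, percentile=percentile)
        for row in gated.itertuples(index=False):
            pol = int(row.polarity)
            try:
                amp, slope, freq, t_ext = sw_features(
                    row.onset, row.zc2, pol, xf, recording.fs
                )
            except ValueError:
                n_trunc += 1
                continue
            if nsw_positive_lfp:
                kind = "nSW" if pol > 0 else "pSW"
            else:
                kind = "pSW" if pol > 0 else "nSW"
            events.append(
                Event(
                    kind=kind, channel=ch.label, onset_s=row.onset,
                    trough_s=row.trough, zc2_s=row.zc2, amplitude_uV=amp,
                    slope_uV_per_s=slope, freq_hz=freq,
                )
            )
    if n_trunc:
        logger.info("detect_slow_waves: dropped %d waves with truncated windows", n_trunc)
    table = EventTable(events, recording.duration_s, recording.patient_id)
    return normalize_features(table)


def corrected_lows_rate(lows_rate: float, ied_rate: float) -> float:
    """LoWS rate corrected for the discharge rate (their product)."""
    if lows_rate < 0 or ied_rate < 0:
        raise ValueError("rates must be non-negative")
    return lows_rate * ied_rate


def spatial_cooccurrence(
    events: EventTable,
    recording_channels: list,
    region: str,
    window: float = 0.1,
) -> float:
    """Mean fraction of other same-region contacts with a co-detected wave.

    For every wave on a contact of ``region``, the fraction of the *other*
    contacts in that region showing any wave with trough within ``+/-window``
    is computed, then averaged over waves. NaN for single-contact regions.
    """
    labels = [c.label for c in recording_channels if c.region == region]
    if len(labels) < 2:
        logger.warning("spatial_cooccurrence: region %r has <2 contacts", region)
        return np.nan
    troughs = {lab: np.sort(events.on_channel(lab).times("trough_s")) for lab in labels}
    fracs = []
    for lab in labels:
        others = [o for o in labels if o != lab]
        for t in troughs[lab]:
            hit = 0
            for o in others:
                tt = troughs[o]
                j = np.searchsorted(tt, t)
                near = []
                if j < tt.size:
                    near.append(abs(tt[j] - t))
                if j > 0:
                    near.append(abs(tt[j - 1] - t))
                if near and min(near) <= window:
                    hit += 1
            fracs.append(hit / len(others))
    return float(np.mean(fracs)) if fracs else np.nan
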