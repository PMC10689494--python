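"""Peri-stimulus time histograms between event classes with a
shuffle-bootstrap null, and the 60 s long-term discharge-rate slope test.

The null for significance is built by re-drawing the index-event times
uniformly over the admissible recording time (preserving their count), the
simplest exchangeable "shuffled position" null. Percentile p-values are
two-sided with an add-one correction, so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .inference import fdr_bh

SMOOTH_S = 0.5
SIG_BIN_S = 0.1  # 10 Hz resolution of the significance analysis
N_BOOT = 5000


def _hanning_kernel(bin_s: float, smooth_s: float = SMOOTH_S) -> np.ndarray:
    n = max(int(round(smooth_s / bin_s)), 1)
    if n % 2 == 0:
        n += 1
    k = np.hanning(n + 2)[1:-1]
    return k / k.sum()


def _binned_occurrence(
    index_times: np.ndarray, mod_times: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Sum over index events of modulated-event counts in each lag bin.

    ``index_times`` may be 1-D (one sequence) or 2-D (replicates x events);
    returns counts with shape ``(..., len(edges) - 1)``.
    """
    mod = np.sort(np.asarray(mod_times, dtype=float))
    idx = np.asarray(index_times, dtype=float)
    cum = np.searchsorted(mod, idx[..., None] + edges[None, :])
    return np.diff(cum, axis=-1).sum(axis=-2)


@dataclass
class PSTH:
    """Smoothed occurrence rate of one event class around another."""

    bin_centers: np.ndarray
    rate: np.ndarray  # modulated events / s / electrode / index event
    bin_s: float
    n_index: int

    @property
    def area(self) -> float:
        return float(self.rate.sum() * self.bin_s)


def psth(
    index_times: Sequence[float],
    mod_times: Sequence[float],
    window: tuple[float, float] = (-1.0, 1.0),
    bin_s: float = 0.02,
    smooth_s: float = SMOOTH_S,
    n_electrodes: int = 1,
) -> PSTH:
    """Occurrence rate of ``mod_times`` around each index event.

    Counts are summed over index events, converted to a rate, convolved with
    a unit-area Hanning kernel of ``smooth_s``, and normalized by the number
    of index events (and electrodes). The histogram is computed on a window
    extended by the kernel half-width so that smoothing conserves area
    inside the reported window.
    """
    index_times = np.asarray(index_times, dtype=float)
    if index_times.size == 0:
        raise ValueError("at least one index event required")
    kernel = _hanning_kernel(bin_s, smooth_s)
    pad = len(kernel) // 2
    lo = window[0] - pad * bin_s
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 2 * pad + 1)
    counts = _binned_occurrence(index_times, np.asarray(mod_times, float), edges)
    rate = counts / (index_times.size * bin_s * n_electrodes)
    sm = np.convolve(rate, kernel, mode="valid") if pad else rate
    centers = window[0] + bin_s * (np.arange(n_bins) + 0.5)
    return PSTH(bin_centers=centers, rate=sm, bin_s=bin_s, n_index=index_times.size)


@dataclass
class PSTHSignificance:
    bin_centers: np.ndarray
    observed: np.ndarray  # group-mean rate per bin
    null_mean: np.ndarray
    null_lo: np.ndarray  # 2.5 percentile
    null_hi: np.ndarray  # 97.5 percentile
    p: np.ndarray
    q: np.ndarray  # BH-FDR adjusted


def psth_significance(
    patients: Sequence[dict],
    window_of_interest: tuple[float, float] = (-1.0, 1.0),
    bin_s: float = SIG_BIN_S,
    smooth_s: float = SMOOTH_S,
    n_boot: int = N_BOOT,
    seed: int | np.random.Generator = 0,
    margin_s: float = 1.0,
) -> PSTHSignificance:
    """Shuffle-bootstrap significance of the group-mean PSTH at 10 Hz bins.

    Each patient is a dict with ``index_times``, ``mod_times`` and
    ``duration`` keys. The null re-draws each patient's index times
    uniformly over ``[margin, duration - margin]``, ``n_boot`` times; p per
    bin is the two-sided add-one percentile of the observed group mean in
    the null distribution, FDR-corrected across bins.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kernel = _hanning_kernel(bin_s, smooth_s)
    pad = len(kernel) // 2
    n_bins = int(round((window_of_interest[1] - window_of_interest[0]) / bin_s))
    lo = window_of_interest[0] - pad * bin_s
    edges = lo + bin_s * np.arange(n_bins + 2 * pad + 1)
    obs = np.zeros(n_bins)
    null = np.zeros((n_boot, n_bins))
    for pat in patients:
        idx = np.asarray(pat["index_times"], dtype=float)
        mod = np.asarray(pat["mod_times"], dtype=float)
        dur = float(pat["duration"])
        if idx.size == 0:
            raise ValueError("each patient needs at least one index event")
        if dur - 2 * margin_s <= 0:
            raise ValueError("recording shorter than twice the margin")
        scale = 1.0 / (idx.size * bin_s)
        counts = _binned_occurrence(idx, mod, edges)
        obs += np.convolve(counts * scale, kernel, mode="valid")
        draws = rng.uniform(margin_s, dur - margin_s, size=(n_boot, idx.size))
        ncounts = _binned_occurrence(draws, mod, edges) * scale
        null += sps.fftconvolve(ncounts, kernel[None, :], mode="valid", axes=1)
    obs /= len(patients)
    null /= len(patients)
    ge = (null >= obs[None, :]).sum(axis=0)
    le = (null <= obs[None, :]).sum(axis=0)
    p = np.minimum(1.0, 2.0 * (1.0 + np.minimum(ge, le)) / (1.0 + n_boot))
    centers = window_of_interest[0] + bin_s * (np.arange(n_bins) + 0.5)
    return PSTHSignificance(
        bin_centers=centers,
        observed=obs,
        null_mean=null.mean(axis=0),
        null_lo=np.percentile(null, 2.5, axis=0),
        null_hi=np.percentile(null, 97.5, axis=0),
        p=p,
        q=fdr_bh(p),
    )


@dataclass
class LongTermSlope:
    slopes: np.ndarray  # per-patient beta, events/s per s
    mean_slope: float
    p: float  # one-sample Wilcoxon vs 0


def long_term_ied_slope(
    patients: Sequence[dict],
    horizon_s: float = 60.0,
    bin_s: float = 1.0,
) -> LongTermSlope:
    """Per-patient least-squares slope of discharge rate over the 60 s after
    each slow wave, with a group one-sample Wilcoxon signed-rank test.

    Each patient is a dict with ``sw_times`` and ``ied_times`` keys.
    """
    if len(patients) < 2:
        raise ValueError("group test requires >= 2 patients")
    slopes = []
    edges = bin_s * np.arange(int(round(horizon_s / bin_s)) + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    for pat in patients:
        sw = np.asarray(pat["sw_times"], dtype=float)
        ied = np.asarray(pat["ied_times"], dtype=float)
        if sw.size == 0 or ied.size == 0:
            raise ValueError("each patient needs >= 1 slow wave and >= 1 discharge")
        counts = _binned_occurrence(sw, ied, edges)
        rate = counts / (sw.size * bin_s)
        if np.all(rate == 0):
            slopes.append(0.0)
        else:
            slopes.append(float(np.polyfit(centers, rate, 1)[0]))
    slopes = np.asarray(slopes)
    if np.all(slopes == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(slopes)[1])
    return LongTermSlope(slopes=slopes, mean_slope=float(slopes.mean()), p=p)
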