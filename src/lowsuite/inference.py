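"""Inference: the parallel-rate-variability (PRV) index, random-intercept
mixed-model trend analyses, paired estimation statistics (effect size with
BCa confidence interval and sign-flip permutation p), multiple-comparison
corrections, behavioral linkage and discharge-validation controls.

All mixed models share one structure: a common slope across patients with a
per-patient random intercept, fit by restricted maximum likelihood; p-values
for slopes are Wald tests. "Time since the start of recording" enters the
slow-wave trend models as a fixed nuisance covariate alongside the patient
random intercept, since a fuller random-effects structure is not
identifiable from the available description of the procedure.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PRV
# ---------------------------------------------------------------------------

def prv(ied_rates: Sequence[float], sw_rates: Sequence[float]) -> float:
    """Parallel rate variability across one patient's electrodes.

    ``sum_n (ied_n / sw_n - sum(ied) / sum(sw))^2``: zero iff the
    per-electrode discharge/slow-wave rate ratios all equal the patient-wide
    ratio (exact proportionality). Electrodes with a zero slow-wave rate are
    excluded with a warning.
    """
    ied = np.asarray(ied_rates, dtype=float)
    sw = np.asarray(sw_rates, dtype=float)
    if ied.shape != sw.shape:
        raise ValueError("rate vectors must have equal length")
    keep = sw > 0
    if not keep.all():
        logger.warning("prv: excluding %d electrode(s) with zero slow-wave rate",
                       int((~keep).sum()))
    ied, sw = ied[keep], sw[keep]
    if ied.size == 0:
        raise ValueError("no electrode with a positive slow-wave rate")
    total_ratio = ied.sum() / sw.sum()
    return float(np.sum((ied / sw - total_ratio) ** 2))


def median_prv_test(prvs: Sequence[float]) -> tuple[float, float]:
    """Median PRV and one-sample Wilcoxon signed-rank p vs 0."""
    prvs = np.asarray(prvs, dtype=float)
    if prvs.size < 5:
        raise ValueError("median PRV test requires >= 5 patients")
    med = float(np.median(prvs))
    if np.all(prvs == 0):
        logger.warning("median_prv_test: all PRVs zero; p = 1 by convention")
        return med, 1.0
    return med, float(stats.wilcoxon(prvs)[1])


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def holm(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def fdr_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Paired estimation statistics
# ---------------------------------------------------------------------------

@dataclass
class EffectSize:
    """Mean paired difference with 95% BCa confidence interval and
    two-sided sign-flip permutation p."""

    mean_diff: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_diff <= self.ci_high:
            raise ValueError("CI must bracket the effect size")


_EXHAUSTIVE_MAX_N = 14


def paired_permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_resamples: int = 5000,
    seed: int | np.random.Generator = 0,
) -> EffectSize:
    """Estimation statistics for paired samples.

    The effect size is ``mean(a - b)``; the confidence interval is a BCa
    bootstrap of the paired differences; p comes from sign-flip permutation
    of the differences (exhaustive for n <= 14, else Monte Carlo with an
    add-one correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 5:
        raise ValueError("paired test requires n >= 5")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = a - b
    es = float(d.mean())
    tol = 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0)))
    if np.all(d == 0):
        return EffectSize(0.0, 0.0, 0.0, 1.0, n)
    if n <= _EXHAUSTIVE_MAX_N:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        null = signs @ d / n
        p = float(np.mean(np.abs(null) >= abs(es) - tol))
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
        null = signs @ d / n
        p = float((1 + np.sum(np.abs(null) >= abs(es) - tol)) / (1 + n_resamples))
    if np.all(d == d[0]):
        ci_lo = ci_hi = es
    else:
        res = stats.bootstrap(
            (d,), np.mean, confidence_level=0.95, n_resamples=n_resamples,
            method="BCa", random_state=np.random.default_rng(rng.integers(2**31)),
        )
        ci_lo, ci_hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        if not np.isfinite(ci_lo) or not np.isfinite(ci_hi):
            ci_lo = ci_hi = es
        ci_lo, ci_hi = min(ci_lo, es), max(ci_hi, es)
    return EffectSize(es, ci_lo, ci_hi, min(p, 1.0), n)


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Common-slope, random-intercept mixed model fit."""

    beta: float
    sem: float
    p: float
    intercept: float
    n_groups: int
    n_obs: int
    converged: bool
    covariate_betas: dict = field(default_factory=dict)


def fit_lmm(
    y: Sequence[float],
    x: Sequence[float],
    group: Sequence,
    covariates: dict[str, Sequence[float]] | None = None,
) -> LMMFit:
    """REML fit of ``y = beta x + gamma covariates + u_group + eps`` with a
    per-group random intercept; Wald p for beta."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    group = np.asarray(group)
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant; slope not identifiable")
    groups, counts = np.unique(group, return_counts=True)
    if groups.size < 2:
        raise ValueError("mixed model requires >= 2 groups")
    if counts.min() < 3:
        raise ValueError("each group needs >= 3 observations")
    cols = {"const": np.ones_like(y), "x": x}
    for name, v in (covariates or {}).items():
        cols[name] = np.asarray(v, dtype=float)
    exog = pd.DataFrame(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=group)
        res = model.fit(reml=True, method="lbfgs")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("fit_lmm: optimizer did not converge")
    return LMMFit(
        beta=float(res.params["x"]),
        sem=float(res.bse["x"]),
        p=float(res.pvalues["x"]),
        intercept=float(res.params["const"]),
        n_groups=int(groups.size),
        n_obs=int(y.size),
        converged=converged,
        covariate_betas={k: float(res.params[k]) for k in (covariates or {})},
    )


def sw_trend_before_ied(
    waves: pd.DataFrame,
    ied_times_by_patient: dict[str, np.ndarray],
    features: tuple[str, ...] = ("norm_slope", "norm_amplitude"),
) -> dict[str, LMMFit]:
    """Trend of normalized slow-wave features across time to the next
    discharge.

    ``waves`` needs columns ``patient``, ``time`` (wave onset, s) and the
    feature columns. Each wave is paired with the next discharge of its
    patient's (already region-scoped) discharge times; the regressor is the
    negated time-to-next-discharge, so a positive slope means the feature
    grows as the discharge approaches. Time since the recording start enters
    as a fixed nuisance covariate. Holm correction is applied across
    features (``p_holm`` attribute added on each fit).
    """
    rows = []
    n_unpaired = 0
    for pat, sub in waves.groupby("patient"):
        tied = np.sort(np.asarray(ied_times_by_patient.get(pat, ()), dtype=float))
        if tied.size == 0:
            n_unpaired += len(sub)
            continue
        t = sub["time"].to_numpy()
        j = np.searchsorted(tied, t)
        ok = j < tied.size
        n_unpaired += int((~ok).sum())
        for i in np.flatnonzero(ok):
            rows.append(
                {"patient": pat, "tti": tied[j[i]] - t[i], "time": t[i],
                 **{f: sub[f].iloc[i] for f in features}}
            )
    if not rows:
        raise ValueError("no wave has a subsequent discharge; no pairs to fit")
    if n_unpaired:
        logger.info("sw_trend_before_ied: %d waves without a later discharge dropped",
                    n_unpaired)
    df = pd.DataFrame(rows)
    fits = {
        f: fit_lmm(df[f], -df["tti"], df["patient"], covariates={"time": df["time"]})
        for f in features
    }
    adj = holm([fits[f].p for f in features])
    for f, q in zip(features, adj):
        fits[f].p_holm = float(q)  # type: ignore[attr-defined]
    return fits


def pre_ied_hg_table(
    x: np.ndarray,
    fs: float,
    ied_times: np.ndarray,
    min_t_star_s: float = 2.0,
    guard_s: float = 0.1,
    band: tuple[float, float] = (45.0, 130.0),
) -> pd.DataFrame | None:
    """Per-bin log high-gamma power before discharges for one patient.

    T* is the largest whole second such that at least 50% of discharges have
    a preceding inter-discharge gap >= T*; discharges with gap >= T* are
    analyzed in 1 s multitaper windows tiling ``(-T* - guard, -guard]``
    relative to the discharge. Returns None (patient excluded) if T* is
    below ``min_t_star_s``.
    """
    from .spectral import multitaper_band_power

    tied = np.sort(np.asarray(ied_times, dtype=float))
    if tied.size < 2:
        return None
    gaps = np.diff(tied, prepend=0.0)
    # largest whole second T with >= 50% of gaps >= T: the ceil(n/2)-th
    # largest gap, floored
    k = int(np.ceil(gaps.size / 2))
    t_star = int(np.floor(np.sort(gaps)[::-1][k - 1]))
    if t_star < min_t_star_s:
        logger.warning("pre_ied_hg_table: T*=%d s < %g s, patient excluded",
                       t_star, min_t_star_s)
        return None
    n_win = int(round(1.0 * fs))
    rows = []
    for k in np.flatnonzero(gaps >= t_star):
        t0 = tied[k]
        for j in range(t_star):
            hi = t0 - guard_s - j
            i1 = int(round(hi * fs))
            i0 = i1 - n_win
            if i0 < 0:
                continue
            power = float(multitaper_band_power(x[i0:i1][None, :], fs, band)[0])
            rows.append({"ied_index": int(k), "time_to_ied": -(j + 0.5) - guard_s,
                         "log_hg": np.log(power)})
    return pd.DataFrame(rows) if rows else None


def hg_trend_before_ied(tables_by_patient: dict[str, pd.DataFrame]) -> LMMFit:
    """Mixed-model trend of pre-discharge log high-gamma power vs time.

    Takes per-patient tables from :func:`pre_ied_hg_table`. The regressor is
    the (negative) bin-center time relative to the discharge, so a positive
    slope is a power build-up approaching the discharge, in log(uV^2)/s.
    """
    frames = [df.assign(patient=p) for p, df in tables_by_patient.items() if df is not None]
    if len(frames) < 2:
        raise ValueError("need >= 2 patients with a valid pre-discharge table")
    df = pd.concat(frames, ignore_index=True)
    return fit_lmm(df["log_hg"], df["time_to_ied"], df["patient"])


def ied_delay_hg_table(
    x: np.ndarray,
    fs: float,
    ied_times: np.ndarray,
    sw_troughs: np.ndarray,
    window_s: float = 0.05,
    band: tuple[float, float] = (45.0, 130.0),
) -> pd.DataFrame:
    """Log high-gamma power around each discharge (+/-``window_s``) paired
    with the delay since the most recent prior slow-wave trough. Discharges
    with no prior wave are dropped and counted."""
    from .spectral import multitaper_band_power

    troughs = np.sort(np.asarray(sw_troughs, dtype=float))
    rows = []
    n_drop = 0
    for t in np.asarray(ied_times, dtype=float):
        k = np.searchsorted(troughs, t)
        if k == 0:
            n_drop += 1
            continue
        i0 = int(round((t - window_s) * fs))
        i1 = int(round((t + window_s) * fs))
        if i0 < 0 or i1 > x.size:
            n_drop += 1
            continue
        power = float(multitaper_band_power(x[i0:i1][None, :], fs, band)[0])
        rows.append({"delay": t - troughs[k - 1], "log_hg": np.log(power)})
    if n_drop:
        logger.info("ied_delay_hg_table: %d discharges dropped (no prior wave/edge)",
                    n_drop)
    return pd.DataFrame(rows, columns=["delay", "log_hg"])


def hg_during_ied_vs_delay(tables_by_patient: dict[str, pd.DataFrame]) -> LMMFit:
    """Mixed model of discharge high-gamma power on the delay since the last
    slow wave (log(uV^2) per s), patient random intercepts."""
    frames = [df.assign(patient=p) for p, df in tables_by_patient.items() if len(df)]
    if len(frames) < 2:
        raise ValueError("need >= 2 patients with delay observations")
    df = pd.concat(frames, ignore_index=True)
    return fit_lmm(df["log_hg"], df["delay"], df["patient"])


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def annotate_trials(
    trials: pd.DataFrame,
    sw_times: np.ndarray,
    ied_times: np.ndarray,
) -> pd.DataFrame:
    """Add per-trial slow-wave and discharge rates (events whose trough falls
    within the trial span, divided by trial duration)."""
    out = trials.copy()
    for name, times in [("sw_rate", sw_times), ("ied_rate", ied_times)]:
        t = np.sort(np.asarray(times, dtype=float))
        lo = np.searchsorted(t, out["onset"].to_numpy())
        hi = np.searchsorted(t, (out["onset"] + out["duration"]).to_numpy())
        out[name] = (hi - lo) / out["duration"].to_numpy()
    return out


@dataclass
class BehaviorLinks:
    rt_models: dict[str, LMMFit]
    accuracy_effects: dict[str, EffectSize]
    n_excluded: dict[str, int]


def behavior_links(
    trials_by_patient: dict[str, pd.DataFrame],
    n_resamples: int = 5000,
    seed: int | np.random.Generator = 0,
) -> BehaviorLinks:
    """Reaction-time mixed models and accuracy comparisons.

    Each per-patient frame must carry phase, rt, accuracy, sw_rate and
    ied_rate columns (see :func:`annotate_trials`). RT models are fit on
    retrieval trials (RT against slow-wave rate with discharge rate as a
    covariate, patient random intercepts), plus an accurate-trials-only
    refit. Accuracy effects are paired tests of per-patient mean rates in
    high vs low accuracy trials per phase and event kind; patients lacking
    one of the accuracy classes are excluded per comparison and counted.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pooled = pd.concat(
        [df.assign(patient=p) for p, df in trials_by_patient.items()], ignore_index=True
    )
    ret = pooled[(pooled["phase"] == "retrieval") & pooled["rt"].notna()]
    rt_models = {
        "sw_retrieval": fit_lmm(ret["rt"], ret["sw_rate"], ret["patient"],
                                covariates={"ied_rate": ret["ied_rate"]}),
        "ied_retrieval": fit_lmm(ret["rt"], ret["ied_rate"], ret["patient"],
                                 covariates={"sw_rate": ret["sw_rate"]}),
    }
    acc = ret[ret["accuracy"] == "high"]
    try:
        rt_models["sw_retrieval_accurate"] = fit_lmm(
            acc["rt"], acc["sw_rate"], acc["patient"],
            covariates={"ied_rate": acc["ied_rate"]})
    except ValueError as err:
        logger.warning("behavior_links: accurate-only refit skipped (%s)", err)
    accuracy_effects: dict[str, EffectSize] = {}
    n_excluded: dict[str, int] = {}
    for phase in ("encoding", "retrieval"):
        for kind in ("sw_rate", "ied_rate"):
            hi_means, lo_means, excluded = [], [], 0
            for pat, df in trials_by_patient.items():
                sub = df[df["phase"] == phase]
                hi = sub[sub["accuracy"] == "high"][kind]
                lo = sub[sub["accuracy"] == "low"][kind]
                if len(hi) == 0 or len(lo) == 0:
                    excluded += 1
                    continue
                hi_means.append(hi.mean())
                lo_means.append(lo.mean())
            key = f"{kind}_{phase}"
            n_excluded[key] = excluded
            if len(hi_means) >= 5:
                accuracy_effects[key] = paired_permutation_test(
                    hi_means, lo_means, n_resamples=n_resamples, seed=rng)
            else:
                logger.warning("behavior_links: <5 patients for %s, comparison skipped",
                               key)
    return BehaviorLinks(rt_models, accuracy_effects, n_excluded)


# ---------------------------------------------------------------------------
# Discharge-validation controls
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    hg_ied_vs_psw: EffectSize | None
    sw_rate_top_ied_electrode: EffectSize | None
    decay_ratio_difference: EffectSize | None


def ied_validation_controls(
    per_patient: Sequence[dict],
    n_resamples: int = 5000,
    seed: int | np.random.Generator = 0,
) -> ValidationReport:
    """Controls that detected slow waves are not mislabeled discharges.

    Each patient dict provides ``recording`` (:class:`~lowsuite.core.Recording`),
    ``ieds`` and ``sws`` (:class:`~lowsuite.core.EventTable`). Three checks:
    (i) high-gamma power around discharge peaks vs positive-wave troughs
    (paired across patients); (ii) slow-wave rate on the max-discharge
    electrode vs the mean of the others; (iii) spatial decay of the sharp
    peak vs the 0-0.5 s after-wave: the contact-1/contact-2 normalized
    amplitude ratios of both components compared pairwise.
    """
    from .spectral import multitaper_band_power

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hg_ied, hg_psw = [], []
    sw_top, sw_rest = [], []
    ratio_sharp, ratio_slow = [], []
    for pat in per_patient:
        rec = pat["recording"]
        ieds, sws = pat["ieds"], pat["sws"]
        fs = rec.fs
        w = int(round(0.05 * fs))

        def _mean_power(label, times):
            vals = []
            x = rec.get(label)
            for t in times:
                c = int(round(t * fs))
                if c - w < 0 or c + w > x.size:
                    continue
                vals.append(multitaper_band_power(x[c - w : c + w][None, :], fs)[0])
            return float(np.mean(vals)) if vals else np.nan

        p_ied = [_mean_power(lab, ieds.on_channel(lab).times()) for lab in
                 rec.channel_labels() if len(ieds.on_channel(lab))]
        p_psw = [_mean_power(lab, sws.of_kind("pSW").on_channel(lab).times()) for lab in
                 rec.channel_labels() if len(sws.of_kind("pSW").on_channel(lab))]
        if p_ied and p_psw:
            hg_ied.append(np.nanmean(p_ied))
            hg_psw.append(np.nanmean(p_psw))

        if rec.n_channels >= 2:
            ied_counts = {lab: len(ieds.on_channel(lab)) for lab in rec.channel_labels()}
            top = max(ied_counts, key=ied_counts.get)
            dur = rec.duration_s
            top_rate = len(sws.on_channel(top)) / dur
            others = [len(sws.on_channel(l)) / dur for l in rec.channel_labels()
                      if l != top]
            sw_top.append(top_rate)
            sw_rest.append(float(np.mean(others)))

        labels = rec.channel_labels()
        if len(labels) >= 2:
            x1, x2 = rec.get(labels[0]), rec.get(labels[1])
            sharp1, sharp2, slow1, slow2 = [], [], [], []
            for t in ieds.on_channel(labels[0]).times():
                c = int(round(t * fs))
                j = min(c + int(round(0.5 * fs)), x1.size)
                if c >= x1.size:
                    continue
                sharp1.append(abs(x1[c]))
                sharp2.append(abs(x2[c]))
                slow1.append(np.max(np.abs(x1[c + 1 : j])) if j > c + 1 else np.nan)
                slow2.append(np.max(np.abs(x2[c + 1 : j])) if j > c + 1 else np.nan)
            if sharp1 and np.mean(sharp1) > 0 and np.nanmean(slow1) > 0:
                ratio_sharp.append(np.mean(sharp2) / np.mean(sharp1))
                ratio_slow.append(np.nanmean(slow2) / np.nanmean(slow1))

    def _maybe_test(a, b):
        if len(a) >= 5 and len(a) == len(b):
            return paired_permutation_test(a, b, n_resamples=n_resamples, seed=rng)
        return None

    return ValidationReport(
        hg_ied_vs_psw=_maybe_test(hg_ied, hg_psw),
        sw_rate_top_ied_electrode=_maybe_test(sw_top, sw_rest),
        decay_ratio_difference=_maybe_test(ratio_sharp, ratio_slow),
    )
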