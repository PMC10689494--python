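"""Config-driven end-to-end orchestration.

A run either simulates the committed synthetic scenario or loads a
recording, then chains discharge detection, slow-wave detection, rates and
validation statistics, spectral summaries, wave-pair coupling and (when
trials and spikes are present) behavior and unit-firing analyses. All
outputs are TSV/JSON; a structured log records every parameter and seed.
One master seed fans out to stage-specific child seeds so each stage is
individually reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import core, coupling, inference, spectral, sw as sw_mod, synth, unitfire
from .core import EventTable, Recording, event_rate
from .ied import detect_ieds
from .sw import detect_slow_waves

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "synth" not in cfg and "recording" not in cfg:
        raise ValueError("config needs either a 'synth' block or a 'recording' path")
    return cfg


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write a result bundle.

    Returns the bundle: a dict of file paths and summary statistics. Raises
    with the failing stage's name on any stage error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "synth" not in config and "recording" not in config:
        raise ValueError("config needs either a 'synth' block or a 'recording' path")
    seed = int(config.get("seed", 0))
    bundle: dict = {"out_dir": str(out), "seed": seed, "stages": {}}

    stage = "simulate" if "synth" in config else "load"
    try:
        if "synth" in config:
            scfg = synth.SynthConfig.from_dict({**config["synth"], "seed": seed})
            ds = synth.generate_dataset(scfg)
            rec = ds.recording
            core.write_recording(rec, out / "recording.h5")
            core.write_events(ds.truth, out / "truth.tsv")
            core.write_spikes(ds.spikes, out / "spikes.tsv")
            core.write_trials(ds.trials, out / "trials.tsv")
            bundle["stages"][stage] = {"config": asdict(scfg)}
            spikes, trials = ds.spikes, ds.trials
        else:
            rec = core.read_recording(
                config["recording"],
                format=config.get("format", "container"),
                sidecar=config.get("sidecar"),
            )
            spikes = (core.read_spikes(config["spikes"]) if "spikes" in config else [])
            trials = (core.read_trials(config["trials"]) if "trials" in config else None)
            bundle["stages"][stage] = {"recording": str(config["recording"])}

        stage = "detect_ied"
        ieds = detect_ieds(rec)
        core.write_events(ieds, out / "ieds.tsv")
        stage = "detect_sw"
        sws = detect_slow_waves(rec, ieds)
        core.write_events(sws, out / "sw.tsv")

        stage = "rates"
        dur, n_el = rec.duration_s, rec.n_channels
        ied_times = np.sort(ieds.times())
        nsw = sws.of_kind("nSW")
        rates = {
            "ied_rate_per_s_per_electrode": event_rate(ieds.times(), dur, n_el),
            "nsw_rate_per_s_per_electrode": event_rate(
                nsw.times(), dur, n_el, refractory=(ied_times, 1.0)),
            "psw_rate_per_s_per_electrode": event_rate(
                sws.of_kind("pSW").times(), dur, n_el, refractory=(ied_times, 1.0)),
        }
        rates["corrected_nsw_rate"] = sw_mod.corrected_lows_rate(
            rates["nsw_rate_per_s_per_electrode"],
            rates["ied_rate_per_s_per_electrode"],
        )
        per_el_ied = [event_rate(ieds.on_channel(l).times(), dur) for l in rec.channel_labels()]
        per_el_sw = [event_rate(nsw.on_channel(l).times(), dur) for l in rec.channel_labels()]
        if all(r > 0 for r in per_el_sw):
            rates["prv"] = inference.prv(per_el_ied, per_el_sw)
        bundle["stages"]["rates"] = rates

        stage = "spectral"
        x0 = rec.samples[0]
        f, psd = spectral.welch_psd(x0, rec.fs)
        bundle["stages"]["spectral"] = {
            "log_delta_power": spectral.welch_band_power(x0, rec.fs, (0.5, 4.0)),
            "log_theta_power": spectral.welch_band_power(x0, rec.fs, (4.1, 7.0)),
            "alpha_peak_hz": spectral.alpha_peak(f, psd),
        }

        stage = "coupling"
        nsw_t = np.sort(nsw.times())
        psw_t = np.sort(sws.of_kind("pSW").times())
        if nsw_t.size and psw_t.size:
            pair = coupling.psth(nsw_t, psw_t, window=(-1.0, 1.0), n_electrodes=n_el)
            bundle["stages"]["coupling"] = {
                "psw_around_nsw_peak_rate": float(pair.rate.max()),
                "psw_around_nsw_peak_lag_s": float(pair.bin_centers[int(np.argmax(pair.rate))]),
            }

        stage = "units"
        if spikes:
            kept = unitfire.filter_units(spikes, min_rate_hz=2.0)
            unit_stats = {"n_units": len(spikes), "n_kept": len(kept)}
            if kept and nsw_t.size:
                troughs = [t for t in nsw_t if 3.0 < t < dur - 3.0]
                mats = []
                for u in kept:
                    try:
                        m, times = unitfire.peri_event_rate(u.spike_times_s, troughs, dur)
                        mats.append(m.mean(axis=0))
                    except ValueError:
                        continue
                if mats:
                    grand = np.mean(mats, axis=0)
                    sel = (times >= -0.15) & (times <= 0.165)
                    unit_stats["downstate_mean_norm_rate"] = float(grand[sel].mean())
            bundle["stages"]["units"] = unit_stats

        stage = "behavior"
        if trials is not None and len(trials):
            annotated = inference.annotate_trials(trials, nsw_t, ied_times)
            annotated.insert(0, "patient", rec.patient_id)
            annotated.to_csv(out / "trials_annotated.tsv", sep="\t", index=False,
                             na_rep="n/a")
            bundle["stages"]["behavior"] = {"n_trials": int(len(annotated))}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_json_default)
    return bundle


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)


def report(bundle: dict) -> str:
    """Human-readable summary of a result bundle."""
    if not bundle or "stages" not in bundle or not bundle["stages"]:
        raise ValueError("empty bundle")
    lines = [f"lowsuite run (seed {bundle.get('seed')}) -> {bundle.get('out_dir')}"]
    stages = bundle["stages"]
    if "rates" in stages:
        r = stages["rates"]
        lines.append(
            f"  rates: nSW {r['nsw_rate_per_s_per_electrode']:.4f}/s/el, "
            f"pSW {r['psw_rate_per_s_per_electrode']:.4f}/s/el, "
            f"IED {r['ied_rate_per_s_per_electrode']:.4f}/s/el"
        )
        if "prv" in r:
            lines.append(f"  PRV: {r['prv']:.4f}")
        if r["ied_rate_per_s_per_electrode"] == 0:
            lines.append("  note: no IEDs detected; discharge-dependent statistics skipped")
    if "spectral" in stages:
        s = stages["spectral"]
        lines.append(
            f"  spectra: log delta {s['log_delta_power']:.2f}, "
            f"log theta {s['log_theta_power']:.2f}, "
            f"alpha peak {s['alpha_peak_hz']:.2f} Hz"
        )
    if "coupling" in stages:
        c = stages["coupling"]
        lines.append(
            f"  coupling: pSW-around-nSW peak {c['psw_around_nsw_peak_rate']:.3f} "
            f"at {c['psw_around_nsw_peak_lag_s']:+.2f} s"
        )
    if "units" in stages:
        u = stages["units"]
        extra = (f", down-state norm rate {u['downstate_mean_norm_rate']:.3f}"
                 if "downstate_mean_norm_rate" in u else "")
        lines.append(f"  units: {u['n_kept']}/{u['n_units']} kept (>=2 Hz){extra}")
    if "behavior" in stages:
        lines.append(f"  behavior: {stages['behavior']['n_trials']} trials annotated")
    missing = [s for s in ("rates", "spectral") if s not in stages]
    if missing:
        lines.append(f"  warning: incomplete bundle, missing stages {missing}")
    return "\n".join(lines)
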