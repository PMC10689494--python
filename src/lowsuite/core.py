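"""Domain containers and I/O shared by every analysis stage.

Conventions: time is in seconds (float), sample indices are 0-based, and all
epoch windows are half-open ``[t0, t1)`` in sample space. LFP amplitudes are
in microvolts throughout. Events, trials and spikes travel as BIDS-events
style tab-separated tables; recordings travel as EDF (read) or as the
package's HDF5 container (read/write) with a channel-metadata sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("hippocampus", "amygdala", "temporal_neocortex")
EVENT_KINDS = ("IED", "nSW", "pSW")

#: Working sampling rate; sources above it are resampled down, sources below
#: are kept as-is.
DEFAULT_WORKING_FS = 512.0


@dataclass(frozen=True)
class ChannelInfo:
    """A recording contact: label, anatomical region and row index."""

    label: str
    region: str
    index: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(
                f"channel {self.label!r}: region {self.region!r} not one of {REGIONS}"
            )


@dataclass
class Recording:
    """Multi-channel referential LFP.

    samples : (n_channels, n_times) float array, microvolts
    fs : sampling rate in Hz
    channels : per-row :class:`ChannelInfo`
    artifact_mask : optional per-timepoint bool, True = excluded
    """

    samples: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    patient_id: str = "p0"
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x timepoints)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel metadata does not match samples")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.samples.shape[1],):
                raise ValueError("artifact_mask length must match timepoints")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def get(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def channel_index(self, label: str) -> int:
        for c in self.channels:
            if c.label == label:
                return c.index
        raise KeyError(f"no channel labelled {label!r}")

    def region_of(self, label: str) -> str:
        return self.channels[self.channel_index(label)].region


@dataclass(frozen=True)
class Event:
    """A detected or planted event.

    For slow waves ``onset_s < trough_s < zc2_s`` are the first zero-crossing,
    the extremum and the second zero-crossing of the 0.5-4 Hz filtered signal;
    ``freq_hz = 1 / (2 (zc2_s - onset_s))``. For IEDs only ``trough_s`` (the
    raw-signal absolute peak) and ``amplitude_uV`` are defined.
    """

    kind: str
    channel: str
    onset_s: float
    trough_s: float
    zc2_s: float = np.nan
    amplitude_uV: float = np.nan
    slope_uV_per_s: float = np.nan
    freq_hz: float = np.nan
    norm_amplitude: float = np.nan
    norm_slope: float = np.nan

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


_EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "channel",
    "trough",
    "amplitude",
    "slope",
    "freq",
    "norm_amplitude",
    "norm_slope",
]


class EventTable:
    """Ordered collection of events plus recording context.

    Events are kept sorted by trough time within channel; duplicate
    ``(channel, trough_s)`` pairs are rejected.
    """

    def __init__(self, events: Iterable[Event], duration_s: float, patient_id: str = "p0"):
        ev = sorted(events, key=lambda e: (e.channel, e.trough_s))
        keys = [(e.channel, e.trough_s) for e in ev]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (channel, trough) events")
        self.events: list[Event] = ev
        self.duration_s = float(duration_s)
        self.patient_id = patient_id

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and np.isclose(self.duration_s, other.duration_s)
            and len(self) == len(other)
            and all(_events_close(a, b) for a, b in zip(self.events, other.events))
        )

    def of_kind(self, *kinds: str) -> "EventTable":
        return EventTable(
            [e for e in self.events if e.kind in kinds], self.duration_s, self.patient_id
        )

    def on_channel(self, label: str) -> "EventTable":
        return EventTable(
            [e for e in self.events if e.channel == label], self.duration_s, self.patient_id
        )

    def times(self, which: str = "trough_s") -> np.ndarray:
        return np.array([getattr(e, which) for e in self.events], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            dur = e.zc2_s - e.onset_s if np.isfinite(e.zc2_s) else 0.0
            rows.append(
                {
                    "onset": e.onset_s,
                    "duration": dur,
                    "trial_type": e.kind,
                    "channel": e.channel,
                    "trough": e.trough_s,
                    "amplitude": e.amplitude_uV,
                    "slope": e.slope_uV_per_s,
                    "freq": e.freq_hz,
                    "norm_amplitude": e.norm_amplitude,
                    "norm_slope": e.norm_slope,
                }
            )
        return pd.DataFrame(rows, columns=_EVENT_COLUMNS)

    def with_events(self, events: Iterable[Event]) -> "EventTable":
        return EventTable(events, self.duration_s, self.patient_id)


def _events_close(a: Event, b: Event) -> bool:
    if a.kind != b.kind or a.channel != b.channel:
        return False
    for f in ("onset_s", "trough_s", "zc2_s", "amplitude_uV", "slope_uV_per_s",
              "freq_hz", "norm_amplitude", "norm_slope"):
        x, y = getattr(a, f), getattr(b, f)
        if np.isnan(x) and np.isnan(y):
            continue
        if not np.isclose(x, y, rtol=1e-9, atol=1e-9):
            return False
    return True


@dataclass
class SpikeTrain:
    """Spike times (s, ascending) of one sorted unit."""

    unit_id: str
    spike_times_s: np.ndarray
    duration_s: float
    patient_id: str = "p0"

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("spike times must be ascending within [0, duration]")
        self.spike_times_s = t

    @property
    def mean_rate_hz(self) -> float:
        return len(self.spike_times_s) / self.duration_s


# ---------------------------------------------------------------------------
# Events / trials / spikes TSV I/O (BIDS-events style)
# ---------------------------------------------------------------------------

def write_events(table: EventTable, path: str | Path) -> None:
    """Write an event table as a TSV with a ``# duration=..`` provenance line."""
    path = Path(path)
    df = table.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# duration_s={table.duration_s!r}\tpatient_id={table.patient_id}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: line 1: missing provenance header")
        meta = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t", na_values=["n/a"])
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=3):
        if row.trial_type not in EVENT_KINDS:
            raise ValueError(f"{path}: line {i}: unknown trial_type {row.trial_type!r}")
        zc2 = row.onset + row.duration if row.duration > 0 else np.nan
        events.append(
            Event(
                kind=row.trial_type,
                channel=str(row.channel),
                onset_s=row.onset,
                trough_s=row.trough,
                zc2_s=zc2,
                amplitude_uV=_nan(row.amplitude),
                slope_uV_per_s=_nan(row.slope),
                freq_hz=_nan(row.freq),
                norm_amplitude=_nan(row.norm_amplitude),
                norm_slope=_nan(row.norm_slope),
            )
        )
    return EventTable(events, float(meta["duration_s"]), meta.get("patient_id", "p0"))


def _nan(x) -> float:
    return float(x) if pd.notna(x) else np.nan


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    cols = ["phase", "onset", "duration", "rt", "accuracy"]
    trials.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    bad = set(df["phase"]) - {"encoding", "retrieval"}
    if bad:
        raise ValueError(f"{path}: unknown trial phase(s) {sorted(bad)}")
    return df


def write_spikes(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    rows = [
        {"unit_id": tr.unit_id, "time_s": t, "duration_s": tr.duration_s,
         "patient_id": tr.patient_id}
        for tr in trains
        for t in tr.spike_times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s", "duration_s", "patient_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path, sep="\t")
    trains = []
    for uid, sub in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(
                unit_id=str(uid),
                spike_times_s=np.sort(sub["time_s"].to_numpy()),
                duration_s=float(sub["duration_s"].iloc[0]),
                patient_id=str(sub["patient_id"].iloc[0]),
            )
        )
    return trains


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def read_channel_sidecar(path: str | Path) -> dict[str, dict]:
    """Channel metadata sidecar: TSV with columns label, region, patient."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.label): {"region": r.region, "patient": str(r.patient)}
            for r in df.itertuples(index=False)}


def write_channel_sidecar(recording: Recording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": recording.channel_labels(),
            "region": [c.region for c in recording.channels],
            "patient": recording.patient_id,
        }
    ).to_csv(path, sep="\t", index=False)


def read_recording(
    path: str | Path,
    format: str = "container",
    sidecar: str | Path | None = None,
    working_fs: float = DEFAULT_WORKING_FS,
) -> Recording:
    """Read a recording from EDF or from the HDF5 container.

    Sources sampled above ``working_fs`` are resampled down to it; sources at
    or below it are kept at their native rate. For EDF input a channel
    sidecar table (label, region, patient) is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "container":
        rec = _read_container(path)
    elif format == "edf":
        if sidecar is None:
            raise ValueError("EDF input requires a channel metadata sidecar")
        rec = _read_edf(path, read_channel_sidecar(sidecar))
    else:
        raise ValueError(f"unknown recording format {format!r}")
    if rec.fs > working_fs:
        rec = resample_recording(rec, working_fs)
    return rec


def _read_edf(path: Path, meta: dict[str, dict]) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = raw.ch_names
    channels = []
    for i, lab in enumerate(labels):
        if lab not in meta:
            raise ValueError(f"channel {lab!r} missing from sidecar metadata")
        channels.append(ChannelInfo(label=lab, region=meta[lab]["region"], index=i))
    patient = meta[labels[0]]["patient"]
    # MNE loads EDF in volts; convert back to microvolts.
    samples = raw.get_data() * 1e6
    return Recording(samples=samples, fs=float(raw.info["sfreq"]),
                     channels=channels, patient_id=patient)


def resample_recording(rec: Recording, target_fs: float) -> Recording:
    from scipy.signal import resample_poly
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    samples = resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return replace(rec, samples=samples, fs=target_fs, artifact_mask=None)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write the HDF5 container: samples, fs and channel metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.attrs["fs"] = rec.fs
        f.attrs["patient_id"] = rec.patient_id
        f.create_dataset("label", data=[c.label.encode() for c in rec.channels])
        f.create_dataset("region", data=[c.region.encode() for c in rec.channels])
        if rec.artifact_mask is not None:
            f.create_dataset("artifact_mask", data=rec.artifact_mask)


def _read_container(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        labels = [s.decode() for s in f["label"][()]]
        regions = [s.decode() for s in f["region"][()]]
        channels = [
            ChannelInfo(label=l, region=r, index=i)
            for i, (l, r) in enumerate(zip(labels, regions))
        ]
        mask = f["artifact_mask"][()] if "artifact_mask" in f else None
        return Recording(
            samples=f["samples"][()],
            fs=float(f.attrs["fs"]),
            channels=channels,
            patient_id=str(f.attrs["patient_id"]),
            artifact_mask=mask,
        )


# ---------------------------------------------------------------------------
# Epoching and rates
# ---------------------------------------------------------------------------

def extract_epochs(
    signal: np.ndarray | Recording,
    event_times: Sequence[float],
    window: tuple[float, float],
    fs: float | None = None,
    channel: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut peri-event epochs out of one channel.

    Returns ``(epochs, kept_times)`` where ``epochs`` is events x timepoints
    with the column at offset ``-t0 * fs`` aligned to the event time. Sample
    indexing is half-open ``[round(t0 fs), round(t1 fs))``. Events whose
    window leaves the recording are dropped and counted in the log.
    """
    if isinstance(signal, Recording):
        if channel is None:
            raise ValueError("channel label required with a Recording input")
        fs = signal.fs
        x = signal.get(channel)
    else:
        if fs is None:
            raise ValueError("fs required with an array input")
        x = np.asarray(signal, dtype=float)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t0 < t1")
    i0 = int(round(t0 * fs))
    i1 = int(round(t1 * fs))
    n = i1 - i0
    rows, kept = [], []
    for t in event_times:
        c = int(round(t * fs))
        if c + i0 < 0 or c + i1 > x.size:
            continue
        rows.append(x[c + i0 : c + i1])
        kept.append(t)
    dropped = len(event_times) - len(kept)
    if dropped:
        logger.info("extract_epochs: dropped %d/%d events at recording edges",
                    dropped, len(event_times))
    if not rows:
        return np.empty((0, n)), np.array([])
    return np.asarray(rows), np.asarray(kept)


def union_spans(spans: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of possibly-overlapping intervals."""
    spans = sorted((s for s in spans if s[1] > s[0]))
    out: list[tuple[float, float]] = []
    for a, b in spans:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def event_rate(
    event_times: Sequence[float] | EventTable,
    duration_s: float,
    n_electrodes: int = 1,
    refractory: tuple[Sequence[float], float] | None = None,
) -> float:
    """Events per second per electrode, optionally refractory-corrected.

    When ``refractory=(ied_times, horizon)`` is given, the union of
    ``(t, t + horizon]`` spans after each IED is subtracted from the
    denominator, mirroring the 1 s post-IED exclusion of the detector.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if isinstance(event_times, EventTable):
        count = len(event_times)
    else:
        count = len(event_times)
    effective = duration_s
    if refractory is not None:
        ied_times, horizon = refractory
        spans = union_spans(
            (t, min(t + horizon, duration_s)) for t in ied_times if t < duration_s
        )
        effective -= sum(b - a for a, b in spans)
    return count / (effective * n_electrodes)
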