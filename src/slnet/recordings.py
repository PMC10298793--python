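"""Multichannel EEG containers, band-pass filtering, epoching, and the
channel -> electrode -> Brodmann montage lookup.

Channels follow the 19-electrode 10-20 montage (Fp1 .. O2) and are numbered
Ch01..Ch19 (1-based, as printed on clinical reports); sample indices are
0-based and epochs use half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "MultichannelRecording",
    "BandDefinition",
    "STUDY_BANDS",
    "Event",
    "Epoch",
    "EpochSet",
    "MontageEntry",
    "MONTAGE",
    "channel_montage",
    "bandpass_filter",
    "segment_epochs",
    "read_recording",
    "write_delimited",
]

#: 10-20 electrode names in channel order Ch01..Ch19.
ELECTRODES_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclass
class MultichannelRecording:
    """A channels x samples EEG array with sampling rate and labels.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (or arbitrary units for synthetic data).
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        One unique label per channel, in row order.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"Ch{i + 1:02d}" for i in range(self.data.shape[0])
            )
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must equal channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[low, high]`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band edges {self.low}-{self.high}")


#: The five analysis bands. The delta low edge of 0.01 Hz reflects the
#: hardware high-pass of the recording amplifier rather than a filter choice.
STUDY_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.01, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)

BAND_BY_NAME = {b.name: b for b in STUDY_BANDS}


@dataclass(frozen=True)
class Event:
    """One task stimulus: a labelled time interval of a recording."""

    subject: str
    task: str
    stimulus: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event end must be after start")


@dataclass
class Epoch:
    subject: str
    task: str
    stimulus: int
    recording: MultichannelRecording


@dataclass
class EpochSet:
    """Epochs sharing a sampling rate and channel ordering."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs:
            fs0 = self.epochs[0].recording.fs
            labels0 = self.epochs[0].recording.channel_labels
            for ep in self.epochs:
                if ep.recording.fs != fs0:
                    raise ValueError("epochs must share a sampling rate")
                if ep.recording.channel_labels != labels0:
                    raise ValueError("epochs must share channel ordering")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def select(self, subject=None, task=None, stimulus=None) -> "EpochSet":
        out = [
            ep
            for ep in self.epochs
            if (subject is None or ep.subject == subject)
            and (task is None or ep.task == task)
            and (stimulus is None or ep.stimulus == stimulus)
        ]
        return EpochSet(out)


@dataclass(frozen=True)
class MontageEntry:
    """Channel -> electrode -> Brodmann area lookup for one channel.

    ``brodmann`` lists candidate areas; ``ambiguous`` is True when the
    electrode overlies more than one area (or the assignment is only stated
    collectively for a group of electrodes), in which case no single area is
    guessed.
    """

    channel_index: int  # 1-based, Ch01..Ch19
    electrode: str
    brodmann: tuple[int, ...]
    ambiguous: bool = False

    @property
    def channel_label(self) -> str:
        return f"Ch{self.channel_index:02d}"


def _m(idx, electrode, areas, ambiguous=False):
    return MontageEntry(idx, electrode, tuple(areas), ambiguous)


#: Electrode-to-Brodmann assignment. Single-area entries are the ones the
#: source montage states individually; grouped or unstated electrodes carry
#: all plausible candidate areas and are flagged ambiguous.
MONTAGE: tuple[MontageEntry, ...] = (
    _m(1, "Fp1", (10,), ambiguous=True),
    _m(2, "Fp2", (10,), ambiguous=True),
    _m(3, "F7", (47,)),
    _m(4, "F3", (8, 9), ambiguous=True),
    _m(5, "Fz", (6, 8), ambiguous=True),
    _m(6, "F4", (8,)),
    _m(7, "F8", (45,)),
    _m(8, "T3", (42,)),
    _m(9, "C3", (1, 2, 5), ambiguous=True),
    _m(10, "Cz", (1, 2, 5), ambiguous=True),
    _m(11, "C4", (1, 2, 5), ambiguous=True),
    _m(12, "T4", (21,)),
    _m(13, "T5", (18, 37), ambiguous=True),
    _m(14, "P3", (7, 39), ambiguous=True),
    _m(15, "Pz", (7,), ambiguous=True),
    _m(16, "P4", (7, 39), ambiguous=True),
    _m(17, "T6", (18, 37), ambiguous=True),
    _m(18, "O1", (18, 37), ambiguous=True),
    _m(19, "O2", (18, 37), ambiguous=True),
)


def channel_montage(channel_index: int) -> MontageEntry:
    """Return the montage entry for a 1-based channel index (1..19)."""
    if not 1 <= channel_index <= 19:
        raise ValueError(f"channel index {channel_index} outside 1..19")
    return MONTAGE[channel_index - 1]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

#: Below this fraction of Nyquist a band-pass low edge makes the IIR design
#: numerically unreliable; the low edge is then dropped (low-pass only).
_MIN_RELATIVE_EDGE = 2e-4


def bandpass_filter(
    rec: MultichannelRecording, band: BandDefinition, order: int = 4
) -> MultichannelRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward (``sosfiltfilt``) application removes group delay, so
    event timing is preserved. When the low edge is a negligible fraction of
    Nyquist (the delta band's 0.01 Hz at typical EEG rates) only the low-pass
    half is applied: the corresponding high-pass is numerically degenerate
    and the amplifier hardware already imposes it.
    """
    nyq = rec.fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band high edge {band.high} Hz not below Nyquist {nyq} Hz"
        )
    if band.low / nyq < _MIN_RELATIVE_EDGE:
        sos = signal.butter(order, band.high, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(
            order, (band.low, band.high), btype="bandpass", fs=rec.fs, output="sos"
        )
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return MultichannelRecording(filtered, rec.fs, rec.channel_labels)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------


def segment_epochs(rec: MultichannelRecording, events: Sequence[Event]) -> EpochSet:
    """Cut one epoch per event using half-open sample intervals [start, end).

    Sample indices are ``round(t * fs)``; an event whose end exceeds the
    recording raises. Overlapping events are allowed.
    """
    if not events:
        raise ValueError("no events to segment")
    epochs = []
    for ev in events:
        start = int(round(ev.start_s * rec.fs))
        end = int(round(ev.end_s * rec.fs))
        if start < 0 or end > rec.n_samples:
            raise ValueError(
                f"event ({ev.subject},{ev.task},{ev.stimulus}) samples "
                f"[{start},{end}) outside recording of {rec.n_samples} samples"
            )
        if end <= start:
            raise ValueError("event spans no samples at this sampling rate")
        seg = MultichannelRecording(
            rec.data[:, start:end].copy(), rec.fs, rec.channel_labels
        )
        epochs.append(Epoch(ev.subject, ev.task, ev.stimulus, seg))
    return EpochSet(epochs)


# ---------------------------------------------------------------------------
# I/O — delimited text (+ JSON sidecar) and EDF
# ---------------------------------------------------------------------------


def _read_sidecar(events_path) -> tuple[float | None, list[Event]]:
    with open(events_path) as fh:
        meta = json.load(fh)
    events = [
        Event(
            subject=str(e["subject"]),
            task=str(e["task"]),
            stimulus=int(e["stimulus"]),
            start_s=float(e["start_s"]),
            end_s=float(e["end_s"]),
        )
        for e in meta.get("events", [])
    ]
    fs = meta.get("fs")
    return (float(fs) if fs is not None else None, events)


def read_recording(
    path,
    format: str = "delimited",
    events_path=None,
    fs: float | None = None,
) -> tuple[MultichannelRecording, list[Event]]:
    """Read a recording plus its events.

    ``delimited``: tab-separated text, one column per channel, header row of
    channel labels; the sampling rate comes from the JSON sidecar (or the
    ``fs`` argument). ``edf``: standard European Data Format, read through
    MNE if available. Events are validated against the recording length.
    """
    path = Path(path)
    if format == "delimited":
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2).T
        side_fs, events = (None, [])
        if events_path is not None:
            side_fs, events = _read_sidecar(events_path)
        fs = fs if fs is not None else side_fs
        if fs is None:
            raise ValueError("sampling rate missing: provide fs or a sidecar")
        rec = MultichannelRecording(data, fs, tuple(labels))
    elif format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - mne is an extra
            raise ImportError("EDF support requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        rec = MultichannelRecording(
            raw.get_data() * 1e6, raw.info["sfreq"], tuple(raw.ch_names)
        )
        events = []
        if events_path is not None:
            _, events = _read_sidecar(events_path)
    else:
        raise ValueError(f"unknown format {format!r}")

    for ev in events:
        if ev.start_s < 0 or ev.end_s * rec.fs > rec.n_samples + 0.5:
            raise ValueError(
                f"event ({ev.subject},{ev.task},{ev.stimulus}) extends past "
                "the recording"
            )
    return rec, events


def write_delimited(
    rec: MultichannelRecording, path, events: Sequence[Event] = (), events_path=None
) -> None:
    """Write a recording as tab-separated text plus an optional JSON sidecar."""
    path = Path(path)
    header = "\t".join(rec.channel_labels)
    np.savetxt(path, rec.data.T, delimiter="\t", header=header, comments="",
               fmt="%.8g")
    if events_path is not None:
        meta = {
            "fs": rec.fs,
            "events": [
                {
                    "subject": ev.subject,
                    "task": ev.task,
                    "stimulus": ev.stimulus,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                }
                for ev in events
            ],
        }
        with open(events_path, "w") as fh:
            json.dump(meta, fh, indent=1)
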