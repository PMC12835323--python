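"""EEG recordings and annotation interval tables.

Defines the shared in-memory containers — :class:`EEGRecording`,
:class:`Interval`, :class:`AnnotationTrack` — and readers/writers for the
two on-disk forms the package standardizes on:

* EDF (European Data Format) for signals, read through MNE;
* plain CSV for signals (one header row of channel labels, one column per
  channel, with the sampling rate carried in a ``# fs=<Hz>`` comment line)
  and for annotations (``onset_s,duration_s,label,channel``).

Time is expressed in seconds as floats, intervals are half-open
``[onset, onset + duration)``, and a recording starts at t = 0.  Amplitudes
are microvolts throughout.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VALID_LABELS",
    "EEGRecording",
    "Interval",
    "AnnotationTrack",
    "ValidationError",
    "read_recording",
    "write_recording_csv",
    "read_annotations",
    "write_annotations",
]

#: Closed set of interval labels understood by the pipeline.
VALID_LABELS = frozenset({"suppression", "burst", "bs_epoch"})


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class Interval:
    """A labeled half-open time interval ``[onset, onset + duration)``.

    Parameters
    ----------
    onset : float
        Seconds from the start of the recording (t = 0).  Non-negative.
    duration : float
        Length in seconds.  Strictly positive.
    label : str
        One of ``suppression``, ``burst``, ``bs_epoch``.
    channel : str
        Channel name, or ``"all"`` for a consensus / whole-montage interval.
    """

    onset: float
    duration: float
    label: str
    channel: str = "all"

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValidationError(f"interval onset must be >= 0, got {self.onset}")
        if not self.duration > 0:
            raise ValidationError(
                f"interval duration must be > 0, got {self.duration}"
            )
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"unknown interval label {self.label!r}; expected one of "
                f"{sorted(VALID_LABELS)}"
            )

    @property
    def end(self) -> float:
        """Exclusive end time in seconds."""
        return self.onset + self.duration

    def overlaps(self, other: "Interval") -> bool:
        """True when the half-open spans intersect (abutting does not count)."""
        return self.onset < other.end and other.onset < self.end


@dataclass
class AnnotationTrack:
    """An ordered collection of :class:`Interval` for one recording.

    Intervals are kept sorted by onset; intervals that share both label and
    channel must not overlap (half-open convention, so abutting is fine).
    """

    intervals: list[Interval] = field(default_factory=list)
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.onset, iv.end, iv.label, iv.channel)
        )
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        last_end: dict[tuple[str, str], float] = {}
        for iv in self.intervals:
            key = (iv.label, iv.channel)
            if key in last_end and iv.onset < last_end[key] - 1e-12:
                raise ValidationError(
                    f"overlapping {iv.label!r} intervals on channel "
                    f"{iv.channel!r} at onset {iv.onset}"
                )
            last_end[key] = max(last_end.get(key, -np.inf), iv.end)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTrack):
            return NotImplemented
        return (
            self.recording_id == other.recording_id
            and self.intervals == other.intervals
        )

    def select(self, label: str | None = None, channel: str | None = None) -> list[Interval]:
        """Intervals filtered by label and/or channel."""
        out = self.intervals
        if label is not None:
            out = [iv for iv in out if iv.label == label]
        if channel is not None:
            out = [iv for iv in out if iv.channel == channel]
        return out

    def total_duration(self, label: str, channel: str = "all") -> float:
        """Sum of durations over intervals with the given label and channel."""
        return float(sum(iv.duration for iv in self.select(label, channel)))

    @property
    def span_end(self) -> float:
        """Latest interval end, or 0 for an empty track."""
        return max((iv.end for iv in self.intervals), default=0.0)


@dataclass
class EEGRecording:
    """A multichannel EEG signal in microvolts.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts; all values finite.
    fs : float
        Sampling frequency in Hz, > 0.
    channel_labels : list of str
        Ordered channel names (e.g. ``Fp1, Fp2, F7, F8`` for the frontal
        montage of a forehead depth-of-anesthesia monitor).
    start_offset : float
        Seconds; the recording's own clock is nevertheless t = 0 based.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim == 1:
            self.signal = self.signal[np.newaxis, :]
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs}")
        if self.signal.shape[0] < 1:
            raise ValidationError("recording must have at least one channel")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        bad = ~np.isfinite(self.signal)
        if bad.any():
            ch_idx, row_idx = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite amplitude in channel "
                f"{self.channel_labels[ch_idx]!r} at sample {row_idx}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.signal.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Single-channel view by label."""
        try:
            idx = self.channel_labels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.signal[idx]


# ---------------------------------------------------------------------------
# Signal I/O


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".edf":
        return "edf"
    if ext in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format from extension {ext!r}; pass format=")


def read_recording(path: str, format: str | None = None, fs: float | None = None) -> EEGRecording:
    """Read a multichannel EEG recording from EDF or CSV.

    Parameters
    ----------
    path : str
        File path; must exist.
    format : {"edf", "csv"}, optional
        Inferred from the file extension when omitted.
    fs : float, optional
        Sampling rate for CSV input.  Overrides (and is otherwise supplied
        by) the ``# fs=<Hz>`` comment line at the top of the file.

    Returns
    -------
    EEGRecording
        Amplitudes in microvolts.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv_signal(path, fs=fs)
    raise ValueError(f"unknown format {fmt!r}")


def _read_edf(path: str) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for corrupt files
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE loads in volts
    rec = EEGRecording(
        signal=data_uv, fs=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names)
    )
    return rec


def _read_csv_signal(path: str, fs: float | None = None) -> EEGRecording:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
        file_fs: float | None = None
        if first.startswith("#"):
            # sidecar comment of the form "# fs=178"
            stripped = first.lstrip("#").strip()
            if stripped.startswith("fs"):
                file_fs = float(stripped.split("=", 1)[1])
            header_line = fh.readline()
        else:
            header_line = first
        labels = [c.strip() for c in header_line.rstrip("\n").split(",")]
        rows: list[list[str]] = list(csv.reader(fh))
    rate = fs if fs is not None else file_fs
    if rate is None:
        raise ValidationError(
            f"{path}: no sampling rate; add a '# fs=<Hz>' first line or pass fs="
        )
    if not rows:
        raise ValidationError(f"{path}: no samples")
    n_cols = len(labels)
    data = np.empty((n_cols, len(rows)), dtype=np.float64)
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise ValidationError(
                f"{path}: row {i + 1} has {len(row)} values, expected {n_cols}"
            )
        for j, cell in enumerate(row):
            try:
                val = float(cell)
            except ValueError:
                val = np.nan
            if not np.isfinite(val):
                raise ValidationError(
                    f"{path}: non-finite value at row {i + 1}, channel {labels[j]!r}"
                )
            data[j, i] = val
    return EEGRecording(signal=data, fs=float(rate), channel_labels=labels)


def write_recording_csv(rec: EEGRecording, path: str) -> None:
    """Write a recording as a CSV signal matrix with a ``# fs=`` sidecar line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.signal.T, delimiter=",", fmt="%.6f")


# ---------------------------------------------------------------------------
# Annotation I/O

_ANNOT_COLUMNS = ("onset_s", "duration_s", "label", "channel")


def read_annotations(path: str, recording_id: str = "") -> AnnotationTrack:
    """Read a labeled-interval table (``onset_s,duration_s,label,channel``).

    Rows may appear in any order; the returned track is sorted by onset.
    Unknown labels and non-positive durations raise :class:`ValidationError`.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    with open(path, "r", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c.strip() for c in reader.fieldnames
        ] != list(_ANNOT_COLUMNS):
            raise ValidationError(
                f"{path}: expected header {','.join(_ANNOT_COLUMNS)!r}, "
                f"got {reader.fieldnames}"
            )
        intervals = []
        for i, row in enumerate(reader):
            try:
                iv = Interval(
                    onset=float(row["onset_s"]),
                    duration=float(row["duration_s"]),
                    label=row["label"].strip(),
                    channel=row["channel"].strip(),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
            intervals.append(iv)
    return AnnotationTrack(intervals=intervals, recording_id=recording_id)


def write_annotations(track: AnnotationTrack, path: str) -> None:
    """Write an annotation track as CSV.

    Onsets and durations are written as 6-decimal fixed point so that a
    written file is byte-stable and round-trips through
    :func:`read_annotations` to an equal track.
    """
    try:
        fh = open(path, "w", newline="")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    with fh:
        fh.write(",".join(_ANNOT_COLUMNS) + "\n")
        for iv in track.intervals:
            fh.write(f"{iv.onset:.6f},{iv.duration:.6f},{iv.label},{iv.channel}\n")
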