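"""Reading and writing EEG recordings (EDF) and seizure annotations (CSV).

The in-memory containers are deliberately small:

* :class:`Recording` — a multichannel scalp EEG block in microvolts with a
  single sampling frequency and ordered 10-20 channel labels.
* :class:`AnnotationSet` — labelled half-open time intervals
  ``[onset, offset)`` in seconds from recording start.  Two labels are used:
  ``"seizure"`` for generalized spike-and-wave discharges and ``"abnormal"``
  for intervals of abnormal activity used in fragmentation analysis.

EDF files are read through :func:`mne.io.read_raw_edf`.  Writing uses a
minimal 16-bit EDF encoder implemented here (one 1-second data record per
second of signal, physical range chosen per channel to cover the data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "AnnotationSet",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
]

_ANNOTATION_LABELS = ("seizure", "abnormal")


@dataclass
class Recording:
    """Multichannel EEG recording.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject.
    fs : float
        Sampling frequency in Hz.
    channels : list of str
        Ordered channel labels (10-20 names such as ``"Fp1"``).
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    subject_id: str
    fs: float
    channels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, labels) -> np.ndarray:
        """Row indices of ``labels`` (case-insensitive) in ``data``."""
        lut = {c.lower(): i for i, c in enumerate(self.channels)}
        try:
            return np.array([lut[str(l).lower()] for l in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err} not present in recording") from None


@dataclass
class AnnotationSet:
    """Labelled half-open intervals ``[onset_s, offset_s)`` for one subject."""

    subject_id: str
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b), str(lab)) for a, b, lab in self.intervals]
        for a, b, lab in ivs:
            if not a < b:
                raise ValueError(f"interval [{a}, {b}) has nonpositive length")
            if lab not in _ANNOTATION_LABELS:
                raise ValueError(f"unknown annotation label {lab!r}")
        for lab in _ANNOTATION_LABELS:
            same = sorted((a, b) for a, b, l in ivs if l == lab)
            for (a1, b1), (a2, _) in zip(same, same[1:]):
                if a2 < b1:
                    raise ValueError(
                        f"overlapping {lab!r} intervals: [{a1}, {b1}) and onset {a2}"
                    )
        self.intervals = sorted(ivs)

    def by_label(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab in self.intervals if lab == label]

    @property
    def seizures(self) -> list[tuple[float, float]]:
        return self.by_label("seizure")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a :class:`Recording` as a 16-bit EDF file.

    One data record per second; each channel's physical range is the integer
    envelope of its data, so the quantization step is
    ``(phys_max - phys_min) / (2**16 - 1)`` microvolts.  Recordings whose
    length is not a whole number of seconds are zero-padded to the next
    second (EDF stores whole data records only).
    """
    if recording.n_channels == 0 or recording.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    if not np.all(np.isfinite(recording.data)):
        raise ValueError("recording contains non-finite samples")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling frequency")
    fs = int(round(fs))

    n_rec = math.ceil(recording.n_samples / fs)
    n_ch = recording.n_channels
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : recording.n_samples] = recording.data

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    flat = pmax - pmin < 1
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field(recording.subject_id[:80], 80)
    header += _ascii_field("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (n_ch + 1), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_rec, 8)
    header += _ascii_field(1, 8)
    header += _ascii_field(n_ch, 4)

    def per_signal(values, width):
        out = bytearray()
        for v in values:
            out += _ascii_field(v, width)
        return out

    header += per_signal([c[:16] for c in recording.channels], 16)
    header += per_signal([""] * n_ch, 80)
    header += per_signal(["uV"] * n_ch, 8)
    header += per_signal([f"{v:.0f}" for v in pmin], 8)
    header += per_signal([f"{v:.0f}" for v in pmax], 8)
    header += per_signal([_DIG_MIN] * n_ch, 8)
    header += per_signal([_DIG_MAX] * n_ch, 8)
    header += per_signal([""] * n_ch, 80)
    header += per_signal([fs] * n_ch, 8)
    header += per_signal([""] * n_ch, 32)

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint((data - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path, subject_id: str | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # mne raises a mix of types for malformed files
        raise ValueError(f"unreadable EDF file {path}: {err}") from err
    if len(raw.ch_names) == 0:
        raise ValueError(f"EDF file {path} contains no channels")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    return Recording(
        subject_id=subject_id or path.stem,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        data=data_uv,
    )


def edf_quantization_step(recording: Recording) -> np.ndarray:
    """Per-channel quantization step the EDF writer will use, in microvolts."""
    pmin = np.floor(recording.data.min(axis=1))
    pmax = np.ceil(recording.data.max(axis=1))
    flat = pmax - pmin < 1
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    return (pmax - pmin) / (_DIG_MAX - _DIG_MIN)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def read_annotations(path) -> dict[str, AnnotationSet]:
    """Read annotation CSV into one :class:`AnnotationSet` per subject.

    Expected columns: ``subject_id, onset_s, duration_s, label``.  Intervals
    are stored half-open as ``[onset, onset + duration)``.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "onset_s", "duration_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(required)}")
    if (df["duration_s"] <= 0).any():
        raise ValueError("annotation durations must be positive")
    out: dict[str, AnnotationSet] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        intervals = [
            (float(r.onset_s), float(r.onset_s) + float(r.duration_s), str(r.label))
            for r in grp.itertuples()
        ]
        out[str(sid)] = AnnotationSet(subject_id=str(sid), intervals=intervals)
    return out


def write_annotations(annsets, path) -> None:
    """Write one or several :class:`AnnotationSet` objects to CSV."""
    if isinstance(annsets, AnnotationSet):
        annsets = [annsets]
    elif isinstance(annsets, dict):
        annsets = list(annsets.values())
    rows = [
        {
            "subject_id": s.subject_id,
            "onset_s": a,
            "duration_s": b - a,
            "label": lab,
        }
        for s in annsets
        for a, b, lab in s.intervals
    ]
    pd.DataFrame(rows, columns=["subject_id", "onset_s", "duration_s", "label"]).to_csv(
        path, index=False
    )
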