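"""Sliding-window segmentation, window taxonomy and classifier features.

The recording is partitioned into 1-s windows advancing by 0.5 s.  Each
window gets a taxonomy code describing its position relative to annotated
seizures (all intervals half-open, overlap = nonempty interior intersection):

====  ==========================================================
code  meaning
====  ==========================================================
0     touches no seizure (interictal)
1     first window partially overlapping a seizure onset
2     second partially overlapping window at the onset
3     first window fully embedded in the seizure
4     embedded windows between the first and the last
5     last embedded window
6     second-to-last partially overlapping window at the offset
7     last partially overlapping window at the offset
====  ==========================================================

With the default geometry a generic seizure has exactly two partial windows
at each boundary; when the onset (offset) falls on the window grid only one
partial window exists there and it takes code 1 (code 7).  A seizure shorter
than one window has no embedded windows at all and its partial windows take
codes 1, 2, 6, 7 in order (3-5 absent).  For detector evaluation any window
with a nonzero code counts as ictal ground truth.

The two classifier features per window m are the global synchronization
index gamma-bar and the normalized amplitude ``Am(n) = Am / Aref`` where
``Am`` is the mean absolute signal over the active channel subset and window
samples and ``Aref`` the same statistic over a 30-s interictal reference at
the start of the recording.  The normalization removes inter-subject
amplitude differences (age, electrode impedance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .preprocessing import FilterSpec, preprocess_array
from .readwrite import AnnotationSet, Recording
from .sync import get_subset, window_global_gamma
from .wavelet import cwt, phase

__all__ = [
    "segment_starts",
    "label_segments",
    "AmplitudeReference",
    "reference_amplitude",
    "extract_features",
]

#: Columns of the per-window feature frame produced by :func:`extract_features`.
FEATURE_COLUMNS = ["subject_id", "start_s", "gamma", "amp_norm", "taxonomy", "label"]


def segment_starts(duration_s: float, window_s: float = 1.0, step_s: float = 0.5) -> np.ndarray:
    """Window start times 0, step, 2*step, ... with last start <= duration - window."""
    if duration_s < window_s:
        return np.array([])
    n = int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1
    return np.arange(n) * step_s


def label_segments(
    starts: np.ndarray,
    annotations: AnnotationSet | list[tuple[float, float]],
    window_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Taxonomy codes 0-7 and binary ictal labels for each window.

    Returns ``(taxonomy, is_ictal)``; ``is_ictal`` is True exactly where the
    taxonomy code is nonzero.
    """
    starts = np.asarray(starts, dtype=float)
    ends = starts + window_s
    taxonomy = np.zeros(starts.size, dtype=int)
    seizures = (
        annotations.seizures if isinstance(annotations, AnnotationSet) else list(annotations)
    )
    for onset, offset in sorted(seizures):
        overlap = (starts < offset) & (ends > onset)
        idx = np.nonzero(overlap)[0]
        if idx.size == 0:
            continue
        embedded = idx[(starts[idx] >= onset) & (ends[idx] <= offset)]
        partial = [i for i in idx if i not in set(embedded)]
        leading = [i for i in partial if starts[i] < onset]
        trailing = [i for i in partial if ends[i] > offset and i not in leading]
        codes: dict[int, int] = {}
        if embedded.size:
            for i in embedded:
                codes[i] = 4
            codes[embedded[0]] = 3
            codes[embedded[-1]] = 5
            for rank, i in enumerate(leading):
                codes[i] = 1 if rank == 0 else 2
            for rank, i in enumerate(reversed(trailing)):
                codes[i] = 7 if rank == 0 else 6
        else:
            # degenerate: seizure shorter than one window, partials only;
            # boundary codes in order (1, 2 from the front; 7, 6 from the back)
            order = sorted(partial)
            codes[order[0]] = 1
            if len(order) >= 2:
                codes[order[-1]] = 7
            if len(order) >= 3:
                codes[order[1]] = 2
            if len(order) >= 4:
                codes[order[-2]] = 6
        for i, c in codes.items():
            if taxonomy[i] == 0 and c != 0:
                taxonomy[i] = c
    return taxonomy, taxonomy != 0


@dataclass(frozen=True)
class AmplitudeReference:
    """Reference amplitude (microvolts) and the interval it was taken from."""

    a_ref: float
    source_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.a_ref > 0:
            raise ValueError("reference amplitude must be positive")


def reference_amplitude(
    recording: Recording,
    subset: tuple[str, ...] | str = "S19",
    annotations: AnnotationSet | None = None,
    ref_window_s: float = 30.0,
) -> AmplitudeReference:
    """Mean absolute amplitude over a seizure-free reference window.

    Uses ``[0, ref_window_s)`` when it is seizure-free (recordings are assumed
    to start interictally); otherwise falls back to the earliest seizure-free
    stretch of the same length, scanning on the 0.5-s grid.
    """
    if isinstance(subset, str):
        subset = get_subset(subset)
    if recording.duration_s < ref_window_s:
        raise ValueError(
            f"recording ({recording.duration_s:.1f} s) shorter than the "
            f"{ref_window_s:.0f}-s reference window"
        )
    seizures = annotations.seizures if annotations is not None else []

    def seizure_free(t0: float) -> bool:
        return all(not (t0 < b and t0 + ref_window_s > a) for a, b in seizures)

    start = None
    for t0 in np.arange(0.0, recording.duration_s - ref_window_s + 1e-9, 0.5):
        if seizure_free(t0):
            start = float(t0)
            break
    if start is None:
        raise ValueError("no seizure-free stretch long enough for the reference amplitude")
    rows = recording.channel_index(subset)
    i0 = int(round(start * recording.fs))
    i1 = int(round((start + ref_window_s) * recording.fs))
    a_ref = float(np.mean(np.abs(recording.data[rows, i0:i1])))
    return AmplitudeReference(a_ref=a_ref, source_window=(start, start + ref_window_s))


def _window_mean_abs(x: np.ndarray, fs: float, starts: np.ndarray, window_s: float) -> np.ndarray:
    """Mean |x| over channels and window samples, one value per window."""
    absmean = np.abs(x).mean(axis=0)
    csum = np.concatenate(([0.0], np.cumsum(absmean)))
    i0 = np.ceil(starts * fs - 1e-9).astype(int)
    i1 = np.ceil((starts + window_s) * fs - 1e-9).astype(int)
    return (csum[i1] - csum[i0]) / (i1 - i0)


def extract_features(
    recording: Recording,
    annotations: AnnotationSet | None = None,
    config: RunConfig | None = None,
    *,
    filter_spec: FilterSpec | None = FilterSpec(),
) -> pd.DataFrame:
    """Full per-window feature frame for one subject.

    Applies preprocessing (pass ``filter_spec=None`` to skip), computes the
    wavelet phases of the active channel subset over the whole recording,
    then per window the global synchronization index and the normalized
    amplitude, plus taxonomy code and binary label from the annotations.

    Returns a DataFrame with columns ``subject_id, start_s, gamma, amp_norm,
    taxonomy, label``.
    """
    config = config or RunConfig()
    subset = get_subset(config.subset_name)
    rows = recording.channel_index(subset)
    fs = recording.fs

    x = recording.data[rows]
    if filter_spec is not None:
        x = preprocess_array(x, fs, filter_spec)
    proc = Recording(recording.subject_id, fs, list(subset), x)

    starts = segment_starts(recording.duration_s, config.window_s, config.step_s)
    if starts.size == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)

    taxonomy, is_ictal = label_segments(
        starts, annotations if annotations is not None else [], config.window_s
    )
    ref = reference_amplitude(proc, subset, annotations, config.ref_window_s)

    phi = phase(cwt(x, fs, config.fc, config.fa))
    gamma = window_global_gamma(phi, fs, starts, config.window_s)
    amp = _window_mean_abs(x, fs, starts, config.window_s) / ref.a_ref

    return pd.DataFrame(
        {
            "subject_id": recording.subject_id,
            "start_s": starts,
            "gamma": gamma,
            "amp_norm": amp,
            "taxonomy": taxonomy,
            "label": is_ictal,
        }
    )
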