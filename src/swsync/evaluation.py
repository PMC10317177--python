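"""Detection metrics (OVR, PERR, FP, MT) and seizure fragmentation (SFRAG).

Window decisions (1-s windows, 0.5-s step) are first OR-merged onto a 0.5-s
timeline: each half-interval of the recording is ictal if at least one of the
(up to two) windows covering it was classified ictal.  On that timeline:

* OVR — percentage of the annotated seizure time covered by ictal timeline,
* PERR — percentage of the non-seizure time falsely marked ictal.

FP (number of interictal windows classified ictal) and MT (number of maximal
consecutive runs of such windows) are counted on the raw window decisions,
before merging.

Seizure fragmentation quantifies interrupted (disorganized) discharges:
the detector, with post-processing disabled, is applied to an interval of
abnormal activity and

    SFRAG = 100% - OVR

of the merged ictal timeline within that interval.  Gaps in the ictal rhythm
shorter than about 0.5 s are below the resolution of the 1-s analysis window
and generally go undetected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "merge_timeline",
    "timeline_intervals",
    "ovr",
    "perr",
    "count_fp_mt",
    "sfrag",
    "SubjectMetrics",
    "subject_metrics",
]


def merge_timeline(window_decisions, *, step_s: float = 0.5) -> np.ndarray:
    """OR-merge window decisions into a binary 0.5-s half-interval timeline.

    With n windows of length 2*step starting at 0, step, ..., the timeline has
    n + 1 half-intervals; half-interval i is ictal iff window i or window i-1
    is ictal.
    """
    d = np.asarray(window_decisions, dtype=bool)
    if d.size == 0:
        return np.zeros(0, dtype=bool)
    halves = np.zeros(d.size + 1, dtype=bool)
    halves[:-1] |= d
    halves[1:] |= d
    return halves


def timeline_intervals(timeline, *, step_s: float = 0.5) -> list[tuple[float, float]]:
    """Maximal ictal intervals [start, end) in seconds of a binary timeline."""
    t = np.asarray(timeline, dtype=bool)
    if t.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], t, [False])).astype(int)))
    return [(edges[i] * step_s, edges[i + 1] * step_s) for i in range(0, edges.size, 2)]


def _intersection(ivs_a, ivs_b) -> float:
    total = 0.0
    for a0, a1 in ivs_a:
        for b0, b1 in ivs_b:
            total += max(0.0, min(a1, b1) - max(a0, b0))
    return total


def ovr(timeline, seizure_intervals, *, step_s: float = 0.5) -> float:
    """Relative overlap (%) of the ictal timeline with the seizure intervals."""
    seizure_intervals = list(seizure_intervals)
    if not seizure_intervals:
        return float("nan")
    total = sum(b - a for a, b in seizure_intervals)
    ictal = timeline_intervals(timeline, step_s=step_s)
    return float(np.clip(100.0 * _intersection(ictal, seizure_intervals) / total, 0.0, 100.0))


def perr(timeline, seizure_intervals, total_duration_s: float, *, step_s: float = 0.5) -> float:
    """Relative duration (%) of false-positive ictal time outside seizures."""
    seizure_intervals = list(seizure_intervals)
    seizure_time = sum(b - a for a, b in seizure_intervals)
    non_seizure = total_duration_s - seizure_time
    if non_seizure <= 0:
        raise ValueError("no non-seizure time in the recording")
    ictal = timeline_intervals(timeline, step_s=step_s)
    ictal_time = sum(b - a for a, b in ictal)
    inside = _intersection(ictal, seizure_intervals)
    return float(np.clip(100.0 * (ictal_time - inside) / non_seizure, 0.0, 100.0))


def count_fp_mt(window_decisions, taxonomy) -> tuple[int, int]:
    """False-positive windows and maximal trains of them.

    FP counts windows with taxonomy 0 (truly interictal) classified ictal;
    MT counts maximal runs of consecutive such windows.
    """
    d = np.asarray(window_decisions, dtype=bool)
    tax = np.asarray(taxonomy, dtype=int)
    if d.shape != tax.shape:
        raise ValueError("decisions and taxonomy must be aligned")
    mis = d & (tax == 0)
    fp = int(mis.sum())
    mt = int(np.sum(np.diff(np.concatenate(([0], mis.astype(int)))) == 1))
    return fp, mt


def sfrag(
    window_decisions,
    window_starts,
    interval: tuple[float, float],
    *,
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> float:
    """Seizure fragmentation (%) of one abnormal-activity interval.

    ``window_decisions`` must come from the detector with post-processing
    disabled.  Only windows overlapping the interval contribute; the merged
    ictal timeline is intersected with the interval and
    SFRAG = 100 - 100 * covered / interval_length.  Intervals shorter than one
    window are below resolution and yield NaN.
    """
    a, b = float(interval[0]), float(interval[1])
    if b - a < window_s:
        return float("nan")
    d = np.asarray(window_decisions, dtype=bool)
    starts = np.asarray(window_starts, dtype=float)
    if d.shape != starts.shape:
        raise ValueError("decisions and window starts must be aligned")
    order = np.argsort(starts)
    d, starts = d[order], starts[order]
    sel = (starts < b) & (starts + window_s > a)
    if not sel.any():
        return 100.0
    # contiguous window block covering the interval
    idx = np.flatnonzero(sel)
    block = d[idx[0] : idx[-1] + 1]
    t0 = starts[idx[0]]
    timeline = merge_timeline(block, step_s=step_s)
    ictal = [(t0 + s, t0 + e) for s, e in timeline_intervals(timeline, step_s=step_s)]
    covered = _intersection(ictal, [(a, b)])
    return float(np.clip(100.0 - 100.0 * covered / (b - a), 0.0, 100.0))


@dataclass
class SubjectMetrics:
    """Per-subject detection metrics."""

    subject_id: str
    ovr: float
    perr: float
    fp: int
    mt: int
    n_seizures: int
    n_detected: int

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "OVR": self.ovr,
            "PERR": self.perr,
            "FP": self.fp,
            "MT": self.mt,
            "n_seizures": self.n_seizures,
            "n_detected": self.n_detected,
        }


def subject_metrics(
    frame: pd.DataFrame,
    decisions,
    seizure_intervals,
    total_duration_s: float,
    *,
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> SubjectMetrics:
    """All detection metrics for one subject.

    ``frame`` is the subject's feature frame (sorted by window start) and
    ``decisions`` the aligned binary classifications.  A seizure counts as
    detected if any window overlapping it is classified ictal.
    """
    frame = frame.sort_values("start_s")
    d = np.asarray(decisions, dtype=bool)
    starts = frame["start_s"].to_numpy(dtype=float)
    timeline = merge_timeline(d, step_s=step_s)
    seizure_intervals = list(seizure_intervals)
    n_det = 0
    for a, b in seizure_intervals:
        sel = (starts < b) & (starts + window_s > a)
        if d[sel].any():
            n_det += 1
    return SubjectMetrics(
        subject_id=str(frame["subject_id"].iloc[0]),
        ovr=ovr(timeline, seizure_intervals, step_s=step_s),
        perr=perr(timeline, seizure_intervals, total_duration_s, step_s=step_s),
        fp=count_fp_mt(d, frame["taxonomy"].to_numpy())[0],
        mt=count_fp_mt(d, frame["taxonomy"].to_numpy())[1],
        n_seizures=len(seizure_intervals),
        n_detected=n_det,
    )
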