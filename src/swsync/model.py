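"""Model/Results interface over the detection pipeline.

:class:`AbsenceDetector` is built from a cohort of per-window feature frames
(optionally computed on the fly from recordings and annotations); its
:meth:`~AbsenceDetector.fit` runs leave-one-subject-out cross-validation and
returns an :class:`AbsenceDetectionResults` carrying the per-subject window
decisions, detection metrics and a printable summary, plus fragmentation
analysis of annotated intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detector as _det
from . import evaluation as _ev
from .config import RunConfig
from .readwrite import AnnotationSet, Recording
from .segmentation import extract_features

__all__ = ["AbsenceDetector", "AbsenceDetectionResults"]


class AbsenceDetector:
    """k-NN absence-seizure detector over a cohort of windowed EEG features.

    Parameters
    ----------
    features : DataFrame
        Concatenated per-subject feature frames (columns ``subject_id,
        start_s, gamma, amp_norm, taxonomy, label``).
    config : RunConfig, optional
        Pipeline parameters.
    annotations : dict of {subject_id: AnnotationSet}, optional
        Needed for the timeline metrics (OVR/PERR, seizure counts).
    durations : dict of {subject_id: float}, optional
        Recording durations in seconds; inferred from the window grid when
        absent.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        config: RunConfig | None = None,
        *,
        annotations: dict[str, AnnotationSet] | None = None,
        durations: dict[str, float] | None = None,
    ) -> None:
        self.features = features.reset_index(drop=True)
        self.config = config or RunConfig()
        self.annotations = annotations or {}
        if durations is None:
            durations = {}
            for sid, grp in self.features.groupby("subject_id"):
                durations[str(sid)] = float(grp["start_s"].max()) + self.config.window_s
        self.durations = durations

    @classmethod
    def from_recordings(
        cls,
        recordings: list[Recording],
        annotations: dict[str, AnnotationSet] | list[AnnotationSet],
        config: RunConfig | None = None,
    ) -> "AbsenceDetector":
        """Compute the feature frames from raw recordings and build the model."""
        config = config or RunConfig()
        if not isinstance(annotations, dict):
            annotations = {a.subject_id: a for a in annotations}
        frames, durations = [], {}
        for rec in recordings:
            ann = annotations.get(rec.subject_id)
            frames.append(extract_features(rec, ann, config))
            durations[rec.subject_id] = rec.duration_s
        return cls(
            pd.concat(frames, ignore_index=True),
            config,
            annotations=annotations,
            durations=durations,
        )

    def fit(self, *, postprocess: bool = True) -> "AbsenceDetectionResults":
        """Run leave-one-subject-out cross-validation."""
        raw = _det.loocv(self.features, self.config, apply_postprocess=False)
        decisions = (
            {sid: _det.postprocess(d) for sid, d in raw.items()} if postprocess else raw
        )
        return AbsenceDetectionResults(self, decisions, raw_decisions=raw, postprocessed=postprocess)


class AbsenceDetectionResults:
    """LOOCV detection results: decisions, metrics and summaries."""

    def __init__(
        self,
        model: AbsenceDetector,
        decisions: dict[str, np.ndarray],
        *,
        raw_decisions: dict[str, np.ndarray] | None = None,
        postprocessed: bool = True,
    ) -> None:
        self.model = model
        self.decisions = decisions
        self.raw_decisions = raw_decisions or decisions
        self.postprocessed = postprocessed
        self._metrics: pd.DataFrame | None = None

    def _subject_frame(self, sid: str) -> pd.DataFrame:
        f = self.model.features
        return f[f["subject_id"] == sid].sort_values("start_s")

    @property
    def metrics(self) -> pd.DataFrame:
        """Per-subject OVR, PERR, FP, MT and seizure detection counts."""
        if self._metrics is None:
            rows = []
            for sid, dec in self.decisions.items():
                frame = self._subject_frame(sid)
                ann = self.model.annotations.get(sid)
                seizures = ann.seizures if ann is not None else []
                m = _ev.subject_metrics(
                    frame,
                    dec,
                    seizures,
                    self.model.durations[sid],
                    window_s=self.model.config.window_s,
                    step_s=self.model.config.step_s,
                )
                rows.append(m.as_dict())
            self._metrics = pd.DataFrame(rows).set_index("subject_id").sort_index()
        return self._metrics

    @property
    def seizure_detection_rate(self) -> float:
        """Fraction of annotated seizures with at least one ictal window."""
        m = self.metrics
        total = m["n_seizures"].sum()
        if total == 0:
            return float("nan")
        return float(m["n_detected"].sum() / total)

    def fragmentation(self, intervals: dict[str, list[tuple[float, float]]] | None = None) -> pd.DataFrame:
        """SFRAG per abnormal-activity interval (raw, non-post-processed decisions).

        ``intervals`` maps subject to intervals; defaults to the annotated
        seizure intervals.
        """
        if intervals is None:
            intervals = {
                sid: ann.seizures for sid, ann in self.model.annotations.items()
            }
        rows = []
        for sid, ivs in intervals.items():
            if sid not in self.raw_decisions:
                continue
            frame = self._subject_frame(sid)
            starts = frame["start_s"].to_numpy(dtype=float)
            for a, b in ivs:
                rows.append(
                    {
                        "subject_id": sid,
                        "onset_s": a,
                        "offset_s": b,
                        "sfrag": _ev.sfrag(
                            self.raw_decisions[sid],
                            starts,
                            (a, b),
                            window_s=self.model.config.window_s,
                            step_s=self.model.config.step_s,
                        ),
                    }
                )
        return pd.DataFrame(rows, columns=["subject_id", "onset_s", "offset_s", "sfrag"])

    def summary(self) -> str:
        """Printable cohort summary (per-subject rows and mean +/- SD)."""
        m = self.metrics
        cfg = self.model.config
        lines = [
            "Absence-seizure detection (LOOCV, k-NN on gamma-bar / normalized amplitude)",
            "=" * 76,
            f"subjects: {len(m):d}    subset: {cfg.subset_name}    "
            f"fc = {cfg.fc:g} Hz    fa = {cfg.fa:g} Hz",
            f"window {cfg.window_s:g} s / step {cfg.step_s:g} s    k = {cfg.knn_k}    "
            f"post-processing: {'on' if self.postprocessed else 'off'}",
            "-" * 76,
            m.to_string(float_format=lambda v: f"{v:0.2f}"),
            "-" * 76,
            f"OVR  = {m['OVR'].mean():0.2f} +/- {m['OVR'].std():0.2f} %",
            f"PERR = {m['PERR'].mean():0.3f} +/- {m['PERR'].std():0.3f} %",
            f"seizures detected: {int(m['n_detected'].sum())}/{int(m['n_seizures'].sum())} "
            f"({100 * self.seizure_detection_rate:0.1f} %)",
        ]
        return "\n".join(lines)

    def plot_features(self, ax=None):
        """Scatter of the (gamma-bar, normalized amplitude) feature plane."""
        from .plotting import plot_feature_scatter

        return plot_feature_scatter(self.model.features, ax=ax)

    def plot_timeline(self, subject_id: str, ax=None):
        """Detection function of one subject against its annotations."""
        from .plotting import plot_detection_timeline

        frame = self._subject_frame(subject_id)
        ann = self.model.annotations.get(subject_id)
        return plot_detection_timeline(
            frame["start_s"].to_numpy(),
            self.decisions[subject_id],
            ann.seizures if ann is not None else [],
            ax=ax,
        )
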