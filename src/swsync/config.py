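"""Run configuration shared by the analysis pipeline and the CLI."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of the synchronization/detection pipeline.

    fc, fa
        Morlet center frequency and analysis pseudo-frequency in Hz.  The
        defaults (1 Hz, 12 Hz) maximize the ictal/interictal contrast of the
        global synchronization index for spike-and-wave EEG.
    window_s, step_s
        Sliding-window length and step in seconds (1 s windows, 0.5 s step,
        i.e. half overlap, emulating live stream analysis).
    subset_name
        Channel subset: ``S19`` (full 10-20 montage), ``S12``, ``S6`` or
        ``S4`` (reduced headsets).
    ref_window_s
        Length of the interictal reference segment used to normalize the
        amplitude feature.
    knn_k, class_ratio, threshold_quantile
        Detector parameters: number of neighbours, interictal:ictal training
        ratio, and the interictal quantile defining the synchronization
        threshold for admitting ictal training windows.
    """

    fc: float = 1.0
    fa: float = 12.0
    window_s: float = 1.0
    step_s: float = 0.5
    subset_name: str = "S19"
    ref_window_s: float = 30.0
    knn_k: int = 10
    class_ratio: int = 3
    threshold_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("require 0 < step_s <= window_s")
        if not (self.fa > self.fc > 0):
            raise ValueError("require fa > fc > 0")
        if not 0 < self.threshold_quantile < 1:
            raise ValueError("threshold_quantile must lie in (0, 1)")
        if self.knn_k < 1 or self.class_ratio < 1:
            raise ValueError("knn_k and class_ratio must be >= 1")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
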