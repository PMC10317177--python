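"""k-NN absence-seizure detector: training-set construction, fitting,
leave-one-subject-out cross-validation and decision post-processing.

Training rows come from a cohort feature frame (see
:mod:`swsync.segmentation`).  Ictal training rows are the windows fully
embedded in seizures (taxonomy 3-5) whose global synchronization exceeds the
95th percentile of the interictal synchronization distribution of the
training subjects; windows that only partially overlap a seizure never enter
the training set (they still count as ictal ground truth at test time).
Because interictal windows vastly outnumber ictal ones, a seeded uniform
subsample at a 3:1 interictal:ictal ratio balances the classes.

The classifier is a plain k-nearest-neighbour vote (k = 10, Euclidean
distance on per-feature standardized coordinates, no distance weighting).
With k even a tie is possible; ties resolve to interictal, biasing against
false positives.

Post-processing relabels every isolated ictal window (no ictal neighbour on
either side) as interictal, so the shortest surviving detection is two
consecutive windows = 1.5 s of merged timeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .config import RunConfig

__all__ = [
    "interictal_threshold",
    "TrainingSet",
    "build_training_set",
    "KnnDetector",
    "fit",
    "loocv",
    "postprocess",
    "save_model",
    "load_model",
]

_FEATURES = ["gamma", "amp_norm"]
_EMBEDDED_CODES = (3, 4, 5)


def interictal_threshold(interictal_gammas, q: float = 0.95) -> float:
    """Empirical q-quantile (linear interpolation) of interictal gamma-bar."""
    g = np.asarray(interictal_gammas, dtype=float)
    g = g[np.isfinite(g)]
    if g.size < 20:
        raise ValueError(f"need at least 20 interictal windows, got {g.size}")
    return float(np.quantile(g, q))


@dataclass
class TrainingSet:
    """Feature rows, labels, row provenance and the fitted scaler."""

    X: np.ndarray  # (n_rows, 2): gamma, amp_norm (unscaled)
    y: np.ndarray  # bool, True = ictal
    subjects: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    threshold: float

    @property
    def n_ictal(self) -> int:
        return int(self.y.sum())

    @property
    def n_interictal(self) -> int:
        return int((~self.y).sum())


def build_training_set(
    cohort: pd.DataFrame,
    held_out: str | None = None,
    *,
    ratio: int = 3,
    q: float = 0.95,
    seed=None,
) -> TrainingSet:
    """Assemble the detector training set from a cohort feature frame.

    ``cohort`` concatenates per-subject feature frames; rows of ``held_out``
    are excluded entirely (LOOCV hygiene — the synchronization threshold is
    also computed on the remaining subjects only).  ``seed`` drives the
    interictal subsample and may be an int or a :class:`numpy.random.Generator`.
    """
    df = cohort if held_out is None else cohort[cohort["subject_id"] != held_out]
    if df["subject_id"].nunique() < 1 or (held_out is not None and df.empty):
        raise ValueError("no training subjects left")
    rng = np.random.default_rng(seed)

    interictal = df[df["taxonomy"] == 0]
    thr = interictal_threshold(interictal["gamma"].to_numpy(), q)
    ictal = df[df["taxonomy"].isin(_EMBEDDED_CODES) & (df["gamma"] > thr)]
    if ictal.empty:
        raise ValueError("no embedded ictal windows exceed the synchronization threshold")

    n_int = ratio * len(ictal)
    if n_int > len(interictal):
        import warnings

        warnings.warn(
            f"only {len(interictal)} interictal windows available for a "
            f"target of {n_int}; using all of them",
            stacklevel=2,
        )
        sample = interictal
    else:
        take = rng.choice(len(interictal), size=n_int, replace=False)
        sample = interictal.iloc[np.sort(take)]

    rows = pd.concat([ictal, sample])
    X = rows[_FEATURES].to_numpy(dtype=float)
    y = np.concatenate([np.ones(len(ictal), bool), np.zeros(len(sample), bool)])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return TrainingSet(
        X=X,
        y=y,
        subjects=rows["subject_id"].to_numpy(),
        mean=mean,
        scale=scale,
        threshold=thr,
    )


@dataclass
class KnnDetector:
    """Fitted k-NN window classifier."""

    training: TrainingSet
    k: int = 10
    _nn: NearestNeighbors = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.k > len(self.training.y):
            raise ValueError(f"k={self.k} exceeds {len(self.training.y)} training rows")
        Xs = (self.training.X - self.training.mean) / self.training.scale
        self._nn = NearestNeighbors(n_neighbors=self.k, metric="euclidean")
        self._nn.fit(Xs)

    def predict(self, features) -> np.ndarray:
        """Binary ictal decision per query row (ties -> interictal)."""
        F = np.asarray(features, dtype=float)
        if F.ndim == 1:
            F = F[None, :]
        if not np.all(np.isfinite(F)):
            raise ValueError("query features must be finite")
        Fs = (F - self.training.mean) / self.training.scale
        _, idx = self._nn.kneighbors(Fs)
        votes = self.training.y[idx].sum(axis=1)
        return votes > self.k / 2

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return self.predict(frame[_FEATURES].to_numpy(dtype=float))


def fit(training_set: TrainingSet, k: int = 10) -> KnnDetector:
    """Fit the k-NN detector on a prepared training set."""
    return KnnDetector(training=training_set, k=k)


def postprocess(decisions) -> np.ndarray:
    """Relabel isolated ictal windows (no ictal neighbour) as interictal."""
    d = np.asarray(decisions, dtype=bool)
    if d.size == 0:
        return d.copy()
    prev_ = np.concatenate(([False], d[:-1]))
    next_ = np.concatenate((d[1:], [False]))
    return d & (prev_ | next_)


def loocv(
    cohort: pd.DataFrame,
    config: RunConfig | None = None,
    *,
    apply_postprocess: bool = True,
) -> dict[str, np.ndarray]:
    """Leave-one-subject-out predictions for every window of every subject.

    One fold per subject: the detector is trained on the other subjects'
    features (with a per-fold seeded interictal subsample derived from
    ``config.seed``) and applied to all windows of the held-out subject.
    Returns ``{subject_id: decisions}`` with decisions aligned to the
    subject's rows in ``cohort`` (sorted by ``start_s``).
    """
    config = config or RunConfig()
    subjects = sorted(cohort["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOOCV needs at least two subjects")
    streams = np.random.SeedSequence(config.seed).spawn(len(subjects))
    out: dict[str, np.ndarray] = {}
    for sid, ss in zip(subjects, streams):
        ts = build_training_set(
            cohort,
            held_out=sid,
            ratio=config.class_ratio,
            q=config.threshold_quantile,
            seed=np.random.default_rng(ss),
        )
        model = fit(ts, k=config.knn_k)
        frame = cohort[cohort["subject_id"] == sid].sort_values("start_s")
        decisions = model.predict_frame(frame)
        if apply_postprocess:
            decisions = postprocess(decisions)
        out[sid] = decisions
    return out


# ---------------------------------------------------------------------------
# Model archive (text format) so `train` and `detect` can be separate runs
# ---------------------------------------------------------------------------


def save_model(model: KnnDetector, path) -> None:
    """Write the fitted detector to a JSON archive."""
    t = model.training
    payload = {
        "format": "swsync-knn/1",
        "k": model.k,
        "threshold": t.threshold,
        "scaler_mean": t.mean.tolist(),
        "scaler_scale": t.scale.tolist(),
        "features": _FEATURES,
        "X": t.X.tolist(),
        "y": t.y.astype(int).tolist(),
        "subjects": [str(s) for s in t.subjects],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> KnnDetector:
    """Read a detector archive written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "swsync-knn/1":
        raise ValueError(f"{path} is not a swsync k-NN model archive")
    ts = TrainingSet(
        X=np.asarray(payload["X"], dtype=float),
        y=np.asarray(payload["y"], dtype=bool),
        subjects=np.asarray(payload["subjects"]),
        mean=np.asarray(payload["scaler_mean"], dtype=float),
        scale=np.asarray(payload["scaler_scale"], dtype=float),
        threshold=float(payload["threshold"]),
    )
    return fit(ts, k=int(payload["k"]))
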