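"""Pairwise, channel and global phase-synchronization indices.

For two channels ``k, l`` with instantaneous wavelet phases ``phi_k, phi_l``
the synchronization index over a data window is the resultant length of the
phase-difference distribution,

    gamma(k, l) = sqrt(<sin d>**2 + <cos d>**2),  d = phi_k - phi_l,

equivalently ``|<exp(i d)>|``.  gamma = 1 means perfect phase locking (the
phase difference is constant), gamma = 0 means a uniform phase-difference
distribution (statistically independent channels).  Averages run over the
valid (non-NaN) phase samples of the window.

Global synchronization is the mean of the off-diagonal entries of the
pairwise matrix over a channel subset, and the channel index gamma(k) is the
mean of row ``k`` (diagonal excluded).  Channel subsets S19/S12/S6/S4 mirror
full and reduced (headband-style) 10-20 montages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .wavelet import cwt, phase

__all__ = [
    "SUBSETS",
    "get_subset",
    "pairwise_gamma",
    "SyncMatrix",
    "sync_matrix",
    "global_gamma",
    "channel_gamma",
    "window_global_gamma",
    "GridSearchResult",
    "grid_search",
]

#: Channel subsets of the 10-20 montage, from the full clinical setup down to
#: four electrodes reachable by a simple headband.
SUBSETS: dict[str, tuple[str, ...]] = {
    "S4": ("Fp1", "Fp2", "T5", "T6"),
    "S6": ("Fp1", "Fp2", "F7", "F8", "O1", "O2"),
    "S12": ("Fp1", "Fp2", "F7", "F8", "F3", "F4", "P3", "P4", "T5", "T6", "O1", "O2"),
    "S19": (
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
        "T3", "C3", "Cz", "C4", "T4",
        "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
    ),
}


def get_subset(name: str) -> tuple[str, ...]:
    try:
        return SUBSETS[name]
    except KeyError:
        raise ValueError(f"unknown channel subset {name!r}; choose from {list(SUBSETS)}") from None


def pairwise_gamma(phi_k, phi_l) -> float:
    """Synchronization index of two equal-length phase series."""
    phi_k = np.asarray(phi_k, dtype=float)
    phi_l = np.asarray(phi_l, dtype=float)
    if phi_k.shape != phi_l.shape:
        raise ValueError("phase series must have equal length")
    valid = np.isfinite(phi_k) & np.isfinite(phi_l)
    if not valid.any():
        raise ValueError("no valid phase samples in window")
    d = phi_k[valid] - phi_l[valid]
    return float(np.hypot(np.mean(np.sin(d)), np.mean(np.cos(d))))


@dataclass
class SyncMatrix:
    """Symmetric pairwise synchronization matrix over a channel subset."""

    labels: tuple[str, ...]
    values: np.ndarray
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        self.values = v


def sync_matrix(
    phases: dict[str, np.ndarray],
    subset: tuple[str, ...],
    *,
    window: tuple[float, float] | None = None,
    fs: float | None = None,
) -> SyncMatrix:
    """Pairwise gamma over all unordered channel pairs of ``subset``.

    ``phases`` maps channel label to its full phase series.  If ``window``
    (seconds) and ``fs`` are given, only samples with timestamps in
    ``[start, end)`` enter the averages.
    """
    missing = [c for c in subset if c not in phases]
    if missing:
        raise KeyError(f"phases missing for channels {missing}")

    def view(label):
        p = np.asarray(phases[label], dtype=float)
        if window is not None:
            if fs is None:
                raise ValueError("fs is required when slicing a window")
            i0 = int(np.ceil(window[0] * fs - 1e-9))
            i1 = int(np.ceil(window[1] * fs - 1e-9))
            p = p[i0:i1]
        return p

    n = len(subset)
    values = np.eye(n)
    sliced = {c: view(c) for c in subset}
    for i, j in combinations(range(n), 2):
        g = pairwise_gamma(sliced[subset[i]], sliced[subset[j]])
        values[i, j] = values[j, i] = g
    return SyncMatrix(labels=tuple(subset), values=values, window=window)


def global_gamma(matrix) -> float:
    """Mean of the N(N-1)/2 upper-triangle entries of a SyncMatrix."""
    values = matrix.values if isinstance(matrix, SyncMatrix) else np.asarray(matrix, float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two channels")
    iu = np.triu_indices(n, k=1)
    return float(values[iu].mean())


def channel_gamma(matrix, k) -> float:
    """Mean pairwise gamma of channel ``k`` with every other subset channel."""
    if isinstance(matrix, SyncMatrix):
        labels, values = matrix.labels, matrix.values
        if isinstance(k, str):
            if k not in labels:
                raise ValueError(f"channel {k!r} not in subset {labels}")
            k = labels.index(k)
    else:
        values = np.asarray(matrix, float)
    n = values.shape[0]
    if not 0 <= int(k) < n:
        raise ValueError(f"channel index {k} outside 0..{n - 1}")
    k = int(k)
    others = [l for l in range(n) if l != k]
    return float(values[k, others].mean())


def window_global_gamma(
    phases: np.ndarray,
    fs: float,
    starts: np.ndarray,
    window_s: float = 1.0,
) -> np.ndarray:
    """Global synchronization index for many windows at once.

    ``phases`` is ``(n_channels, n_samples)``; ``starts`` are window onsets in
    seconds.  Uses cumulative sums of the per-pair unit phasors, so the cost
    is one pass per channel pair instead of one per pair and window.  NaN
    phases are excluded from the averages sample-wise.
    """
    phases = np.asarray(phases, dtype=float)
    n_ch, n_samp = phases.shape
    if n_ch < 2:
        raise ValueError("need at least two channels")
    starts = np.asarray(starts, dtype=float)
    i0 = np.ceil(starts * fs - 1e-9).astype(int)
    i1 = np.ceil((starts + window_s) * fs - 1e-9).astype(int)
    if (i0 < 0).any() or (i1 > n_samp).any():
        raise ValueError("window outside the phase series")

    valid = np.isfinite(phases)
    z = np.exp(1j * np.where(valid, phases, 0.0))
    z[~valid] = 0.0

    pairs = list(combinations(range(n_ch), 2))
    gamma_sum = np.zeros(len(starts))
    pair_cnt = np.zeros(len(starts))
    for k, l in pairs:
        p = z[k] * np.conj(z[l])
        v = (valid[k] & valid[l]).astype(float)
        csum = np.concatenate(([0.0 + 0.0j], np.cumsum(p)))
        ccnt = np.concatenate(([0.0], np.cumsum(v)))
        cnt = ccnt[i1] - ccnt[i0]
        res = np.abs(csum[i1] - csum[i0])
        ok = cnt > 0
        gamma_sum[ok] += res[ok] / cnt[ok]
        pair_cnt += ok
    if (pair_cnt == 0).any():
        raise ValueError("some windows have no valid phase samples for any pair")
    return gamma_sum / pair_cnt


@dataclass
class GridSearchResult:
    """Objective surface of the (fc, fa) wavelet-parameter search."""

    fc_grid: np.ndarray
    fa_grid: np.ndarray
    objective: np.ndarray  # shape (len(fc_grid), len(fa_grid)), in percent
    best: tuple[float, float]


DEFAULT_FC_GRID = np.round(np.arange(0.6, 2.01, 0.2), 10)
DEFAULT_FA_GRID = np.arange(5.0, 20.5, 1.0)


def grid_search(
    segments,
    labels,
    fs: float,
    fc_grid=None,
    fa_grid=None,
    *,
    pad_s: float = 1.0,
) -> GridSearchResult:
    """Search (fc, fa) maximizing the ictal/interictal contrast of gamma-bar.

    ``segments`` is a sequence of multichannel arrays ``(n_channels,
    n_samples)`` — isolated data windows, reflect-padded internally before the
    wavelet transform — and ``labels`` marks each as ictal (True) or
    interictal (False).  The objective at each grid node is the percentage
    difference ``100 * (mean ictal gamma-bar - mean interictal gamma-bar) /
    mean interictal gamma-bar``.
    """
    fc_grid = DEFAULT_FC_GRID if fc_grid is None else np.asarray(fc_grid, float)
    fa_grid = DEFAULT_FA_GRID if fa_grid is None else np.asarray(fa_grid, float)
    labels = np.asarray(labels, dtype=bool)
    if len(segments) != labels.size:
        raise ValueError("one label per segment required")
    if labels.all() or (~labels).all():
        raise ValueError("grid search needs both ictal and interictal segments")

    objective = np.zeros((fc_grid.size, fa_grid.size))
    for i, fc in enumerate(fc_grid):
        for j, fa in enumerate(fa_grid):
            if fa <= fc:
                objective[i, j] = -np.inf
                continue
            gbar = np.empty(labels.size)
            for s, seg in enumerate(segments):
                seg = np.atleast_2d(np.asarray(seg, float))
                phi = phase(cwt(seg, fs, fc, fa, pad_s=pad_s))
                gbar[s] = window_global_gamma(
                    phi, fs, np.array([0.0]), window_s=seg.shape[-1] / fs
                )[0]
            m_ict = gbar[labels].mean()
            m_int = gbar[~labels].mean()
            objective[i, j] = 100.0 * (m_ict - m_int) / m_int
    i, j = np.unravel_index(np.argmax(objective), objective.shape)
    return GridSearchResult(
        fc_grid=fc_grid,
        fa_grid=fa_grid,
        objective=objective,
        best=(float(fc_grid[i]), float(fa_grid[j])),
    )
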