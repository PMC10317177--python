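"""Synthetic multichannel spike-and-wave EEG with ground-truth annotations.

The generator produces 19-channel 10-20 recordings whose statistics mirror
what the detector assumes about absence-seizure EEG:

* background — per-channel 1/f ("pink") noise plus an alpha rhythm realized
  as independent narrowband (8-12 Hz) noise per channel, stronger over the
  occipital electrodes; channels are statistically independent, so the
  interictal global synchronization index stays low;
* seizures — generalized spike-and-wave discharges: a shared waveform (one
  sharp Gaussian-derivative spike plus a half-sine slow wave per cycle at
  2.5-5.5 Hz, default 3 Hz) broadcast to all channels with per-channel gain
  and a small constant phase offset drawn from the configured jitter.  The
  shared waveform makes the channels phase-locked, the defining property of
  these seizures.  Discharge amplitude is a configurable multiple (default 4)
  of the background mean absolute amplitude;
* seizure schedule — non-overlapping, none within the first 30 s (which the
  amplitude normalization uses as its interictal reference); durations drawn
  from a triangular distribution on [3, 20] s with mode 10 s, matching the
  clinical range and median;
* fragmentation — optional gaps strictly inside seizures realized in one of
  three modes: ``"spike_loss"`` (spikes vanish, the slow delta wave
  persists), ``"cessation"`` (discharges stop, background persists) or
  ``"desync"`` (discharges continue but channels lose their common phase);
* interictal epileptiform bursts — short (< 2 s) generalized discharges that
  exercise the detector's false-positive behaviour — and frontal blink
  artifacts.

Everything derives from a single master seed, so cohorts are bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .readwrite import AnnotationSet, Recording
from .sync import SUBSETS

__all__ = ["SimConfig", "GroundTruth", "gen_background", "gen_swd", "gen_recording", "gen_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator (amplitudes in µV)."""

    n_subjects: int = 10
    fs: float = 250.0
    duration_s: float = 600.0
    montage: tuple[str, ...] = SUBSETS["S19"]
    # background
    pink_exponent: float = 1.0
    background_rms: float = 15.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    alpha_rms: float = 6.0
    occipital_alpha_gain: float = 2.5
    # spike-and-wave discharges
    swd_rate: float = 3.0  # Hz, clinical range 2.5-5.5
    swd_gain: float = 4.0  # ictal mean |x| as a multiple of background mean |x|
    swd_channel_gain_std: float = 0.1  # per-channel gain spread around 1
    spike_width_s: float = 0.02
    phase_jitter: float = 0.3  # radians at the discharge rate, across channels
    # seizure schedule
    n_seizures: int = 6
    seizure_duration_range: tuple[float, float] = (3.0, 20.0)
    seizure_duration_mode: float = 10.0
    seizure_duration_s: float | None = None  # fixed duration overriding the distribution
    min_seizure_gap_s: float = 10.0
    # fragmentation
    frag_fraction: float = 0.0
    frag_min_gap_s: float = 1.5
    frag_mode: str = "cessation"  # spike_loss | cessation | desync
    # interictal events
    burst_rate_per_min: float = 0.2
    burst_gain: float = 3.0
    blink_rate_per_min: float = 1.0
    blink_amplitude: float = 120.0
    # inter-subject variability: per-subject overall amplitude scale range
    amp_scale_range: tuple[float, float] = (0.6, 1.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2.5 <= self.swd_rate <= 5.5:
            raise ValueError("swd_rate must lie in the clinical 2.5-5.5 Hz band")
        if self.frag_mode not in ("spike_loss", "cessation", "desync"):
            raise ValueError(f"unknown fragmentation mode {self.frag_mode!r}")
        if not 0 <= self.frag_fraction < 1:
            raise ValueError("frag_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Intervals the generator implanted, all half-open seconds."""

    seizures: list[tuple[float, float]] = field(default_factory=list)
    gaps: list[tuple[float, float]] = field(default_factory=list)
    artifacts: list[tuple[float, float, str]] = field(default_factory=list)

    def to_annotations(self, subject_id: str) -> AnnotationSet:
        return AnnotationSet(
            subject_id=subject_id,
            intervals=[(a, b, "seizure") for a, b in self.seizures],
        )


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f**exponent power spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def gen_background(config: SimConfig, rng: np.random.Generator, n_samples: int | None = None) -> np.ndarray:
    """Background EEG ``(n_channels, n_samples)`` in µV (independent channels)."""
    fs = config.fs
    n = n_samples if n_samples is not None else int(round(config.duration_s * fs))
    n_ch = len(config.montage)
    out = np.empty((n_ch, n))
    sos = sps.butter(4, config.alpha_band, btype="bandpass", fs=fs, output="sos")
    for c, label in enumerate(config.montage):
        pink = _pink_noise(n, config.pink_exponent, rng) * config.background_rms
        alpha = sps.sosfilt(sos, rng.standard_normal(n))
        alpha *= config.alpha_rms / max(alpha.std(), 1e-12)
        if label in ("O1", "O2"):
            alpha *= config.occipital_alpha_gain
        out[c] = pink + alpha
    return out


def _swd_cycle(fs: float, rate: float, spike_width_s: float) -> tuple[np.ndarray, np.ndarray]:
    """One spike-and-wave cycle: (full waveform, slow-wave-only waveform)."""
    n = int(round(fs / rate))
    t = np.arange(n) / fs
    period = n / fs
    # slow wave: one full (dominantly negative) sine arc over the cycle
    slow = -np.sin(2.0 * np.pi * t / period)
    # spike: derivative-of-Gaussian transient early in the cycle
    t0 = 0.18 * period
    u = (t - t0) / spike_width_s
    spike = -u * np.exp(-(u**2) / 2.0) * np.exp(1 / 2)  # peak amplitude 1
    full = slow + 2.5 * spike
    return full, slow


def gen_swd(
    duration_s: float,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    slow_only: bool = False,
) -> np.ndarray:
    """Generalized SWD segment ``(n_channels, n_samples)`` with unit mean |x|.

    A shared cyclic waveform is broadcast to every channel with per-channel
    gain (~N(1, 0.1^2)) and a per-channel constant time shift equivalent to
    the configured phase jitter at the discharge rate.  ``slow_only`` drops
    the spikes (fragmentation mode "spike_loss").
    """
    if duration_s < 1.0 / config.swd_rate:
        raise ValueError("SWD segment must contain at least one cycle")
    fs = config.fs
    n = int(round(duration_s * fs))
    full, slow = _swd_cycle(fs, config.swd_rate, config.spike_width_s)
    base = slow if slow_only else full
    n_cycles = int(np.ceil(n / base.size))
    shared = np.tile(base, n_cycles)[:n]
    # soft onset/offset so discharges do not start with a step
    ramp = min(int(0.1 * fs), n // 4)
    if ramp > 0:
        env = np.ones(n)
        env[:ramp] = np.linspace(0, 1, ramp)
        env[-ramp:] = np.linspace(1, 0, ramp)
        shared = shared * env
    shared /= np.mean(np.abs(shared))

    n_ch = len(config.montage)
    gains = np.clip(rng.normal(1.0, config.swd_channel_gain_std, size=n_ch), 0.5, None)
    shift_std = config.phase_jitter / (2.0 * np.pi * config.swd_rate)
    shifts = np.rint(rng.normal(0.0, shift_std, size=n_ch) * fs).astype(int)
    out = np.empty((n_ch, n))
    for c in range(n_ch):
        out[c] = gains[c] * np.roll(shared, shifts[c])
    return out


def _place_intervals(
    n: int,
    durations: np.ndarray,
    lo: float,
    hi: float,
    min_gap: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Place n non-overlapping intervals of given durations inside [lo, hi]."""
    slack = (hi - lo) - durations.sum() - min_gap * (n - 1)
    if slack < 0:
        raise ValueError(
            f"cannot fit {n} seizures totalling {durations.sum():.1f} s into "
            f"{hi - lo:.1f} s of recording"
        )
    cuts = np.sort(rng.uniform(0, slack, size=n)) if n else np.array([])
    out = []
    for i in range(n):
        start = lo + cuts[i] + float(durations[:i].sum()) + min_gap * i
        start = round(start * 10.0) / 10.0  # 0.1-s grid: onsets mostly off the window grid
        out.append((start, start + float(durations[i])))
    return out


def _frag_gaps(
    onset: float,
    offset: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Gap intervals strictly inside a seizure, totalling frag_fraction."""
    total = config.frag_fraction * (offset - onset)
    if total <= 0:
        return []
    min_gap = config.frag_min_gap_s
    n_gaps = max(1, int(total // (2 * min_gap)))
    # ensure each gap >= min_gap
    while n_gaps > 1 and total / n_gaps < min_gap:
        n_gaps -= 1
    lengths = np.full(n_gaps, total / n_gaps)
    margin = 0.5  # keep gaps clear of the seizure edges
    sep = 0.2  # minimum separation between gaps
    span = (offset - margin) - (onset + margin)
    if lengths.sum() + sep * (n_gaps - 1) > span:
        lengths = np.array([min(total, span)])
        n_gaps = 1
    slack = span - lengths.sum() - sep * (n_gaps - 1)
    cuts = np.sort(rng.uniform(0, max(slack, 0.0), size=n_gaps))
    gaps = []
    for i in range(n_gaps):
        start = onset + margin + cuts[i] + float(lengths[:i].sum()) + sep * i
        gaps.append((start, start + float(lengths[i])))
    return gaps


def gen_recording(
    config: SimConfig,
    seed=None,
    subject_id: str = "S01",
    *,
    amp_scale: float = 1.0,
) -> tuple[Recording, GroundTruth]:
    """One annotated synthetic recording.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    generator; ``amp_scale`` multiplies the whole recording (inter-subject
    amplitude variability the normalized-amplitude feature must absorb).
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed if seed is not None else config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    data = gen_background(config, rng, n)
    bg_mean_abs = float(np.mean(np.abs(data)))
    truth = GroundTruth()

    # --- seizure schedule -------------------------------------------------
    if config.n_seizures:
        lo_d, hi_d = config.seizure_duration_range
        if config.seizure_duration_s is not None:
            durations = np.full(config.n_seizures, config.seizure_duration_s)
        else:
            durations = rng.triangular(
                lo_d, config.seizure_duration_mode, hi_d, size=config.n_seizures
            )
        seizures = _place_intervals(
            config.n_seizures,
            durations,
            lo=35.0,
            hi=config.duration_s - 5.0,
            min_gap=config.min_seizure_gap_s,
            rng=rng,
        )
    else:
        seizures = []

    def idx(t: float) -> int:
        return int(round(t * fs))

    for onset, offset in seizures:
        dur = offset - onset
        swd = gen_swd(dur, config, rng) * config.swd_gain * bg_mean_abs
        i0, i1 = idx(onset), idx(offset)
        swd = swd[:, : i1 - i0]
        gaps = _frag_gaps(onset, offset, config, rng)
        for g0, g1 in gaps:
            j0, j1 = idx(g0) - i0, idx(g1) - i0
            if config.frag_mode == "cessation":
                swd[:, j0:j1] = 0.0
            elif config.frag_mode == "spike_loss":
                slow = gen_swd(dur, config, rng, slow_only=True)
                swd[:, j0:j1] = slow[:, j0:j1] * config.swd_gain * bg_mean_abs
            else:  # desync: per-channel, per-cycle random time offsets
                seg = swd[:, j0:j1]
                cyc = int(round(fs / config.swd_rate))
                for c in range(seg.shape[0]):
                    for s in range(0, seg.shape[1], cyc):
                        e = min(s + cyc, seg.shape[1])
                        shift = rng.integers(-cyc // 3, cyc // 3 + 1)
                        seg[c, s:e] = np.roll(seg[c, s:e], shift)
                swd[:, j0:j1] = seg
        data[:, i0:i1] += swd
        truth.seizures.append((onset, offset))
        truth.gaps.extend(gaps)

    # --- interictal epileptiform bursts ------------------------------------
    def free(t0: float, t1: float) -> bool:
        keep_out = [(a - 5.0, b + 5.0) for a, b in seizures] + [(0.0, 32.0)]
        keep_out += [(a - 2.0, b + 2.0) for a, b, _ in truth.artifacts]
        return all(not (t0 < b and t1 > a) for a, b in keep_out)

    n_bursts = rng.poisson(config.burst_rate_per_min * config.duration_s / 60.0)
    for _ in range(n_bursts):
        dur = float(rng.uniform(0.6, 1.8))
        for _attempt in range(50):
            t0 = float(rng.uniform(35.0, config.duration_s - 5.0 - dur))
            if free(t0, t0 + dur):
                burst = gen_swd(dur, config, rng) * config.burst_gain * bg_mean_abs
                i0 = idx(t0)
                data[:, i0 : i0 + burst.shape[1]] += burst
                truth.artifacts.append((t0, t0 + dur, "burst"))
                break

    # --- blink artifacts ----------------------------------------------------
    frontal = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.4, "F8": 0.4}
    rows = {lab: i for i, lab in enumerate(config.montage)}
    n_blinks = rng.poisson(config.blink_rate_per_min * config.duration_s / 60.0)
    for _ in range(n_blinks):
        dur = 0.4
        for _attempt in range(50):
            t0 = float(rng.uniform(32.0, config.duration_s - 2.0))
            if free(t0, t0 + dur):
                m = int(round(dur * fs))
                pulse = np.sin(np.linspace(0, np.pi, m)) ** 2 * config.blink_amplitude
                i0 = idx(t0)
                for lab, g in frontal.items():
                    if lab in rows:
                        data[rows[lab], i0 : i0 + m] += g * pulse
                truth.artifacts.append((t0, t0 + dur, "blink"))
                break

    data *= amp_scale
    rec = Recording(subject_id=subject_id, fs=fs, channels=list(config.montage), data=data)
    return rec, truth


def gen_cohort(config: SimConfig) -> list[tuple[Recording, GroundTruth]]:
    """Independent subjects with per-subject seeds derived from the master seed.

    Per-subject overall amplitude scales are spread across
    ``config.amp_scale_range`` to emulate age/impedance differences.
    """
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_subjects)
    lo, hi = config.amp_scale_range
    scales = np.linspace(lo, hi, config.n_subjects)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        rec, truth = gen_recording(
            config, seed=rng, subject_id=f"P{i + 1:02d}", amp_scale=float(scales[i])
        )
        out.append((rec, truth))
    return out
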