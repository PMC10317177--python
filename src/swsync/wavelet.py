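"""Complex Morlet continuous wavelet transform and instantaneous phase.

The analysis uses a single scale ``a = fc / fa`` of the complex Morlet mother
wavelet

    psi(t) = pi**(-1/4) * exp(2j*pi*fc*t) * exp(-t**2 / 2),

whose Fourier transform is the real Gaussian

    psi_hat(f) = sqrt(2) * pi**(1/4) * exp(-2 * pi**2 * (f - fc)**2).

``fc`` (the center frequency) is where the wavelet's Fourier power spectrum
peaks; the scale ``a`` maps it to the pseudo-frequency ``fa = fc / a`` at
which the signal is analysed.  The transform keeps the ``1/a`` normalization

    T[s](a, t0) = (1/a) * integral s(t) * conj(psi((t - t0) / a)) dt,

discretized as a Riemann sum on the sampling grid; any amplitude
normalization cancels in the phase, which is all the synchronization index
uses.

Because data windows are short relative to the wavelet support, boundary
effects matter: the transform is computed over the full continuous recording
where possible, and isolated segments are reflect-padded (1 s by default) on
both sides before transforming, with the pads discarded afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "WaveletParams",
    "morlet",
    "morlet_spectrum",
    "scale_for",
    "pseudo_frequency",
    "cwt",
    "phase",
]

_INVALID_MAG_RATIO = 1e-12


@dataclass(frozen=True)
class WaveletParams:
    """Center frequency, pseudo-frequency and the implied scale a = fc/fa."""

    fc: float
    fa: float

    def __post_init__(self) -> None:
        if not (self.fc > 0 and self.fa > 0):
            raise ValueError("fc and fa must be positive")

    @property
    def a(self) -> float:
        return self.fc / self.fa


def morlet(t, fc: float):
    """Complex Morlet mother wavelet evaluated at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    return np.pi ** (-0.25) * np.exp(2j * np.pi * fc * t) * np.exp(-(t**2) / 2.0)


def morlet_spectrum(f, fc: float):
    """Fourier transform of the Morlet wavelet (real, positive, peak at fc)."""
    f = np.asarray(f, dtype=float)
    return np.sqrt(2.0) * np.pi**0.25 * np.exp(-2.0 * np.pi**2 * (f - fc) ** 2)


def scale_for(fc: float, fa: float) -> float:
    """Scale ``a`` at which the Morlet with center ``fc`` analyses ``fa``."""
    if fc <= 0 or fa <= 0:
        raise ValueError("fc and fa must be positive")
    return fc / fa


def pseudo_frequency(fc: float, a: float) -> float:
    """Pseudo-frequency of scale ``a``: fa = fc / a."""
    if fc <= 0 or a <= 0:
        raise ValueError("fc and a must be positive")
    return fc / a


def _kernel(fs: float, fc: float, fa: float, truncate: float) -> np.ndarray:
    """Sampled, truncated kernel so that cwt = convolve(s, kernel, 'same').

    With the substitution u = (t - t0)/a the transform is
    T(t0) = integral s(t0 + a u) conj(psi(u)) du; on the sample grid this is a
    convolution with g[m] = psi(m*dt/a) * dt/a (the Morlet envelope is even
    and conjugation flips the sign of the oscillation, so conj(psi(-x)) =
    psi(x)).  The kernel is truncated at ``truncate`` envelope standard
    deviations (|t/a| <= truncate).
    """
    a = scale_for(fc, fa)
    dt = 1.0 / fs
    half = int(np.ceil(truncate * a * fs))
    m = np.arange(-half, half + 1)
    return morlet(m * dt / a, fc) * (dt / a)


def cwt(
    x,
    fs: float,
    fc: float,
    fa: float,
    *,
    pad_s: float = 1.0,
    truncate: float = 8.0,
) -> np.ndarray:
    """Single-scale complex Morlet CWT of ``x`` (last axis = time).

    ``pad_s`` seconds of reflect padding are added on both sides and removed
    from the result, which suppresses edge artifacts for signals that are
    sliced out of a longer stream.  Pass ``pad_s=0`` for an unpadded
    transform.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        return np.zeros(x.shape, dtype=complex)
    if fs <= 0:
        raise ValueError("fs must be positive")
    kernel = _kernel(fs, fc, fa, truncate)
    npad = int(round(pad_s * fs))
    npad = min(npad, x.shape[-1] - 1)
    if npad > 0:
        pad_width = [(0, 0)] * (x.ndim - 1) + [(npad, npad)]
        xp = np.pad(x, pad_width, mode="reflect")
    else:
        xp = x
    shape = [1] * (xp.ndim - 1) + [kernel.size]
    coeffs = fftconvolve(xp, kernel.reshape(shape), mode="same", axes=-1)
    if npad > 0:
        coeffs = coeffs[..., npad : npad + x.shape[-1]]
    return coeffs


def cwt_direct(x, fs: float, fc: float, fa: float, *, truncate: float = 6.0) -> np.ndarray:
    """Time-domain Riemann-sum CWT (no padding).

    Slow reference path kept for cross-checking the FFT-based transform.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("reference path handles 1-D signals only")
    a = scale_for(fc, fa)
    dt = 1.0 / fs
    half = int(np.ceil(truncate * a * fs))
    n = x.shape[-1]
    out = np.zeros(n, dtype=complex)
    for t0 in range(n):
        lo = max(0, t0 - half)
        hi = min(n, t0 + half + 1)
        m = np.arange(lo, hi)
        # conj(psi(-u)) = psi(u), so psi*((m - t0)/a) = psi((t0 - m)/a)
        out[t0] = np.sum(x[lo:hi] * morlet((t0 - m) * dt / a, fc)) * dt / a
    return out


def phase(coeffs, *, min_mag_ratio: float = _INVALID_MAG_RATIO) -> np.ndarray:
    """Instantaneous phase (radians in (-pi, pi]) of CWT coefficients.

    Samples whose magnitude is below ``min_mag_ratio`` times the maximum
    magnitude are numerically meaningless and returned as NaN; downstream
    averages must skip them.
    """
    coeffs = np.asarray(coeffs, dtype=complex)
    phi = np.angle(coeffs)
    mag = np.abs(coeffs)
    cutoff = min_mag_ratio * (mag.max() if mag.size else 0.0)
    phi = np.where(mag > cutoff, phi, np.nan)
    return phi
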