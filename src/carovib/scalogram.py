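"""Analytic Morse-wavelet CWT magnitude scalograms on the 5-60 Hz band.

The generalized Morse wavelet is defined in the frequency domain as

    Psi(omega) = U(omega) * c * omega**beta * exp(-omega**gamma)

with symmetry parameter gamma, beta = P^2 / gamma for time-bandwidth product
P^2 (here gamma = 3, P^2 = 60, so beta = 20), U the unit step making the
wavelet exactly analytic, and c chosen so the peak response is 1 (L-infinity
normalization).  The peak sits at omega_peak = (beta/gamma)**(1/gamma).

The CWT is evaluated as a frequency-domain filter bank: the segment is
reflected to double length, multiplied spectrum-by-spectrum with each scaled
wavelet, inverse-transformed, and the central half retained.  Because every
filter is band-limited, the coefficient rows can optionally be sampled on a
coarser time grid *exactly* (fold the product spectrum, short inverse FFT) -
the decimated rows equal every d-th column of the full-rate transform to
machine precision, which the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft as sfft


@dataclass(frozen=True)
class MorseParams:
    gamma: float = 3.0
    time_bandwidth: float = 60.0  # P^2
    voices_per_octave: int = 12
    f_min_hz: float = 5.0
    f_max_hz: float = 60.0

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    @property
    def omega_peak(self) -> float:
        """Radian frequency (per unit scale) of the wavelet's peak response."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    def validate(self, fs: float) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if not (0 < self.f_min_hz < self.f_max_hz < fs / 2):
            raise ValueError(
                f"analysis band ({self.f_min_hz}, {self.f_max_hz}) Hz outside (0, {fs / 2}) Hz"
            )
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")


def morse_freq_response(omega: np.ndarray, params: MorseParams) -> np.ndarray:
    """Peak-normalized Morse wavelet frequency response; zero for omega <= 0."""
    omega = np.asarray(omega, dtype=np.float64)
    out = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    b, g = params.beta, params.gamma
    wp = params.omega_peak
    # evaluate in log space: Psi(w)/Psi(wp) = exp(b*ln(w/wp) - (w^g - wp^g))
    out[pos] = np.exp(b * np.log(w / wp) - (w**g - wp**g))
    return out


@dataclass(frozen=True)
class Filterbank:
    filters: np.ndarray  # [n_freqs, n_fft] real spectra on the padded grid
    freqs_hz: np.ndarray  # ascending center frequencies
    fs: float
    n_samples: int  # segment length the bank was built for
    n_fft: int  # padded length (2 * n_samples)
    max_support_bin: int  # highest FFT bin with non-negligible response


def center_frequencies(params: MorseParams) -> np.ndarray:
    """Log-spaced grid f_k = f_min * 2^(k/v) staying within [f_min, f_max]."""
    v = params.voices_per_octave
    n = int(np.floor(v * np.log2(params.f_max_hz / params.f_min_hz))) + 1
    return params.f_min_hz * 2.0 ** (np.arange(n) / v)


def build_filterbank(fs: float, n_samples: int, params: MorseParams | None = None) -> Filterbank:
    """Morse filter bank matched to reflect-padded segments of ``n_samples``."""
    params = params or MorseParams()
    params.validate(fs)
    if n_samples < 64:
        raise ValueError("segments shorter than 64 samples are not supported")
    freqs = center_frequencies(params)
    n_fft = 2 * n_samples
    fft_freqs = sfft.fftfreq(n_fft, d=1.0 / fs)  # Hz, two-sided
    # scale each row so the response peaks at its center frequency: the row for
    # center f evaluates Psi at omega_peak * (fft_freq / f)
    ratio = fft_freqs[None, :] / freqs[:, None]
    filters = morse_freq_response(params.omega_peak * ratio, params)
    support = np.nonzero(filters.max(axis=0) > 1e-12)[0]
    max_support_bin = int(support.max()) if support.size else 0
    return Filterbank(
        filters=filters,
        freqs_hz=freqs,
        fs=fs,
        n_samples=n_samples,
        n_fft=n_fft,
        max_support_bin=max_support_bin,
    )


@lru_cache(maxsize=8)
def cached_filterbank(fs: float, n_samples: int, params: MorseParams) -> Filterbank:
    return build_filterbank(fs, n_samples, params)


def cwt(segment: np.ndarray, fb: Filterbank, time_decimate: int = 1) -> np.ndarray:
    """Complex CWT coefficients of one segment, [n_freqs x n_samples/d].

    ``time_decimate`` = d > 1 returns the coefficients sampled every d-th
    column; exact (not an approximation) as long as the folded spectrum length
    exceeds the filters' support, which is asserted.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.size != fb.n_samples:
        raise ValueError(f"segment length {x.size} != filter bank length {fb.n_samples}")
    d = int(time_decimate)
    n = fb.n_samples
    pad = n // 2
    if d < 1 or n % (2 * d) or (2 * pad != n):
        raise ValueError("time_decimate must divide half the segment length")
    xp = np.concatenate([x[pad - 1 :: -1] if pad else x[:0], x, x[: -pad - 1 : -1]])
    if d == 1:
        X = sfft.fft(xp)
        W = sfft.ifft(fb.filters * X[None, :], axis=-1)
        return W[:, pad : pad + n]
    m = fb.n_fft // d
    if m <= fb.max_support_bin:
        raise ValueError(
            f"time_decimate={d} folds the spectrum onto itself "
            f"(need {fb.n_fft} / d > {fb.max_support_bin})"
        )
    # the analytic filters vanish above max_support_bin < m, so folding the
    # product spectrum to length m is just truncation; the one-sided rfft
    # covers every bin that matters
    X = sfft.rfft(xp)
    folded = fb.filters[:, :m] * X[None, :m]
    W = sfft.ifft(folded, axis=-1) / d
    return W[:, pad // d : (pad + n) // d]


@dataclass
class Scalogram:
    """|W(a,b)| on the analysis-band frequency grid."""

    magnitude: np.ndarray  # [n_freqs, n_times], all >= 0
    freqs_hz: np.ndarray  # ascending
    times_s: np.ndarray
    fs: float

    @property
    def energy(self) -> np.ndarray:
        """Cellwise energy |W|^2 (the quantity all features integrate)."""
        return self.magnitude**2


def magnitude_scalogram(
    coeffs: np.ndarray,
    freqs_hz: np.ndarray,
    fs: float,
    f_min_hz: float = 5.0,
    f_max_hz: float = 60.0,
    time_decimate: int = 1,
) -> Scalogram:
    """Elementwise modulus, restricted to rows inside the analysis band."""
    freqs_hz = np.asarray(freqs_hz, dtype=np.float64)
    keep = (freqs_hz >= f_min_hz) & (freqs_hz <= f_max_hz)
    mag = np.abs(coeffs[keep])
    n_times = coeffs.shape[1]
    times = np.arange(n_times) * (time_decimate / fs)
    return Scalogram(magnitude=mag, freqs_hz=freqs_hz[keep], times_s=times, fs=fs)


def scalogram_of_segment(
    segment: np.ndarray,
    fs: float,
    params: MorseParams | None = None,
    time_decimate: int = 1,
) -> Scalogram:
    """Convenience wrapper: filter bank (cached) -> CWT -> magnitude scalogram."""
    params = params or MorseParams()
    fb = cached_filterbank(float(fs), int(np.asarray(segment).size), params)
    W = cwt(segment, fb, time_decimate=time_decimate)
    return magnitude_scalogram(
        W, fb.freqs_hz, fs, params.f_min_hz, params.f_max_hz, time_decimate=time_decimate
    )
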