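"""Interpretable scalogram biomarkers.

All features integrate the squared CWT magnitude S(f,t) = |W(f,t)|^2 over the
5-60 Hz analysis band and are normalized to be invariant to positive amplitude
scaling of the input segment (and hence to the wavelet normalization
convention).  Four signal aspects are covered:

* how much energy sits high in the band - fractional upper-band energy ratios
  (upper 30/40/50 % of the band, vs total and vs the complementary lower part),
* where the energy is concentrated - spectral centroid, spread and the 85 %/
  95 % cumulative-energy roll-off positions along the frequency axis,
* how dispersed the time-frequency image is - Shannon image entropy on the
  full band and as an upper/lower ratio, and the Gini sparsity index,
* how sharp the time-frequency texture is - mean Sobel gradient magnitude,
  globally and as an upper/lower ratio.

The core six-feature vector used for multivariate modelling is
``CORE_FEATURES``; everything else forms the extended screening set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .scalogram import Scalogram

CORE_FEATURES: tuple[str, ...] = (
    "hf_fraction_top50",
    "gini_sparsity",
    "spectral_centroid_hz",
    "sobel_edge_energy",
    "image_entropy",
    "spectral_spread_hz",
)

EXTENDED_FEATURES: tuple[str, ...] = (
    "hf_ratio_top30_total",
    "hf_ratio_top40_total",
    "hf_ratio_top30_lower",
    "hf_ratio_top40_lower",
    "hf_ratio_top50_lower",
    "rolloff_85_hz",
    "rolloff_95_hz",
    "entropy_upper_lower_ratio",
    "sobel_upper_lower_ratio",
)

ALL_FEATURES: tuple[str, ...] = CORE_FEATURES + EXTENDED_FEATURES

Region = Literal["full", "upper", "lower"]


@dataclass(frozen=True)
class FeatureConfig:
    band: tuple[float, float] = (5.0, 60.0)
    upper_fractions: tuple[float, ...] = (0.3, 0.4, 0.5)
    rolloff_quantiles: tuple[float, ...] = (0.85, 0.95)
    entropy_normalized: bool = True
    sobel_log: bool = False  # Sobel on log-magnitude instead of raw magnitude

    def validate(self) -> None:
        if not all(0 < q < 1 for q in self.upper_fractions):
            raise ValueError("upper_fractions must lie in (0, 1)")
        if not all(0 < p < 1 for p in self.rolloff_quantiles):
            raise ValueError("rolloff_quantiles must lie in (0, 1)")


def fractional_band_cut(f_lo: float, f_hi: float, q: float) -> float:
    """Lower edge of the upper fraction ``q`` of the band [f_lo, f_hi].

    The upper 50 % of 5-60 Hz is 32.5-60 Hz.
    """
    if not 0 < q < 1:
        raise ValueError(f"fraction q must lie in (0, 1); got {q}")
    return f_hi - q * (f_hi - f_lo)


def band_energy(scal: Scalogram, f_a: float, f_b: float) -> float:
    """Sum of |W|^2 over rows with f_a <= f <= f_b (all time columns)."""
    rows = (scal.freqs_hz >= f_a) & (scal.freqs_hz <= f_b)
    if not rows.any():
        return 0.0
    return float(scal.energy[rows].sum())


def _upper_mask(scal: Scalogram, q: float, band: tuple[float, float]) -> np.ndarray:
    f_cut = fractional_band_cut(band[0], band[1], q)
    return scal.freqs_hz >= f_cut


def hf_ratio(
    scal: Scalogram,
    q: float,
    denominator: Literal["total", "lower"] = "total",
    band: tuple[float, float] = (5.0, 60.0),
) -> float:
    """Upper-band energy over total (or over the complementary lower band)."""
    upper = _upper_mask(scal, q, band)
    S = scal.energy
    e_up = float(S[upper].sum())
    e_lo = float(S[~upper].sum())
    total = e_up + e_lo
    if total == 0:
        raise ValueError("zero total energy")
    if denominator == "total":
        return e_up / total
    if e_lo == 0:
        return float("inf")
    return e_up / e_lo


def _freq_marginal(scal: Scalogram) -> np.ndarray:
    p = scal.energy.sum(axis=1)
    total = p.sum()
    if total == 0:
        raise ValueError("zero total energy")
    return p / total


def spectral_centroid(scal: Scalogram) -> float:
    """Energy-weighted mean frequency (Hz) of the frequency marginal."""
    return float(np.dot(scal.freqs_hz, _freq_marginal(scal)))


def spectral_spread(scal: Scalogram) -> float:
    """Energy-weighted SD (Hz) about the spectral centroid."""
    p = _freq_marginal(scal)
    c = float(np.dot(scal.freqs_hz, p))
    return float(np.sqrt(np.dot((scal.freqs_hz - c) ** 2, p)))


def spectral_rolloff(scal: Scalogram, p: float) -> float:
    """Lowest grid frequency below which >= p of total energy accumulates."""
    if not 0 < p < 1:
        raise ValueError("rolloff quantile must lie in (0, 1)")
    marg = _freq_marginal(scal)
    cum = np.cumsum(marg)
    idx = int(np.searchsorted(cum, p - 1e-12))
    idx = min(idx, marg.size - 1)
    return float(scal.freqs_hz[idx])


def _region_slices(scal: Scalogram, region, band: tuple[float, float]):
    if region == "full" or region is None:
        return np.ones(scal.freqs_hz.size, dtype=bool)
    kind, q = region
    upper = _upper_mask(scal, q, band)
    return upper if kind == "upper" else ~upper


def image_entropy(
    scal: Scalogram,
    region="full",
    normalized: bool = True,
    band: tuple[float, float] = (5.0, 60.0),
) -> float:
    """Shannon entropy of the cell-energy distribution over the region.

    ``region`` is ``"full"`` or a tuple ``("upper"|"lower", q)``.  Normalized
    variant divides by ln(number of cells), giving a value in [0, 1].
    """
    rows = _region_slices(scal, region, band)
    S = scal.energy[rows]
    total = S.sum()
    if total == 0 or S.size == 0:
        return float("nan")
    p = S / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = float(-plogp.sum())
    if normalized:
        h /= np.log(S.size) if S.size > 1 else 1.0
    return h


def _sobel_magnitude(image: np.ndarray) -> np.ndarray:
    # standard 3x3 Sobel pair with edge replication
    gx = ndimage.sobel(image, axis=1, mode="nearest")
    gy = ndimage.sobel(image, axis=0, mode="nearest")
    return np.sqrt(gx * gx + gy * gy)


def sobel_edge_energy(
    scal: Scalogram,
    region="full",
    band: tuple[float, float] = (5.0, 60.0),
    log: bool = False,
) -> float:
    """Mean Sobel gradient magnitude of the scalogram scaled to [0, 1]."""
    img = scal.magnitude
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("scalogram must be at least 3x3 for Sobel gradients")
    mx = img.max()
    if mx == 0:
        return 0.0
    img = np.log1p(img / mx) / np.log(2.0) if log else img / mx
    grad = _sobel_magnitude(img)
    rows = _region_slices(scal, region, band)
    return float(grad[rows].mean())


def gini_sparsity(values: np.ndarray | Scalogram) -> float:
    """Gini sparsity index of nonnegative magnitudes: 0 = uniform, -> 1 = one spike.

    G = 2 * sum_k k * x_(k) / (N * sum x) - (N + 1) / N  on ascending-sorted x.
    """
    if isinstance(values, Scalogram):
        values = values.magnitude
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0 or (x < 0).any():
        raise ValueError("Gini requires a nonempty nonnegative array")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for all-zero input")
    xs = np.sort(x)
    n = xs.size
    k = np.arange(1, n + 1, dtype=np.float64)
    return float(2.0 * np.dot(k, xs) / (n * total) - (n + 1.0) / n)


def extract_features(scal: Scalogram, config: FeatureConfig | None = None) -> dict[str, float]:
    """All biomarkers of one scalogram, core six first, extended set after."""
    config = config or FeatureConfig()
    config.validate()
    band = config.band
    S = scal.energy
    total = S.sum()
    if total == 0:
        raise ValueError("zero-energy scalogram")

    freqs = scal.freqs_hz
    row_energy = S.sum(axis=1)
    marg = row_energy / total
    half = freqs >= fractional_band_cut(band[0], band[1], 0.5)

    # shared intermediates: one Sobel pass and one p*log(p) pass serve the
    # full-band features and both half-band ratios
    mx = scal.magnitude.max()
    img = (
        np.log1p(scal.magnitude / mx) / np.log(2.0)
        if config.sobel_log
        else scal.magnitude / mx
    )
    grad = _sobel_magnitude(img)
    with np.errstate(divide="ignore", invalid="ignore"):
        slogs = np.where(S > 0, S * np.log(S), 0.0)

    def region_entropy(mask: np.ndarray) -> float:
        e = float(row_energy[mask].sum())
        n_cells = int(mask.sum()) * S.shape[1]
        if e == 0 or n_cells == 0:
            return float("nan")
        h = np.log(e) - float(slogs[mask].sum()) / e
        return h / np.log(n_cells) if config.entropy_normalized and n_cells > 1 else h

    out: dict[str, float] = {}
    out["hf_fraction_top50"] = float(row_energy[half].sum()) / total
    out["gini_sparsity"] = gini_sparsity(scal)
    c = float(np.dot(freqs, marg))
    out["spectral_centroid_hz"] = c
    out["sobel_edge_energy"] = float(grad.mean())
    out["image_entropy"] = region_entropy(np.ones_like(half))
    out["spectral_spread_hz"] = float(np.sqrt(np.dot((freqs - c) ** 2, marg)))

    for q in config.upper_fractions:
        tag = f"top{int(round(q * 100))}"
        upper = freqs >= fractional_band_cut(band[0], band[1], q)
        e_up = float(row_energy[upper].sum())
        e_lo = total - e_up
        if tag != "top50":
            out[f"hf_ratio_{tag}_total"] = e_up / total
        out[f"hf_ratio_{tag}_lower"] = e_up / e_lo if e_lo else float("inf")
    cum = np.cumsum(marg)
    for p in config.rolloff_quantiles:
        idx = min(int(np.searchsorted(cum, p - 1e-12)), freqs.size - 1)
        out[f"rolloff_{int(round(p * 100))}_hz"] = float(freqs[idx])
    h_up, h_lo = region_entropy(half), region_entropy(~half)
    out["entropy_upper_lower_ratio"] = h_up / h_lo if h_lo else float("inf")
    s_up, s_lo = float(grad[half].mean()), float(grad[~half].mean())
    out["sobel_upper_lower_ratio"] = s_up / s_lo if s_lo else float("inf")
    return out
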