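"""Channel preprocessing and Manders colocalization with automatic thresholding.

Two-channel intensity images (16-bit grayscale, 0.5 μm/px) are first
corrected for bleed-through — regions detected in a source channel (e.g.
insulin/β-cells) are zeroed in the target immune-marker channel — then
smoothed with a disc median filter.  Colocalization is quantified by the
Manders coefficients

    M1 = Σ_{i : P1ᵢ > T}    P1ᵢ / Σᵢ P1ᵢ
    M2 = Σ_{i : P2ᵢ > aT+b} P2ᵢ / Σᵢ P2ᵢ

where the channel-1 threshold T is found automatically: the channel-2
intensities are regressed on channel 1 (P2 ≈ a·P1 + b, all pixels), then
T is stepped down from max(P1) through the distinct channel-1 intensities
until the Pearson correlation of the two channels restricted to
sub-threshold pixels (P1 < T and P2 < aT + b) is no longer positive.
This is the automatic-threshold variant of Manders analysis in which the
threshold is chosen so that below it the channels are uncorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "ChannelImage",
    "MandersResult",
    "DegenerateFitError",
    "UndefinedCoefficientError",
    "subtract_bleedthrough",
    "median_filter",
    "fit_channel_regression",
    "auto_threshold",
    "manders",
    "manders_pipeline",
]

DEFAULT_PIXEL_SIZE = 0.5  # μm/px


class DegenerateFitError(ValueError):
    """Channel-1 intensities have zero variance; regression undefined."""


class UndefinedCoefficientError(ValueError):
    """A channel has zero total intensity; Manders coefficient undefined."""


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel intensity image with its pixel size in μm/px."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "pixels", arr)


@dataclass(frozen=True)
class MandersResult:
    """Manders coefficients with the fitted threshold and channel regression."""

    m1: float
    m2: float
    threshold: float
    a: float
    b: float
    warning: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.m1 <= 1.0 and 0.0 <= self.m2 <= 1.0):
            raise ValueError("Manders coefficients must lie in [0, 1]")


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ChannelImage) else np.asarray(img, dtype=float)


def subtract_bleedthrough(source, target, mask_threshold: float | None = None) -> ChannelImage:
    """Zero the target channel wherever the source channel shows signal.

    ``mask_threshold`` defaults to Otsu's threshold on the source channel;
    pixels with source intensity >= threshold are set to 0 in the target,
    all other pixels are untouched.  Used to remove, e.g., insulin-channel
    bleed-through from immune-marker channels.
    """
    src = _pixels(source)
    tgt = _pixels(target)
    if src.shape != tgt.shape:
        raise ValueError("source and target shapes differ")
    if mask_threshold is None:
        mask_threshold = float(threshold_otsu(src))
    out = tgt.copy()
    out[src >= mask_threshold] = 0.0
    ps = target.pixel_size if isinstance(target, ChannelImage) else DEFAULT_PIXEL_SIZE
    return ChannelImage(out, ps)


def median_filter(img, radius_px: int = 2) -> ChannelImage:
    """Disc median filter (nearest-edge padding) to suppress background noise."""
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    arr = _pixels(img)
    out = ndimage.median_filter(arr, footprint=disk(radius_px), mode="nearest")
    ps = img.pixel_size if isinstance(img, ChannelImage) else DEFAULT_PIXEL_SIZE
    return ChannelImage(out, ps)


def fit_channel_regression(ch1, ch2) -> tuple[float, float]:
    """OLS fit of channel-2 on channel-1 intensity over all pixels: P2 ≈ a·P1 + b."""
    p1 = _pixels(ch1).ravel()
    p2 = _pixels(ch2).ravel()
    if p1.shape != p2.shape:
        raise ValueError("channel shapes differ")
    if np.ptp(p1) == 0:
        raise DegenerateFitError("channel 1 has zero intensity variance")
    a, b = np.polyfit(p1, p2, 1)
    return float(a), float(b)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def auto_threshold(ch1, ch2, a: float, b: float) -> tuple[float, bool]:
    """Largest channel-1 threshold at which sub-threshold pixels are uncorrelated.

    Steps T down from max(P1) through the sorted distinct channel-1
    intensities; at each step the Pearson correlation of (P1, P2) is
    computed over pixels with P1 < T and P2 < a·T + b.  Steps with fewer
    than 3 such pixels, or zero variance, are skipped (correlation
    undefined).  Returns ``(T, warning)`` where ``warning`` is True if
    the correlation never dropped to <= 0 (T then falls back to min(P1)).
    """
    p1 = _pixels(ch1).ravel()
    p2 = _pixels(ch2).ravel()
    if p1.shape != p2.shape:
        raise ValueError("channel shapes differ")
    for t in np.unique(p1)[::-1]:
        sel = (p1 < t) & (p2 < a * t + b)
        if sel.sum() < 3:
            continue
        r = _pearson(p1[sel], p2[sel])
        if np.isnan(r):
            continue
        if r <= 0.0:
            return float(t), False
    warnings.warn(
        "sub-threshold correlation never reached zero; returning min intensity",
        stacklevel=2,
    )
    return float(p1.min()), True


def manders(ch1, ch2, threshold: float, a: float, b: float, warning: bool = False) -> MandersResult:
    """Manders coefficients at the given channel-1 threshold.

    M1 is the fraction of total channel-1 intensity in pixels with
    P1 > T; M2 the fraction of total channel-2 intensity in pixels with
    P2 > a·T + b.
    """
    p1 = _pixels(ch1).ravel()
    p2 = _pixels(ch2).ravel()
    tot1 = p1.sum()
    tot2 = p2.sum()
    if tot1 == 0 or tot2 == 0:
        raise UndefinedCoefficientError("a channel has zero total intensity")
    m1 = p1[p1 > threshold].sum() / tot1
    m2 = p2[p2 > a * threshold + b].sum() / tot2
    return MandersResult(float(m1), float(m2), float(threshold), float(a), float(b), warning)


def manders_pipeline(ch1, ch2) -> MandersResult:
    """Regression → automatic threshold → Manders coefficients, in one call."""
    a, b = fit_channel_regression(ch1, ch2)
    t, warn = auto_threshold(ch1, ch2, a, b)
    return manders(ch1, ch2, t, a, b, warning=warn)
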