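"""Hybrid contrast enhancement for low-contrast grayscale images.

The transform runs in two stages. First a histogram-equalization-style
mapping redistributes intensities through the empirical CDF,

    F(k) = lo + (hi - lo) * cdf(k),

where ``lo``/``hi`` are by default the observed minimum and maximum
intensities (preserving the dynamic range of already-windowed images) and
``k`` indexes the ``L`` gray levels. Second, a local-statistics contrast
stretch amplifies deviations from the local mean:

    G(x, y) = Q(x, y) * (F(x, y) - c * mu(x, y)) + mu(x, y)**a,
    Q(x, y) = K * gm / (sigma(x, y) + beta),

with ``mu``/``sigma`` the windowed local mean and standard deviation,
``gm`` the global mean of F, and K, beta, c, a scalar gains. With
``c = a = 1`` this is classical adaptive contrast enhancement. The output
is clipped back to ``[0, L-1]``. Everything here is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "EnhancementParams",
    "IntensityHistogram",
    "to_grayscale",
    "intensity_histogram",
    "histogram_transform",
    "local_stats",
    "contrast_stretch",
    "enhance",
]

#: BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class EnhancementParams:
    """Scalar gains of the contrast-stretch stage.

    Parameters
    ----------
    K : float
        Gain constant of the stretching function Q. Must be positive.
    beta : float
        Stabilizer added to the local standard deviation so Q stays finite
        on flat regions. Must be positive.
    c : float
        Coefficient of the local mean subtracted from F.
    a : float
        Exponent applied to the local mean in the additive term
        (``mu**a``); with ``mean_term="linear"`` it multiplies instead
        (``mu*a``).
    window : int
        Odd side length of the square window for local statistics.
    mean_term : str
        ``"power"`` (default) reads the additive local-mean term as
        ``mu**a``; ``"linear"`` reads it as ``mu*a``.
    """

    K: float = 0.8
    beta: float = 1.0
    c: float = 1.0
    a: float = 1.0
    window: int = 7
    mean_term: str = "power"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.mean_term not in ("power", "linear"):
            raise ValueError(f"mean_term must be 'power' or 'linear', got {self.mean_term!r}")


@dataclass(frozen=True)
class IntensityHistogram:
    """Empirical intensity distribution of a grayscale image over L levels."""

    counts: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray
    levels: int
    total: int


def _validate_gray(img: np.ndarray, levels: int) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    if img.size == 0:
        raise ValueError("empty image")
    if levels < 2:
        raise ValueError(f"level count must be >= 2, got {levels}")
    if img.min() < 0 or img.max() > levels - 1:
        raise ValueError(
            f"pixel values must lie in [0, {levels - 1}], "
            f"got range [{img.min()}, {img.max()}]"
        )
    return img


def to_grayscale(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Convert an M×N×3 raster to a single-channel image (BT.601 luma).

    Already-grayscale 2-D inputs pass through unchanged (as float64).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return _validate_gray(image, levels)
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image @ LUMA_WEIGHTS
        return _validate_gray(gray, levels)
    raise ValueError(
        f"expected an M×N or M×N×3 raster, got shape {np.asarray(image).shape}"
    )


def intensity_histogram(img: np.ndarray, levels: int = 256) -> IntensityHistogram:
    """Probability density and cumulative distribution of pixel intensities.

    Real-valued pixels are binned by flooring to the nearest lower integer
    level. Counts conserve the pixel total M*N; the pdf sums to 1 and the
    cdf is non-decreasing with last entry 1.
    """
    img = _validate_gray(img, levels)
    idx = np.clip(np.floor(img).astype(np.int64), 0, levels - 1)
    counts = np.bincount(idx.ravel(), minlength=levels)
    total = img.size
    pdf = counts / total
    cdf = np.cumsum(pdf)
    return IntensityHistogram(counts=counts, pdf=pdf, cdf=cdf, levels=levels, total=total)


def histogram_transform(
    img: np.ndarray,
    hist: IntensityHistogram | None = None,
    levels: int = 256,
    fixed_range: bool = False,
) -> np.ndarray:
    """CDF-based intensity remapping.

    Each pixel at level ``k`` maps to ``lo + (hi - lo) * cdf[k]``. By
    default ``lo``/``hi`` are the observed min/max intensities; with
    ``fixed_range=True`` they are 0 and L-1. A constant image is returned
    unchanged (the mapping is ill-posed when the observed range collapses).
    """
    img = _validate_gray(img, levels)
    if hist is None:
        hist = intensity_histogram(img, levels)
    if fixed_range:
        lo, hi = 0.0, float(levels - 1)
    else:
        lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return img.copy()
    idx = np.clip(np.floor(img).astype(np.int64), 0, levels - 1)
    return lo + (hi - lo) * hist.cdf[idx]


def local_stats(
    img: np.ndarray, window: int = 7
) -> tuple[np.ndarray, np.ndarray, float]:
    """Windowed local mean and standard deviation plus the global mean.

    Borders are handled by reflect padding. Returns ``(mu, sigma, gm)``
    where ``gm`` is the exact pixel mean of the image.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    mu = uniform_filter(img, size=window, mode="reflect")
    musq = uniform_filter(img * img, size=window, mode="reflect")
    var = np.clip(musq - mu * mu, 0.0, None)
    sigma = np.sqrt(var)
    gm = float(img.mean())
    return mu, sigma, gm


def contrast_stretch(
    F: np.ndarray,
    params: EnhancementParams | None = None,
    levels: int = 256,
    q_override: float | np.ndarray | None = None,
) -> np.ndarray:
    """Local-statistics contrast stretch, clipped to ``[0, L-1]``.

    ``q_override`` replaces the stretching function Q with a fixed value;
    it exists so the algebraic identity limit (Q=1, c=1, a=1 gives G=F) is
    directly checkable.
    """
    if params is None:
        params = EnhancementParams()
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2 or F.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    mu, sigma, gm = local_stats(F, params.window)
    if q_override is not None:
        Q = np.broadcast_to(np.asarray(q_override, dtype=np.float64), F.shape)
    else:
        Q = params.K * gm / (sigma + params.beta)
    if params.mean_term == "power":
        mean_term = np.power(mu, params.a)
    else:
        mean_term = mu * params.a
    # Residual form of Q*(F - c*mu) + mean_term: algebraically identical,
    # but exact (not merely close) in the identity limit Q=1, c=1, a=1.
    residual = F - params.c * mu
    G = F + (Q - 1.0) * residual + (mean_term - params.c * mu)
    return np.clip(G, 0.0, float(levels - 1))


def enhance(
    image: np.ndarray,
    params: EnhancementParams | None = None,
    levels: int = 256,
    fixed_range: bool = False,
) -> np.ndarray:
    """Full enhancement chain: grayscale -> histogram remap -> stretch.

    Deterministic: the same input and parameters always yield bit-identical
    output.
    """
    if params is None:
        params = EnhancementParams()
    gray = to_grayscale(image, levels)
    hist = intensity_histogram(gray, levels)
    F = histogram_transform(gray, hist, levels, fixed_range=fixed_range)
    return contrast_stretch(F, params, levels)
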