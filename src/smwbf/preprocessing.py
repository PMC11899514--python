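"""Ten-image filter-bank augmentation for grayscale ultrasound frames.

Ultrasound acquisition settings vary in gain, dynamic range and depth,
and speckle noise dominates fine texture.  To make downstream detectors
robust to this variation, each input frame is expanded into ten variants
built from four filter families:

* intensity adjustment — linear contrast stretch mapping the 1st/99th
  intensity percentiles to full range;
* adaptive histogram equalization — CLAHE with a configurable clip limit;
* low-pass — Gaussian blur blended with the original,
  ``coeff * blur + (1 - coeff) * original``;
* high-pass — unsharp masking, ``original + coeff * (original - blur)``.

The blend coefficient takes two values (``alpha=1.5``, ``beta=0.5``),
giving two low-pass and two high-pass variants.  The concrete ten-image
grid is: each of the two contrast-enhanced bases (intensity-adjusted and
CLAHE) passed through {identity, low-pass(alpha), low-pass(beta),
high-pass(alpha), high-pass(beta)}.  This 2 x 5 composition is this
package's reconstruction of the scheme — the filter families, the
alpha/beta pair and the count of ten are fixed requirements, but the
exact wiring between them is a design choice documented in
``docs/methods.md``.

All operations work on float64 images in [0, 1] internally and return
the caller's scale (uint8 in → uint8 out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import exposure

__all__ = [
    "PreprocParams",
    "intensity_adjust",
    "adaptive_hist_eq",
    "lowpass",
    "highpass_sharpen",
    "augment_ten",
    "AUGMENT_VARIANTS",
]


@dataclass(frozen=True)
class PreprocParams:
    alpha: float = 1.5
    beta: float = 0.5
    gaussian_sigma: float = 2.0
    clahe_clip: float = 0.01

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0.0):
            raise ValueError(
                f"require alpha > beta > 0, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.gaussian_sigma <= 0.0:
            raise ValueError(f"gaussian_sigma must be positive, got {self.gaussian_sigma}")


def _as_float(img: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return (float image in [0,1], was_uint8)."""
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0, True
    out = img.astype(np.float64)
    if out.size and out.max() > 1.0:  # tolerate [0,255] floats
        out = out / 255.0
    return out, False


def _restore(img: np.ndarray, was_uint8: bool) -> np.ndarray:
    img = np.clip(img, 0.0, 1.0)
    if was_uint8:
        return np.round(img * 255.0).astype(np.uint8)
    return img


def intensity_adjust(img: np.ndarray) -> np.ndarray:
    """Contrast stretch: 1st/99th percentiles mapped to the full range.

    A constant image is returned unchanged.
    """
    f, u8 = _as_float(img)
    lo, hi = np.percentile(f, (1.0, 99.0))
    if hi <= lo:
        return img.copy()
    return _restore(exposure.rescale_intensity(f, in_range=(lo, hi)), u8)


def adaptive_hist_eq(img: np.ndarray, params: PreprocParams = PreprocParams()) -> np.ndarray:
    """CLAHE tile-based equalization; constant images pass through."""
    f, u8 = _as_float(img)
    if np.ptp(f) == 0.0:
        return img.copy()
    # skimage picks 1/8th-of-image tiles; tiny images fall back to one tile.
    kwargs = {}
    if min(f.shape) < 16:
        kwargs["kernel_size"] = f.shape
    return _restore(exposure.equalize_adapthist(f, clip_limit=params.clahe_clip, **kwargs), u8)


def lowpass(img: np.ndarray, coeff: float, params: PreprocParams = PreprocParams()) -> np.ndarray:
    """Gaussian blur blended with the original: coeff·blur + (1−coeff)·img."""
    f, u8 = _as_float(img)
    blur = gaussian_filter(f, sigma=params.gaussian_sigma)
    return _restore(coeff * blur + (1.0 - coeff) * f, u8)


def highpass_sharpen(img: np.ndarray, coeff: float, params: PreprocParams = PreprocParams()) -> np.ndarray:
    """Unsharp masking: img + coeff·(img − blur)."""
    f, u8 = _as_float(img)
    blur = gaussian_filter(f, sigma=params.gaussian_sigma)
    return _restore(f + coeff * (f - blur), u8)


# Deterministic variant order of the ten augmented outputs.
AUGMENT_VARIANTS: tuple[str, ...] = (
    "intensity",
    "intensity_lowpass_alpha",
    "intensity_lowpass_beta",
    "intensity_highpass_alpha",
    "intensity_highpass_beta",
    "clahe",
    "clahe_lowpass_alpha",
    "clahe_lowpass_beta",
    "clahe_highpass_alpha",
    "clahe_highpass_beta",
)


def augment_ten(img: np.ndarray, params: PreprocParams = PreprocParams()) -> list[np.ndarray]:
    """The ten augmented variants of one frame, in :data:`AUGMENT_VARIANTS` order."""
    bases = [intensity_adjust(img), adaptive_hist_eq(img, params)]
    out: list[np.ndarray] = []
    for base in bases:
        out.append(base.copy())
        out.append(lowpass(base, params.alpha, params))
        out.append(lowpass(base, params.beta, params))
        out.append(highpass_sharpen(base, params.alpha, params))
        out.append(highpass_sharpen(base, params.beta, params))
    return out
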