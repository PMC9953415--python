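"""Colour-threshold classification and integrated-density measurement.

The X-gal reaction product deposits a blue precipitate in the cytoplasm of
cells with SA-β-gal activity.  On a brightfield image the stain appears as
blue-teal pixels on a near-white background.  This module classifies
stain-positive pixels by per-channel RGB intensity ranges and measures the
signal as the *integrated density* (ID): the sum of inverted-grayscale
intensities over the positive pixels, so that darker (more stained) pixels
contribute more.  No colour deconvolution or background subtraction is
applied; the measurement is a plain sum over the thresholded selection.

Conventions
-----------
* Images are ``(H, W, 3)`` arrays on the 0–255 scale (uint8 on disk).
* Grayscale conversion is the unweighted channel mean ``(R + G + B) / 3``,
  computed in real arithmetic; ITU-R luminance weights (0.299/0.587/0.114)
  are available via ``luminance=True`` but are not the default.
* Inverted grayscale is ``255 - gray``, so black scores 255 and white 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColorThreshold",
    "SignalMeasurement",
    "apply_color_threshold",
    "to_inverted_gray",
    "measure_signal",
    "render_overlay",
]

#: Highlight colour for QC overlays; pure magenta does not occur in X-gal
#: stained material, so highlighted pixels are unambiguous.
OVERLAY_COLOR = (255, 0, 255)

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ColorThreshold:
    """Inclusive per-channel intensity ranges defining stain-positive pixels.

    A pixel is positive iff every channel lies within its ``[min, max]``
    range (conjunction over R, G, B).  For X-gal on a light background the
    informative bounds are the red/green maxima: stained pixels are darker
    in red and green while retaining blue.
    """

    r_min: int = 0
    r_max: int = 255
    g_min: int = 0
    g_max: int = 255
    b_min: int = 0
    b_max: int = 255

    def __post_init__(self) -> None:
        for ch in "rgb":
            lo = getattr(self, f"{ch}_min")
            hi = getattr(self, f"{ch}_max")
            if not (0 <= lo <= hi <= 255):
                raise ValueError(
                    f"channel {ch}: require 0 <= min <= max <= 255, got [{lo}, {hi}]"
                )

    def contains(self, other: "ColorThreshold") -> bool:
        """True if every range of *other* lies within this threshold's range."""
        return all(
            getattr(self, f"{ch}_min") <= getattr(other, f"{ch}_min")
            and getattr(other, f"{ch}_max") <= getattr(self, f"{ch}_max")
            for ch in "rgb"
        )

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.r_min, self.r_max, self.g_min, self.g_max, self.b_min, self.b_max)


@dataclass(frozen=True)
class SignalMeasurement:
    """Area, integrated density and mean grey of the positive selection.

    ``integrated_density`` is the sum of inverted-grayscale values over the
    positive pixels; on unscaled 8-bit images this equals the raw integrated
    density.  ``mean_gray = integrated_density / area_px`` (0 for an empty
    selection).
    """

    area_px: int
    integrated_density: float
    mean_gray: float

    def __post_init__(self) -> None:
        if self.area_px < 0 or self.integrated_density < 0:
            raise ValueError("area and integrated density must be non-negative")
        if self.integrated_density > 255.0 * self.area_px + 1e-9:
            raise ValueError("integrated density exceeds 255 x area")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img


def apply_color_threshold(img: np.ndarray, thr: ColorThreshold) -> np.ndarray:
    """Classify stain-positive pixels by inclusive per-channel ranges.

    Returns an ``(H, W)`` boolean mask; pixel ``(i, j)`` is True iff each of
    its channels lies in the corresponding ``[min, max]`` range.  No
    morphological post-processing is applied.
    """
    img = _check_rgb(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return (
        (r >= thr.r_min) & (r <= thr.r_max)
        & (g >= thr.g_min) & (g <= thr.g_max)
        & (b >= thr.b_min) & (b <= thr.b_max)
    )


def to_inverted_gray(img: np.ndarray, luminance: bool = False) -> np.ndarray:
    """Convert RGB to inverted grayscale on the 0–255 scale.

    ``inverted = 255 - gray`` with ``gray`` the real-valued (not truncated)
    channel mean, or the ITU-R BT.601 luminance when ``luminance=True``.
    Darker pixels — more X-gal precipitate — map to higher values.
    """
    img = _check_rgb(img).astype(np.float64)
    if luminance:
        gray = img @ _LUMA_WEIGHTS
    else:
        gray = img.mean(axis=2)
    return 255.0 - gray


def measure_signal(
    img: np.ndarray, mask: np.ndarray, luminance: bool = False
) -> SignalMeasurement:
    """Measure area, integrated density and mean grey over a positive mask.

    Only thresholded pixels contribute; there is no background subtraction
    and no deconvolution.  An empty mask yields ``(0, 0.0, 0.0)``.
    """
    img = _check_rgb(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {img.shape[:2]}"
        )
    area = int(mask.sum())
    if area == 0:
        return SignalMeasurement(0, 0.0, 0.0)
    inv = to_inverted_gray(img, luminance=luminance)
    # fsum: correctly-rounded, order-independent sum, so the measurement is
    # reproducible to the last bit regardless of mask layout
    integrated = math.fsum(inv[mask])
    return SignalMeasurement(area, integrated, integrated / area)


def render_overlay(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Return a copy of *img* with positive pixels tinted pure magenta.

    Used for supervised QC: the analyst inspects the overlay to confirm the
    selection covers stained material and nothing else.  Deterministic; an
    empty mask returns an unmodified copy.
    """
    img = _check_rgb(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {img.shape[:2]}"
        )
    out = img.copy()
    out[mask] = OVERLAY_COLOR
    return out
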