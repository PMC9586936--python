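"""Histology preparation: background masking and patch cropping.

FLIM renderings use a dark background for zero-signal areas while scanned
histology slides have a bright field; before the two modalities meet (in
translation training and in registration), the histology background is
blackened.  The pipeline is: greyscale conversion, colour inversion, global
histogram equalisation for contrast, Otsu binarisation, and pixel-wise
multiplication of the resulting tissue mask with the original image.

All coordinates are 0-based with a top-left origin, x = column, y = row, and
rectangles are half-open: [x, x+w) x [y, y+h).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from flimcoreg.visual import equalise

__all__ = [
    "HistologyPatch",
    "otsu_threshold",
    "background_mask",
    "apply_mask",
    "crop_patch",
    "to_grey",
]

LUMA = np.array([0.299, 0.587, 0.114])


def to_grey(rgb: np.ndarray) -> np.ndarray:
    """Standard luma-weighted greyscale conversion; preserves uint8/float scale."""
    arr = np.asarray(rgb)
    if arr.ndim == 2:
        return arr.copy()
    grey = arr[..., :3] @ LUMA
    if np.issubdtype(arr.dtype, np.integer):
        return np.clip(np.round(grey), 0, 255).astype(np.uint8)
    return grey


@dataclass
class HistologyPatch:
    """A rectangular crop of a whole-slide image with its recorded position."""

    rgb: np.ndarray
    origin: tuple[int, int]
    size: tuple[int, int]
    mpp: float | None = None

    def __post_init__(self) -> None:
        if self.rgb.size == 0:
            raise ValueError("patch image is empty")

    def metadata(self) -> dict:
        return {"origin": list(self.origin), "size": list(self.size), "mpp": self.mpp}

    def save_metadata(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.metadata(), f, indent=2)


def otsu_threshold(image: np.ndarray, levels: int = 256) -> int:
    """Otsu's threshold: the grey level maximising between-class variance.

    ``image`` must be an integer single-channel image with values in
    [0, levels).  Pixels <= the returned level form the low class; ties are
    broken towards the lowest level.
    """
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.floating):
        img = np.clip(np.round(img * (levels - 1)), 0, levels - 1).astype(int)
    if img.min() == img.max():
        raise ValueError("constant image: Otsu threshold is undefined")
    hist = np.bincount(img.ravel().astype(int), minlength=levels).astype(float)
    p = hist / hist.sum()
    omega0 = np.cumsum(p)
    mu = np.cumsum(p * np.arange(levels))
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * omega0 - mu) ** 2 / (omega0 * omega1)
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))


def background_mask(rgb: np.ndarray) -> np.ndarray:
    """Tissue mask for a bright-field histology image: 1 on tissue, 0 on background.

    grey -> invert -> equalise -> Otsu binarise.  After inversion the (dark)
    tissue is bright, so pixels above the Otsu level are tissue.
    """
    grey = to_grey(rgb)
    if np.issubdtype(grey.dtype, np.floating):
        grey = np.clip(np.round(grey * 255), 0, 255).astype(np.uint8)
    inverted = (255 - grey).astype(np.uint8)
    if inverted.min() == inverted.max():
        warnings.warn("constant histology image: returning an all-zero mask", RuntimeWarning)
        return np.zeros(grey.shape, dtype=np.uint8)
    enhanced = equalise(inverted)
    level = otsu_threshold(enhanced)
    return (enhanced > level).astype(np.uint8)


def apply_mask(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixel-wise multiplication of the binary mask with the image (per channel)."""
    img = np.asarray(rgb)
    m = np.asarray(mask)
    if m.shape != img.shape[:2]:
        raise ValueError("mask shape must match image spatial shape")
    if img.ndim == 3:
        m = m[:, :, None]
    return (img * m).astype(img.dtype)


def crop_patch(
    wsi: np.ndarray,
    origin: tuple[int, int],
    size: tuple[int, int],
    mpp: float | None = None,
) -> HistologyPatch:
    """Crop a rectangle [x, x+w) x [y, y+h) from a whole-slide image.

    Replaces the interactive cropping step: the recorded origin is what the
    stitching stage later averages into the mosaic layout.
    """
    x, y = origin
    w, h = size
    H, W = wsi.shape[:2]
    if w <= 0 or h <= 0:
        raise ValueError("size must be positive")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(f"rectangle ({x},{y})+({w}x{h}) outside the {W}x{H} WSI")
    return HistologyPatch(rgb=wsi[y : y + h, x : x + w].copy(), origin=(x, y), size=(w, h), mpp=mpp)
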