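"""Registration-quality metrics.

Similarity metrics (MSE, normalised mutual information, normalised
cross-correlation) quantify agreement of the warped and fixed images.  For
multimodal pairs these metrics are known to disagree with visual registration
quality — the FLIM/histology appearance gap means a well-registered pair can
score worse than a misregistered one — so when ground truth is available the
corner-reprojection error of the estimated homography is the authoritative
recovery diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from flimcoreg.histoprep import to_grey
from flimcoreg.register import Homography

__all__ = ["MetricReport", "similarity", "corner_error"]


@dataclass
class MetricReport:
    mse: float
    nmi: float
    ncc: float
    corner_error_px: float | None = None


def _as_grey_float(image: np.ndarray) -> np.ndarray:
    g = to_grey(np.asarray(image, dtype=float))
    return g.astype(float)


def similarity(image_a: np.ndarray, image_b: np.ndarray, metric: str, bins: int = 64) -> float:
    """Similarity between two images: ``mse``, ``nmi`` or ``ncc``.

    Colour inputs are luma-converted first.  NMI is the symmetric variant
    2 I(A;B) / (H(A) + H(B)) on a joint histogram with equal-width bins.
    """
    a = _as_grey_float(image_a)
    b = _as_grey_float(image_b)
    if a.shape != b.shape:
        raise ValueError("image shapes must match")
    if metric == "mse":
        return float(np.mean((a - b) ** 2))
    if a.min() == a.max() or b.min() == b.max():
        raise ValueError(f"constant image: {metric} is undefined")
    if metric == "ncc":
        an = a - a.mean()
        bn = b - b.mean()
        return float((an * bn).sum() / np.sqrt((an**2).sum() * (bn**2).sum()))
    if metric == "nmi":
        joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
        pxy = joint / joint.sum()
        px = pxy.sum(axis=1)
        py = pxy.sum(axis=0)
        nz = pxy > 0
        hxy = -np.sum(pxy[nz] * np.log(pxy[nz]))
        hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
        hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
        mi = hx + hy - hxy
        return float(2.0 * mi / (hx + hy))
    raise ValueError(f"unknown metric {metric!r}")


def corner_error(H_est: Homography | np.ndarray, H_true: Homography | np.ndarray, N: int) -> float:
    """Mean displacement (px) of the four image corners under H_est vs H_true."""
    He = H_est if isinstance(H_est, Homography) else Homography(np.asarray(H_est))
    Ht = H_true if isinstance(H_true, Homography) else Homography(np.asarray(H_true))
    corners = np.array([[0, 0], [N - 1, 0], [0, N - 1], [N - 1, N - 1]], dtype=float)
    pe = He.apply(corners)
    pt = Ht.apply(corners)
    return float(np.linalg.norm(pe - pt, axis=1).mean())


def report(
    warped: np.ndarray,
    fixed: np.ndarray,
    H_est=None,
    H_true=None,
    N: int | None = None,
    bins: int = 64,
) -> MetricReport:
    """Convenience bundle of all metrics for one registration outcome."""
    ce = None
    if H_est is not None and H_true is not None and N is not None:
        ce = corner_error(H_est, H_true, N)
    return MetricReport(
        mse=similarity(warped, fixed, "mse"),
        nmi=similarity(warped, fixed, "nmi", bins=bins),
        ncc=similarity(warped, fixed, "ncc"),
        corner_error_px=ce,
    )
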