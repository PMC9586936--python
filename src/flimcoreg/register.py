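"""Homography regression under a windowed partial-photometric L1 (PPM) loss.

The moving image (a false-histology rendering of a FLIM tile) is aligned to a
fixed histology patch by directly optimising the 3x3 homography matrix H with
plain gradient descent on the photometric L1 loss.  Because the cropped patch
has a larger field of view than the FLIM tile, the border frame of the fixed
image contains content the moving image cannot explain; the loss is therefore
restricted to a centred square window (the "partial photometric" mask), and
the surrounding hollow-rectangle frame is excluded.

The warp is an inverse-mapped bilinear resampler written so that the exact
analytic gradient of the masked loss with respect to every entry of H is
available — this is what makes the plain gradient-descent schedule of
`regress` work.  Internally H is conditioned by expressing pixel coordinates
in [-1, 1]; the public matrix is always in pixel coordinates with h33 = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Homography",
    "PpmWindow",
    "RegressionConfig",
    "RegistrationResult",
    "warp",
    "warp_grad",
    "ppm_mask",
    "ppm_l1",
    "ppm_loss_and_grad",
    "regress",
    "blend",
]


@dataclass(frozen=True)
class Homography:
    """3x3 projective transform acting on homogeneous pixel coordinates [x, y, 1]^T."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if not np.all(np.isfinite(m)):
            raise ValueError("homography entries must be finite")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Homography":
        m = np.eye(3)
        m[0, 2] = tx
        m[1, 2] = ty
        return cls(m)

    def normalised(self) -> "Homography":
        """Return the same transform scaled so h33 = 1."""
        m = self.matrix
        if abs(m[2, 2]) < 1e-12:
            return self
        return Homography(m / m[2, 2])

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of pixel points through the homography."""
        pts = np.asarray(points, dtype=float)
        ph = np.concatenate([pts, np.ones((len(pts), 1))], axis=1)
        q = ph @ self.matrix.T
        return q[:, :2] / q[:, 2:3]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"H": self.normalised().matrix.tolist()}, f, indent=2)

    @classmethod
    def from_json(cls, path) -> "Homography":
        with open(path) as f:
            return cls(np.asarray(json.load(f)["H"]))


@dataclass(frozen=True)
class PpmWindow:
    """Side length, in pixels, of the centred square over which the loss is taken."""

    w: int

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("window side must be positive")


@dataclass
class RegressionConfig:
    """Gradient-descent schedule for the homography regression.

    Defaults follow the fixed schedule used throughout the comparison study:
    200 epochs, learning rate 0.01 decayed by a factor of 10 at epoch 100,
    a 200-pixel PPM window on 256-pixel images.
    """

    epochs: int = 200
    learning_rate: float = 0.01
    decay_factor: float = 0.1
    decay_epoch: int = 100
    window: PpmWindow = field(default_factory=lambda: PpmWindow(200))
    image_side: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.window, int):
            self.window = PpmWindow(self.window)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay_factor must be in (0, 1]")


@dataclass
class RegistrationResult:
    H_final: Homography
    loss_trace: np.ndarray
    warped: np.ndarray
    converged: bool


# ---------------------------------------------------------------------------
# warping

def _sample_coords(image: np.ndarray, G: np.ndarray, out_shape: tuple[int, int]):
    """Source coordinates (qx, qy, u, v, w) for each output pixel under grid matrix G."""
    oh, ow = out_shape
    xs, ys = np.meshgrid(np.arange(ow, dtype=float), np.arange(oh, dtype=float))
    u = G[0, 0] * xs + G[0, 1] * ys + G[0, 2]
    v = G[1, 0] * xs + G[1, 1] * ys + G[1, 2]
    w = G[2, 0] * xs + G[2, 1] * ys + G[2, 2]
    w = np.where(np.abs(w) < 1e-12, 1e-12, w)
    return u / w, v / w, u, v, w, xs, ys


def _bilinear(image: np.ndarray, qx: np.ndarray, qy: np.ndarray):
    """Bilinear sample with zero fill outside; also returns d/dqx and d/dqy.

    ``image`` is (H, W) or (H, W, C); returned arrays share its trailing shape.
    """
    grey = image.ndim == 2
    img = image[:, :, None] if grey else image
    H, W, C = img.shape
    x0 = np.floor(qx).astype(int)
    y0 = np.floor(qy).astype(int)
    fx = qx - x0
    fy = qy - y0

    def fetch(yy, xx):
        valid = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        out = np.zeros(yy.shape + (C,), dtype=float)
        out[valid] = img[yy[valid], xx[valid]]
        return out

    p00 = fetch(y0, x0)
    p01 = fetch(y0, x0 + 1)
    p10 = fetch(y0 + 1, x0)
    p11 = fetch(y0 + 1, x0 + 1)
    fx_ = fx[..., None]
    fy_ = fy[..., None]
    top = p00 * (1 - fx_) + p01 * fx_
    bot = p10 * (1 - fx_) + p11 * fx_
    val = top * (1 - fy_) + bot * fy_
    dqx = (p01 - p00) * (1 - fy_) + (p11 - p10) * fy_
    dqy = bot - top
    if grey:
        return val[..., 0], dqx[..., 0], dqy[..., 0]
    return val, dqx, dqy


def warp(image: np.ndarray, H: Homography | np.ndarray, out_size: tuple[int, int] | None = None) -> np.ndarray:
    """Warp ``image`` by homography ``H`` (moving -> fixed pixel coordinates).

    Inverse-mapped resampling: each output pixel samples the input at the
    H^-1-transformed location with bilinear interpolation; samples falling
    outside the source are zero.
    """
    Hm = H.matrix if isinstance(H, Homography) else Homography(np.asarray(H)).matrix
    if out_size is None:
        out_shape = image.shape[:2]
    else:
        out_shape = (int(out_size[1]), int(out_size[0]))  # (h, w) from (w, h)
    G = np.linalg.inv(Hm)
    qx, qy, *_ = _sample_coords(image, G, out_shape)
    val, _, _ = _bilinear(np.asarray(image, dtype=float), qx, qy)
    return val


def warp_grad(image: np.ndarray, H: Homography | np.ndarray, out_size=None):
    """Warp plus the exact Jacobian of every output pixel w.r.t. the 9 entries of H.

    Returns ``(warped, jac)`` with ``jac`` of shape ``(3, 3) + warped.shape``.
    Intended for verification and small images; `regress` uses the fused
    loss-gradient path instead.
    """
    Hm = (H.matrix if isinstance(H, Homography) else np.asarray(H, dtype=float))
    out_shape = image.shape[:2] if out_size is None else (int(out_size[1]), int(out_size[0]))
    G = np.linalg.inv(Hm)
    qx, qy, u, v, w, xs, ys = _sample_coords(image, G, out_shape)
    val, dIdqx, dIdqy = _bilinear(np.asarray(image, dtype=float), qx, qy)
    ones = np.ones_like(xs)
    p = np.stack([xs, ys, ones])  # (3, h, w)
    # d(warped)/dG_ij, then chain through dG/dH = -G E G
    extra = (1,) * (val.ndim - 2)
    jacG = np.zeros((3, 3) + val.shape)
    for j in range(3):
        pj = p[j].reshape(p[j].shape + extra)
        jacG[0, j] = dIdqx * (pj / w.reshape(w.shape + extra))
        jacG[1, j] = dIdqy * (pj / w.reshape(w.shape + extra))
        jacG[2, j] = -(dIdqx * u.reshape(u.shape + extra) + dIdqy * v.reshape(v.shape + extra)) * pj / (
            w.reshape(w.shape + extra) ** 2
        )
    jacH = -np.einsum("ki,ij...,jl->kl...", G.T, jacG, G.T)
    return val, jacH


def ppm_mask(N: int, window: PpmWindow | int) -> np.ndarray:
    """Binary mask: 1 on the centred w x w square, 0 on the excluded border frame."""
    w = window.w if isinstance(window, PpmWindow) else int(window)
    if w > N:
        raise ValueError(f"window {w} exceeds image side {N}")
    if w <= 0:
        raise ValueError("window side must be positive")
    off = (N - w) // 2
    mask = np.zeros((N, N), dtype=bool)
    mask[off : off + w, off : off + w] = True
    return mask


def ppm_l1(warped: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute difference over masked pixels (and channels), images in [0, 1]."""
    if warped.shape != target.shape:
        raise ValueError("image shapes must match")
    m = np.asarray(mask, dtype=bool)
    if m.shape != warped.shape[:2]:
        raise ValueError("mask shape must match image spatial shape")
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty PPM mask")
    diff = np.abs(warped - target)
    if warped.ndim == 3:
        return float(diff[m].sum() / (n * warped.shape[2]))
    return float(diff[m].sum() / n)


def ppm_loss_and_grad(moving: np.ndarray, fixed: np.ndarray, H: np.ndarray, mask: np.ndarray):
    """PPM L1 loss and its exact gradient with respect to the 9 entries of H.

    ``H`` maps moving to fixed pixel coordinates; the mask lives in the fixed
    frame.  Returns ``(loss, grad (3, 3), warped)``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    m = np.asarray(mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty PPM mask")
    G = np.linalg.inv(np.asarray(H, dtype=float))
    qx, qy, u, v, w, xs, ys = _sample_coords(moving, G, fixed.shape[:2])
    val, dIdqx, dIdqy = _bilinear(moving, qx, qy)
    diff = val - fixed
    channels = moving.shape[2] if moving.ndim == 3 else 1
    denom = n * channels
    loss = float(np.abs(diff)[m].sum() / denom)
    sgn = np.sign(diff) / denom
    sgn[~m] = 0.0
    if moving.ndim == 3:
        gx = (sgn * dIdqx).sum(axis=2)
        gy = (sgn * dIdqy).sum(axis=2)
    else:
        gx = sgn * dIdqx
        gy = sgn * dIdqy
    p = (xs, ys, np.ones_like(xs))
    gradG = np.zeros((3, 3))
    a = gx / w
    b = gy / w
    c = -(gx * u + gy * v) / (w * w)
    for j in range(3):
        gradG[0, j] = (a * p[j]).sum()
        gradG[1, j] = (b * p[j]).sum()
        gradG[2, j] = (c * p[j]).sum()
    gradH = -(G.T @ gradG @ G.T)
    return loss, gradH, val


def _norm_matrices(h: int, w: int):
    """Pixel -> [-1, 1] coordinate normalisation matrix and its inverse."""
    T = np.array(
        [
            [2.0 / max(w - 1, 1), 0.0, -1.0],
            [0.0, 2.0 / max(h - 1, 1), -1.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return T, np.linalg.inv(T)


def _prepare(img: np.ndarray, side: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.max() > 1.0 + 1e-9:
        img = img / 255.0
    if img.shape[:2] != (side, side):
        img = _sk_resize(img, (side, side), anti_aliasing=True, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def regress(
    false_histology: np.ndarray,
    histology_patch: np.ndarray,
    config: RegressionConfig | None = None,
) -> RegistrationResult:
    """Estimate the homography aligning the moving image to the fixed patch.

    Starting from the identity matrix, each epoch warps the moving image by
    the current H, evaluates the PPM L1 loss under the centred window, and
    updates all 9 entries of H by plain gradient descent at the scheduled
    learning rate (multiplied by ``decay_factor`` at ``decay_epoch``).  The
    reported homography is the one with the minimum loss over all epochs.
    """
    config = config or RegressionConfig()
    N = config.image_side
    moving = _prepare(false_histology, N)
    fixed = _prepare(histology_patch, N)
    if (moving.ndim == 3) != (fixed.ndim == 3):
        raise ValueError("moving and fixed images must both be RGB or both greyscale")
    mask = ppm_mask(N, config.window)
    T, Tinv = _norm_matrices(N, N)

    Hn = np.eye(3)  # H in normalised coordinates
    best = (np.inf, Hn.copy())
    trace = np.empty(config.epochs)
    lr = config.learning_rate
    for epoch in range(config.epochs):
        if epoch == config.decay_epoch:
            lr *= config.decay_factor
        Hp = Tinv @ Hn @ T
        loss, gradHp, _ = ppm_loss_and_grad(moving, fixed, Hp, mask)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite PPM loss at epoch {epoch}; H = {Hp.tolist()}"
            )
        trace[epoch] = loss
        if loss < best[0]:
            best = (loss, Hn.copy())
        gradHn = Tinv.T @ gradHp @ T.T  # chain rule through Hp = Tinv Hn T
        Hn = Hn - lr * gradHn

    H_best = Homography(Tinv @ best[1] @ T).normalised()
    warped = warp(moving, H_best, out_size=(N, N))
    converged = best[0] <= trace[0]
    return RegistrationResult(H_final=H_best, loss_trace=trace, warped=warped, converged=converged)


def blend(image_a: np.ndarray, image_b: np.ndarray, mode: str = "greyscale", alpha: float = 0.5) -> np.ndarray:
    """Blend two registered images for visual inspection.

    ``greyscale`` mode renders image_a in green and image_b in magenta (R+B),
    the convention used throughout for FLIM vs histology overlays; identical
    inputs therefore blend to neutral grey.  ``colour`` mode is plain alpha
    composition ``alpha * a + (1 - alpha) * b``.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape[:2] != b.shape[:2]:
        raise ValueError("image shapes must match")
    if mode == "greyscale":
        ga = a if a.ndim == 2 else a @ np.array([0.299, 0.587, 0.114])
        gb = b if b.ndim == 2 else b @ np.array([0.299, 0.587, 0.114])
        return np.stack([gb, ga, gb], axis=-1)
    if mode == "colour":
        if a.shape != b.shape:
            raise ValueError("colour blending requires identical shapes")
        return alpha * a + (1 - alpha) * b
    raise ValueError(f"unknown blend mode {mode!r}")
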