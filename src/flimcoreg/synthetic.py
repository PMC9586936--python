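"""Synthetic phantoms with known ground truth for every pipeline stage.

The generators emulate the acquisition geometry of a full-spectral FLIM
microarray scan — Poisson mono-exponential decay hypercubes with
region-dependent lifetimes, H&E-like pseudo-histology textures sharing the
region geometry, warped image pairs with a known homography, and overlapping
tile grids — so that reconstruction, translation, registration and stitching
are all testable without any downloaded data.  Everything is a pure function
of its spec and seed.

The default desk-scale cube is 64 x 64 spatial, 16 spectral bands over
500-780 nm and 32 time channels of 0.4 ns, with ~1e4 counts per pixel at the
shortest wavelength rolling off towards the red end — small enough that the
full pipeline runs in seconds while keeping the lifetime-fit statistics of
the full-size measurement.  The two default tissue regions use lifetimes of
1.5 ns and 3.0 ns, the printed adenocarcinoma vs healthy-alveoli contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian

from flimcoreg.hypercube import FlimHypercube
from flimcoreg.register import Homography, warp
from flimcoreg.stitch import MosaicLayout

__all__ = [
    "PhantomSpec",
    "poisson_decay",
    "make_phantom",
    "make_texture",
    "make_warped_pair",
    "make_tile_grid",
    "two_region_map",
    "random_homography",
]

#: H&E-like palette for pseudo-histology rendering (RGB in [0, 1])
STROMA_PINK = np.array([0.91, 0.74, 0.82])
NUCLEUS_PURPLE = np.array([0.38, 0.18, 0.50])
BACKGROUND_WHITE = np.array([0.97, 0.96, 0.97])


def two_region_map(size: int = 64) -> np.ndarray:
    """Left/right half-plane region map: label 0 (tumour) vs 1 (alveoli)."""
    m = np.zeros((size, size), dtype=int)
    m[:, size // 2 :] = 1
    return m


@dataclass
class PhantomSpec:
    """Everything needed to generate one synthetic FLIM tile and its histology twin."""

    size: int = 64
    region_map: np.ndarray | None = None  # label per pixel; default two-region
    taus_ns: tuple[float, ...] = (1.5, 3.0)  # per-region lifetimes
    amplitudes: tuple[float, ...] = (1e4, 1e4)  # per-region total counts/pixel at band 0
    n_bands: int = 16
    n_time: int = 32
    time_bin_ns: float = 0.4
    wavelength_range_nm: tuple[float, float] = (500.0, 780.0)
    rolloff_band: int | None = None  # intensity halves past this band; None = flat
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.taus_ns):
            raise ValueError("region lifetimes must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if self.region_map is None:
            self.region_map = two_region_map(self.size)
        self.region_map = np.asarray(self.region_map, dtype=int)
        if self.region_map.shape != (self.size, self.size):
            raise ValueError("region map must be size x size")
        if self.region_map.max() >= len(self.taus_ns):
            raise ValueError("region label without a lifetime assignment")

    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range_nm, self.n_bands)

    def band_scale(self) -> np.ndarray:
        """Per-band intensity scaling emulating the red-end roll-off of emission."""
        s = np.arange(self.n_bands, dtype=float)
        if self.rolloff_band is None:
            return np.ones(self.n_bands)
        return 1.0 / (1.0 + np.exp((s - self.rolloff_band) / 2.0))


def poisson_decay(
    tau: float,
    total_counts: float,
    T: int = 32,
    bin_width: float = 0.4,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Poisson-sampled mono-exponential decay histogram over ``T`` bins.

    The expected histogram is proportional to ``exp(-t / tau)`` at the bin
    centres, normalised to ``total_counts`` expected photons in the window.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if T < 3:
        raise ValueError("need at least 3 time bins")
    rng = np.random.default_rng(rng)
    t = (np.arange(T) + 0.5) * bin_width
    expected = np.exp(-t / tau)
    expected *= total_counts / expected.sum()
    return rng.poisson(expected)


def _decay_expectation(tau_map, amp_map, t):
    """Expected counts (x, y, t) for per-pixel lifetimes and total-count amplitudes."""
    shape = tau_map.shape + (len(t),)
    exp_map = np.zeros(shape)
    for tau in np.unique(tau_map):
        decay = np.exp(-t / tau)
        decay /= decay.sum()
        m = tau_map == tau
        exp_map[m] = amp_map[m, None] * decay
    return exp_map


def make_texture(
    size: int,
    seed: int = 0,
    n_blobs: int = 120,
    blob_radius: tuple[float, float] = (3.0, 9.0),
    blur_sigma: float = 1.0,
    region_mask: np.ndarray | None = None,
    background: np.ndarray = BACKGROUND_WHITE,
) -> np.ndarray:
    """H&E-like RGB texture: purple nuclei blobs over pink stroma on a bright field.

    ``region_mask`` restricts blob centres (and stroma) to a region, which is
    how phantoms put informative structure exactly where an experiment needs
    it (e.g. only in an annular rim).
    """
    rng = np.random.default_rng(seed)
    img = np.ones((size, size, 3)) * background
    yy, xx = np.mgrid[0:size, 0:size]
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        img[region_mask] = STROMA_PINK
        candidates = np.argwhere(region_mask)
    else:
        img[:] = STROMA_PINK
        candidates = None
    for _ in range(n_blobs):
        if candidates is not None:
            if len(candidates) == 0:
                break
            cy, cx = candidates[rng.integers(len(candidates))]
        else:
            cy, cx = rng.integers(0, size, 2)
        r = rng.uniform(*blob_radius)
        shade = rng.uniform(0.7, 1.3)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        img[blob] = np.clip(NUCLEUS_PURPLE * shade, 0, 1)
    img = gaussian(img, sigma=blur_sigma, channel_axis=-1)
    return np.clip(img, 0.0, 1.0)


def make_phantom(spec: PhantomSpec):
    """Generate a synthetic FLIM tile and its ground truth.

    Returns
    -------
    cube : FlimHypercube
        Poisson decay hypercube with region-wise lifetimes.
    tau_map : ndarray
        Ground-truth lifetime per pixel (ns).
    pseudo_histology : ndarray
        H&E-like RGB image sharing the exact region geometry: region-0 pixels
        are rendered densely nucleated (tumour-like), other regions as sparser
        stroma, so FLIM and histology share structure but differ in appearance.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.region_map
    tau_map = np.asarray(spec.taus_ns, dtype=float)[labels]
    amp_map = np.asarray(spec.amplitudes, dtype=float)[labels]
    t = (np.arange(spec.n_time) + 0.5) * spec.time_bin_ns
    base = _decay_expectation(tau_map, amp_map, t)  # (x, y, t)
    scale = spec.band_scale()
    expected = base[:, :, None, :] * scale[None, None, :, None]
    counts = rng.poisson(expected)
    cube = FlimHypercube(
        counts=counts,
        wavelengths=spec.wavelengths(),
        time_bin_ns=spec.time_bin_ns,
    )

    # pseudo-histology: same geometry, H&E appearance, denser nuclei in region 0
    histo = make_texture(
        spec.size,
        seed=spec.seed + 1,
        n_blobs=max(10, spec.size**2 // 60),
        blob_radius=(2.0, max(3.0, spec.size / 16)),
        region_mask=labels == 0,
    )
    sparse = make_texture(
        spec.size,
        seed=spec.seed + 2,
        n_blobs=max(3, spec.size**2 // 400),
        blob_radius=(1.5, max(2.5, spec.size / 24)),
        region_mask=labels != 0,
    )
    histo = np.where((labels == 0)[:, :, None], histo, sparse)
    return cube, tau_map, histo


def random_homography(
    N: int,
    rng: np.random.Generator | int | None = None,
    max_translation_px: float = 10.0,
    max_rotation_deg: float = 5.0,
    scale_range: tuple[float, float] = (0.95, 1.05),
    max_perspective: float = 1e-4,
) -> Homography:
    """Random ground-truth homography about the image centre, in pixel coordinates."""
    rng = np.random.default_rng(rng)
    ang = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    s = rng.uniform(*scale_range)
    tx, ty = rng.uniform(-max_translation_px, max_translation_px, 2)
    px, py = rng.uniform(-max_perspective, max_perspective, 2)
    c = (N - 1) / 2.0
    centre = np.array([[1, 0, -c], [0, 1, -c], [0, 0, 1.0]])
    A = np.array(
        [
            [s * np.cos(ang), -s * np.sin(ang), tx],
            [s * np.sin(ang), s * np.cos(ang), ty],
            [px, py, 1.0],
        ]
    )
    H = np.linalg.inv(centre) @ A @ centre
    return Homography(H).normalised()


def make_warped_pair(
    image: np.ndarray,
    H_true: Homography,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
):
    """Ground-truth registration pair: (moving, fixed, H_true).

    ``fixed = warp(image, H_true)`` plus clipped Gaussian noise; `regress`
    applied to the pair should recover ``H_true``.
    """
    rng = np.random.default_rng(rng)
    fixed = warp(image, H_true)
    if noise_sd > 0:
        fixed = fixed + rng.normal(0.0, noise_sd, fixed.shape)
    return np.asarray(image, dtype=float), np.clip(fixed, 0.0, 1.0), H_true


def make_fov_pair(
    patch_fov_px: int,
    seed: int = 12,
    scene_size: int = 512,
    moving_side: int = 256,
    ring_band: tuple[int, int] | None = None,
    n_blobs: int = 1600,
    blob_radius: tuple[float, float] = (4.0, 14.0),
    blur_sigma: float = 2.0,
):
    """Moving tile and fixed patch with different fields of view, from one scene.

    The moving image is the central ``moving_side`` crop of a textured scene;
    the fixed patch is the central ``patch_fov_px`` crop resized to
    ``moving_side``, so the true homography is a pure scaling about the image
    centre.  This reproduces the situation the window choice of the PPM loss
    has to cope with: a patch with a larger field of view surrounds the
    warped moving image with content it cannot explain, while ``ring_band``
    (a sup-norm annulus, in scene pixels from the centre, outside which and
    inside which the scene is a uniform bright field) concentrates all
    informative structure away from the centre, starving small windows.

    Returns ``(moving, patch, H_true)``.
    """
    from skimage.transform import resize as _resize

    if ring_band is not None:
        yy, xx = np.mgrid[0:scene_size, 0:scene_size]
        r = np.maximum(np.abs(yy - scene_size / 2), np.abs(xx - scene_size / 2))
        lo, hi = ring_band
        scene = make_texture(
            scene_size, seed=seed, n_blobs=n_blobs, blob_radius=blob_radius,
            blur_sigma=blur_sigma, region_mask=(r > lo) & (r < hi),
        )
        scene[r < lo - 2] = BACKGROUND_WHITE  # exactly uniform interior
    else:
        scene = make_texture(
            scene_size, seed=seed, n_blobs=n_blobs, blob_radius=blob_radius, blur_sigma=blur_sigma
        )

    def central(img, side):
        o = (img.shape[0] - side) // 2
        return img[o : o + side, o : o + side]

    moving = central(scene, moving_side)
    patch = _resize(
        central(scene, patch_fov_px), (moving_side, moving_side),
        anti_aliasing=True, preserve_range=True,
    )
    s = moving_side / patch_fov_px
    c = (moving_side - 1) / 2
    H_true = Homography(
        np.array([[s, 0.0, c * (1 - s)], [0.0, s, c * (1 - s)], [0.0, 0.0, 1.0]])
    )
    return moving, np.clip(patch, 0.0, 1.0), H_true


def make_tile_grid(
    mosaic: np.ndarray,
    rows: int,
    cols: int,
    overlap_px: int = 8,
    jitter_px: int = 0,
    seed: int = 0,
):
    """Cut an overlapping (optionally jittered) tile grid from a mosaic image.

    Returns ``(tiles, grid_indices, true_layout)`` where ``tiles[i]`` was cut
    at ``true_layout.offsets[i]`` — the exact positions, jitter included — and
    ``grid_indices[i]`` is the (row, col) of the tile in the scan order.
    """
    h, w = mosaic.shape[:2]
    if overlap_px < 0 or jitter_px < 0:
        raise ValueError("overlap and jitter must be non-negative")
    ts_x = -(-(w + (cols - 1) * overlap_px) // cols) if cols > 1 else w
    ts_y = -(-(h + (rows - 1) * overlap_px) // rows) if rows > 1 else h
    if ts_x <= 0 or ts_y <= 0 or ts_x > w or ts_y > h:
        raise ValueError("tile geometry infeasible for this mosaic size")
    rng = np.random.default_rng(seed)
    tiles, indices, offsets = [], [], []
    for r in range(rows):
        for c in range(cols):
            # base grid spans the full mosaic so the last tile reaches the edge
            x = round(c * (w - ts_x) / (cols - 1)) if cols > 1 else 0
            y = round(r * (h - ts_y) / (rows - 1)) if rows > 1 else 0
            if jitter_px:
                x += int(rng.integers(-jitter_px, jitter_px + 1))
                y += int(rng.integers(-jitter_px, jitter_px + 1))
            x = int(np.clip(x, 0, w - ts_x))
            y = int(np.clip(y, 0, h - ts_y))
            tiles.append(mosaic[y : y + ts_y, x : x + ts_x].copy())
            indices.append((r, c))
            offsets.append((float(x), float(y)))
    layout = MosaicLayout(
        offsets=offsets,
        canvas_size=(w, h),
        grid_shape=(rows, cols),
        grid_indices=indices,
    )
    return tiles, indices, layout
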