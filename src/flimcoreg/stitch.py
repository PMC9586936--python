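"""Mosaic assembly of registered tiles and cell-level spectral profiling.

Adjacent FLIM tiles are acquired with overlap across a microarray; once each
tile is registered to its histology patch, the recorded patch positions are
averaged into a regular grid layout and the tiles are pasted onto one canvas,
optionally over the whole-slide histology image.  Overlapping pixels are
averaged, with zero-valued (photon-filtered) pixels excluded so the dark
background of one tile does not dim tissue from its neighbour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["MosaicLayout", "average_layout", "compose", "cell_profile"]


@dataclass
class MosaicLayout:
    """Tile-to-canvas placement.

    offsets : list of (x, y) canvas offsets, in tile order.
    canvas_size : (width, height) in pixels.
    grid_shape : (rows, cols) when the acquisition is a regular grid.
    grid_indices : per-tile (row, col), aligned with ``offsets``.
    spacing : recovered (sx, sy) mean tile spacing, if estimated.
    """

    offsets: list[tuple[float, float]]
    canvas_size: tuple[int, int] | None = None
    grid_shape: tuple[int, int] | None = None
    grid_indices: list[tuple[int, int]] | None = None
    spacing: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for x, y in self.offsets:
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError("offsets must be finite")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "offsets": [list(o) for o in self.offsets],
                    "canvas_size": self.canvas_size,
                    "grid_shape": self.grid_shape,
                    "grid_indices": [list(g) for g in self.grid_indices] if self.grid_indices else None,
                    "spacing": self.spacing,
                },
                f,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "MosaicLayout":
        with open(path) as f:
            d = json.load(f)
        return cls(
            offsets=[tuple(o) for o in d["offsets"]],
            canvas_size=tuple(d["canvas_size"]) if d.get("canvas_size") else None,
            grid_shape=tuple(d["grid_shape"]) if d.get("grid_shape") else None,
            grid_indices=[tuple(g) for g in d["grid_indices"]] if d.get("grid_indices") else None,
            spacing=tuple(d["spacing"]) if d.get("spacing") else None,
        )


def average_layout(
    patch_positions: list[tuple[tuple[int, int], tuple[float, float]]],
    snap: bool = True,
) -> MosaicLayout:
    """Average recorded patch positions into a mosaic layout.

    Each entry is ``((row, col), (x, y))`` — the grid index of a tile and the
    recorded position of its cropped histology patch.  The mean horizontal and
    vertical spacings are estimated from adjacent-tile displacements; with
    ``snap`` (default) every tile is placed on the regular grid defined by
    those means anchored at the mean origin, which is what "simply averaging"
    the patch positions amounts to.  ``snap=False`` passes the raw positions
    through (useful when per-tile placements are already trusted).
    """
    if not patch_positions:
        raise ValueError("need at least one position")
    idx = {tuple(g): np.asarray(p, dtype=float) for g, p in patch_positions}
    order = [tuple(g) for g, _ in patch_positions]
    if len(patch_positions) == 1:
        (g, p), = patch_positions
        return MosaicLayout(offsets=[tuple(map(float, p))], grid_indices=[tuple(g)], spacing=None)

    dx = [idx[(r, c + 1)][0] - idx[(r, c)][0] for (r, c) in idx if (r, c + 1) in idx]
    dy = [idx[(r + 1, c)][1] - idx[(r, c)][1] for (r, c) in idx if (r + 1, c) in idx]
    sx = float(np.mean(dx)) if dx else 0.0
    sy = float(np.mean(dy)) if dy else 0.0
    origins = np.array([idx[(r, c)] - [c * sx, r * sy] for (r, c) in order])
    origin = origins.mean(axis=0)
    rows = max(r for r, _ in order) + 1
    cols = max(c for _, c in order) + 1
    if snap:
        offsets = [(float(origin[0] + c * sx), float(origin[1] + r * sy)) for (r, c) in order]
    else:
        offsets = [tuple(map(float, idx[g])) for g in order]
    return MosaicLayout(
        offsets=offsets,
        grid_shape=(rows, cols),
        grid_indices=list(order),
        spacing=(sx, sy),
    )


def compose(
    tiles: list[np.ndarray],
    layout: MosaicLayout,
    background: np.ndarray | None = None,
    alpha: float = 1.0,
    exclude_zero: bool = True,
) -> np.ndarray:
    """Paste tiles at their layout offsets, averaging overlaps.

    Overlapping pixels are combined by unweighted mean; when ``exclude_zero``
    (default) pixels that are exactly zero in a tile (the filtered dark
    background) do not participate in the average.  An optional background
    image (canvas-sized) is composited beneath with weight ``1 - alpha``
    where tiles are present and shown unchanged elsewhere.
    """
    if len(tiles) != len(layout.offsets):
        raise ValueError("layout does not cover all tiles")
    multichannel = tiles[0].ndim == 3
    if layout.canvas_size is not None:
        cw, ch = layout.canvas_size
    else:
        cw = max(int(round(x)) + t.shape[1] for t, (x, y) in zip(tiles, layout.offsets))
        ch = max(int(round(y)) + t.shape[0] for t, (x, y) in zip(tiles, layout.offsets))
    C = tiles[0].shape[2] if multichannel else 1
    acc = np.zeros((ch, cw, C), dtype=float)
    cnt = np.zeros((ch, cw, C), dtype=float)
    for tile, (x, y) in zip(tiles, layout.offsets):
        t = np.asarray(tile, dtype=float)
        if t.ndim == 2:
            t = t[:, :, None]
        xi, yi = int(round(x)), int(round(y))
        th, tw = t.shape[:2]
        if xi < 0 or yi < 0 or xi + tw > cw or yi + th > ch:
            raise ValueError(f"tile at ({x}, {y}) falls outside the {cw}x{ch} canvas")
        if exclude_zero:
            nz = np.any(t != 0, axis=2, keepdims=True) * np.ones_like(t)
        else:
            nz = np.ones_like(t)
        acc[yi : yi + th, xi : xi + tw] += t * nz
        cnt[yi : yi + th, xi : xi + tw] += nz
    covered = cnt > 0
    out = np.zeros_like(acc)
    out[covered] = acc[covered] / cnt[covered]
    if background is not None:
        bg = np.asarray(background, dtype=float)
        if bg.ndim == 2:
            bg = bg[:, :, None]
        if bg.shape[:2] != (ch, cw):
            raise ValueError("background must match the canvas size")
        out = np.where(covered, alpha * out + (1 - alpha) * bg, bg)
    if not multichannel:
        out = out[:, :, 0]
    return out


def cell_profile(
    lifetime_stack: np.ndarray,
    location: tuple[int, int],
    wavelengths: np.ndarray | None = None,
    band_range_nm: tuple[float, float] | None = None,
    half: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral lifetime profile of a cell at ``location`` = (x, y).

    Because single cells span a few pixels, the lifetime within the centred
    (2*half+1)^2 window (5 x 5 by default) is averaged per wavelength to give
    the cell's absolute lifetime; the profile can be restricted to a band
    range in nm.  Returns ``(wavelengths, profile)``.
    """
    arr = np.asarray(lifetime_stack, dtype=float)
    if arr.ndim != 3:
        raise ValueError("lifetime stack must be (H, W, S)")
    x, y = location
    h, w, S = arr.shape
    if not (half <= x < w - half and half <= y < h - half):
        raise ValueError(f"location ({x}, {y}) too close to the border for a {2*half+1}x{2*half+1} window")
    window = arr[y - half : y + half + 1, x - half : x + half + 1, :]
    profile = window.mean(axis=(0, 1))
    wl = np.arange(S, dtype=float) if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if band_range_nm is not None:
        lo, hi = band_range_nm
        sel = (wl >= lo) & (wl <= hi)
        wl, profile = wl[sel], profile[sel]
    return wl, profile
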