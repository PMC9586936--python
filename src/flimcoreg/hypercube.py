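"""FLIM hypercube containers, spectral denoising, lifetime reconstruction and filtering.

A full-spectral FLIM measurement is a 4-D photon-count array indexed
``(x, y, spectral, time)``.  Per spectral band, each pixel's time histogram is
a fluorescence decay; the reconstruction fits a mono-exponential model
``A * exp(-t / tau)`` by nonlinear least squares to obtain the lifetime image,
while the intensity image is the plain photon sum over time channels.

Photon-starved pixels are suppressed by a square-root-of-the-mean threshold:
with ``Nhat`` the mean measured fluorescence concentration, a pixel whose
intensity is <= sqrt(Nhat) has both intensity and lifetime zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "FlimHypercube",
    "SpectralStack",
    "spectral_moving_mean",
    "reconstruct",
    "photon_filter",
    "global_normalise",
    "load_hypercube",
    "save_hypercube",
    "load_stack",
    "save_stack",
]

#: pixels whose summed counts fall below this cannot support a decay fit
DEFAULT_FIT_FLOOR = 25


@dataclass
class FlimHypercube:
    """Raw 4-D photon-count measurement, shape ``(M, M, S, T)``.

    Parameters
    ----------
    counts : ndarray
        Non-negative photon counts indexed ``(x, y, spectral, time)``.
    wavelengths : ndarray
        Per-band emission wavelength in nm, strictly increasing.
    time_bin_ns : float
        Width of one time channel in nanoseconds.
    fov_um : float, optional
        Field of view of the tile in microns.
    """

    counts: np.ndarray
    wavelengths: np.ndarray
    time_bin_ns: float
    fov_um: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.counts.ndim != 4:
            raise ValueError(f"counts must be 4-D (x, y, s, t); got shape {self.counts.shape}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("spatial extents must be equal (M x M)")
        if len(self.wavelengths) != self.counts.shape[2]:
            raise ValueError("wavelength grid does not match spectral extent")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.time_bin_ns <= 0:
            raise ValueError("time_bin_ns must be positive")

    @property
    def spatial_size(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bands(self) -> int:
        return self.counts.shape[2]

    @property
    def n_time(self) -> int:
        return self.counts.shape[3]

    def time_axis(self) -> np.ndarray:
        """Bin-centre time stamps in ns."""
        return (np.arange(self.n_time) + 0.5) * self.time_bin_ns


@dataclass
class SpectralStack:
    """Paired per-band intensity and lifetime images derived from a hypercube.

    ``intensity`` holds photon counts (>= 0) and ``lifetime`` holds the fitted
    mono-exponential lifetime in ns; both have shape ``(M, M, S)``.  ``nhat``
    is the mean measured fluorescence concentration used by the photon filter
    (per band by default, optionally one scalar for the whole stack).
    """

    intensity: np.ndarray
    lifetime: np.ndarray
    wavelengths: np.ndarray
    nhat: np.ndarray | float | None = None
    fov_um: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.lifetime = np.asarray(self.lifetime, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.intensity.shape != self.lifetime.shape:
            raise ValueError("intensity and lifetime must have identical shape")
        if self.intensity.ndim != 3:
            raise ValueError("stack arrays must be 3-D (x, y, s)")
        if len(self.wavelengths) != self.intensity.shape[2]:
            raise ValueError("wavelength grid does not match spectral extent")
        if np.any(self.intensity < 0) or np.any(self.lifetime < 0):
            raise ValueError("intensity and lifetime must be non-negative")

    @property
    def n_bands(self) -> int:
        return self.intensity.shape[2]

    def band_index(self, band: int | float) -> int:
        """Resolve a band given either an integer index or a wavelength in nm."""
        if isinstance(band, (int, np.integer)):
            if not 0 <= band < self.n_bands:
                raise ValueError(f"band index {band} outside [0, {self.n_bands})")
            return int(band)
        return int(np.argmin(np.abs(self.wavelengths - float(band))))


def spectral_moving_mean(cube: FlimHypercube, width: int = 8) -> FlimHypercube:
    """Moving mean over spectral bands with a centred, edge-truncated window.

    Each output band is the mean of the input over a window of ``width`` bands
    centred on it; at the spectral edges the window shrinks rather than pads,
    so no counts are invented.
    """
    S = cube.n_bands
    if not 1 <= width <= S:
        raise ValueError(f"width must be in [1, {S}]; got {width}")
    left = (width - 1) // 2
    right = width // 2
    c = np.cumsum(cube.counts, axis=2, dtype=float)
    c = np.concatenate([np.zeros_like(c[:, :, :1]), c], axis=2)  # prefix sums
    s = np.arange(S)
    lo = np.maximum(0, s - left)
    hi = np.minimum(S - 1, s + right)
    window_sums = c[:, :, hi + 1] - c[:, :, lo]
    out = window_sums / (hi - lo + 1)[:, None]
    return replace(cube, counts=out)


def _fit_decays(y: np.ndarray, t: np.ndarray, tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Vectorised Gauss-Newton fit of ``A * exp(-k t)`` to count histograms.

    Parameters
    ----------
    y : ndarray, shape (P, T)
        Count histograms, one row per pixel/band.
    t : ndarray, shape (T,)
        Bin-centre time stamps in ns.

    Returns
    -------
    tau : ndarray, shape (P,)
        Fitted lifetimes 1/k in ns; 0 where the fit is infeasible.
    """
    P, T = y.shape
    total = y.sum(axis=1)
    tau = np.zeros(P)
    if P == 0:
        return tau

    # initial k from a count-weighted log-linear fit (standard for Poisson decays)
    with np.errstate(divide="ignore"):
        logy = np.where(y > 0, np.log(np.maximum(y, 1e-300)), 0.0)
    w = y.astype(float)
    sw = w.sum(axis=1)
    swt = (w * t).sum(axis=1)
    swt2 = (w * t * t).sum(axis=1)
    swl = (w * logy).sum(axis=1)
    swtl = (w * t * logy).sum(axis=1)
    denom = sw * swt2 - swt**2
    ok = denom > 0
    slope = np.zeros(P)
    slope[ok] = (sw[ok] * swtl[ok] - swt[ok] * swl[ok]) / denom[ok]
    k = np.clip(-slope, 1e-3, 1e3)
    A = np.maximum(y.max(axis=1), 1e-12)

    mu = np.full(P, 1e-3)  # Levenberg damping
    prev_sse = np.full(P, np.inf)
    for _ in range(max_iter):
        e = np.exp(-np.outer(k, t))
        model = A[:, None] * e
        r = model - y
        sse = (r * r).sum(axis=1)
        # partials: d/dA = e ; d/dk = -A t e
        Jk = -A[:, None] * t[None, :] * e
        g_A = (e * r).sum(axis=1)
        g_k = (Jk * r).sum(axis=1)
        h_AA = (e * e).sum(axis=1)
        h_Ak = (e * Jk).sum(axis=1)
        h_kk = (Jk * Jk).sum(axis=1)
        h_AA_d = h_AA * (1 + mu)
        h_kk_d = h_kk * (1 + mu)
        det = h_AA_d * h_kk_d - h_Ak**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dA = -(h_kk_d * g_A - h_Ak * g_k) / det
        dk = -(h_AA_d * g_k - h_Ak * g_A) / det
        improved = sse <= prev_sse
        mu = np.where(improved, mu * 0.3, mu * 10.0)
        mu = np.clip(mu, 1e-12, 1e8)
        prev_sse = np.minimum(prev_sse, sse)
        A = np.maximum(A + dA, 1e-12)
        k = np.clip(k + dk, 1e-6, 1e6)
        step = np.abs(dk) / np.maximum(k, 1e-12)
        if np.all(step < tol):
            break

    tau = np.where((k > 1e-6) & np.isfinite(k) & (total > 0), 1.0 / k, 0.0)
    return tau


def reconstruct(cube: FlimHypercube, fit_floor: int = DEFAULT_FIT_FLOOR) -> SpectralStack:
    """Reconstruct per-band intensity and lifetime images from a hypercube.

    Intensity is the photon sum over time channels.  Lifetime is the ``tau``
    of a per-pixel, per-band nonlinear least-squares fit of
    ``A * exp(-t / tau)`` to the time histogram; pixels whose total counts
    fall below ``fit_floor`` get lifetime 0.
    """
    if cube.n_time < 3:
        raise ValueError("at least 3 time channels are required for a decay fit")
    intensity = cube.counts.sum(axis=3, dtype=float)
    lifetime = np.zeros_like(intensity)
    feasible = intensity >= fit_floor
    if feasible.any():
        y = cube.counts[feasible].astype(float)
        lifetime[feasible] = _fit_decays(y, cube.time_axis())
    return SpectralStack(
        intensity=intensity,
        lifetime=np.maximum(lifetime, 0.0),
        wavelengths=cube.wavelengths,
        fov_um=cube.fov_um,
    )


def photon_filter(
    stack: SpectralStack,
    nhat: np.ndarray | float | None = None,
    scope: str = "band",
) -> SpectralStack:
    """Square-root threshold filter suppressing photon-starved pixels.

    For every pixel and band, if the intensity is <= sqrt(Nhat) then both the
    intensity and the lifetime are zeroed; otherwise both pass unchanged.

    Parameters
    ----------
    nhat : optional
        Freeze the mean concentration instead of recomputing it (makes the
        filter idempotent).  Per-band array or scalar.
    scope : {"band", "stack"}
        Whether Nhat is the mean intensity per spectral band (default) or one
        scalar over the whole stack.
    """
    if nhat is None:
        if scope == "band":
            nhat = stack.intensity.mean(axis=(0, 1))
        elif scope == "stack":
            nhat = float(stack.intensity.mean())
        else:
            raise ValueError(f"unknown nhat scope {scope!r}")
    thr = np.sqrt(np.asarray(nhat, dtype=float))
    keep = stack.intensity > thr  # i <= sqrt(Nhat) is zeroed
    return SpectralStack(
        intensity=np.where(keep, stack.intensity, 0.0),
        lifetime=np.where(keep, stack.lifetime, 0.0),
        wavelengths=stack.wavelengths,
        nhat=nhat,
        fov_um=stack.fov_um,
    )


def global_normalise(
    stacks: list[SpectralStack], per_band: bool = False
) -> list[SpectralStack]:
    """Rescale intensities of all stacks of one microarray by a shared factor.

    The factor is the global intensity maximum across all stacks (per band if
    ``per_band``), mapping intensities into [0, 1].  Lifetimes are untouched;
    their display range is a rendering concern.
    """
    if not stacks:
        raise ValueError("need at least one stack")
    wl0 = stacks[0].wavelengths
    for st in stacks[1:]:
        if not np.array_equal(st.wavelengths, wl0):
            raise ValueError("stacks must share one wavelength grid")
    if per_band:
        peak = np.max([st.intensity.max(axis=(0, 1)) for st in stacks], axis=0)
    else:
        peak = max(float(st.intensity.max()) for st in stacks)
    if np.all(np.asarray(peak) == 0):
        warnings.warn("all-zero stack collection; normalisation skipped", RuntimeWarning)
        return list(stacks)
    scale = np.where(np.asarray(peak) > 0, np.asarray(peak, dtype=float), 1.0)
    return [replace(st, intensity=st.intensity / scale) for st in stacks]


# ---------------------------------------------------------------------------
# HDF5 I/O — one dataset `counts` with attrs, per the fixed on-disk layout

def save_hypercube(path, cube: FlimHypercube) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=cube.counts)
        d.attrs["wavelengths_nm"] = cube.wavelengths
        d.attrs["time_bin_ns"] = cube.time_bin_ns
        if cube.fov_um is not None:
            d.attrs["fov_um"] = cube.fov_um


def load_hypercube(path) -> FlimHypercube:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        return FlimHypercube(
            counts=d[...],
            wavelengths=d.attrs["wavelengths_nm"],
            time_bin_ns=float(d.attrs["time_bin_ns"]),
            fov_um=float(d.attrs["fov_um"]) if "fov_um" in d.attrs else None,
        )


def save_stack(path, stack: SpectralStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=stack.intensity)
        f.create_dataset("lifetime", data=stack.lifetime)
        f.attrs["wavelengths_nm"] = stack.wavelengths
        if stack.nhat is not None:
            f.attrs["nhat"] = stack.nhat
        if stack.fov_um is not None:
            f.attrs["fov_um"] = stack.fov_um


def load_stack(path) -> SpectralStack:
    with h5py.File(path, "r") as f:
        return SpectralStack(
            intensity=f["intensity"][...],
            lifetime=f["lifetime"][...],
            wavelengths=f.attrs["wavelengths_nm"],
            nhat=f.attrs.get("nhat"),
            fov_um=float(f.attrs["fov_um"]) if "fov_um" in f.attrs else None,
        )
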