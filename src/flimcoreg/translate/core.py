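"""Unpaired FLIM-to-false-histology translation with a cycle-consistent objective.

Two generator/discriminator pairs are trained on unaligned image sets: G_FH
maps FLIM-domain renderings to histology-like appearance, G_HF maps back, and
the overall objective is

    L = L_FH(G_FH, D_FH) + L_HF(G_HF, D_HF) + lambda * L_cyc(G_FH, G_HF)

with least-squares adversarial terms and an L1 cycle-consistency term.  The
point of the stage is not faithful virtual staining: it is to give the FLIM
tile enough histology-like structure that the photometric homography
regression downstream can work on colour images.

Downstream code depends only on the translator interface — a callable taking
an RGB image (and optional intensity mask) — so an identity or
contrast-boost translator substitutes for a trained model in any pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from flimcoreg.histoprep import apply_mask, background_mask, to_grey
from flimcoreg.translate import _autograd as ag
from flimcoreg.translate._autograd import Adam, Tensor
from flimcoreg.translate.networks import Discriminator, Generator, IdentityGenerator
from flimcoreg.visual import equalise

__all__ = [
    "TranslationModel",
    "TranslateConfig",
    "cycle_objective",
    "train",
    "translate",
    "save_checkpoint",
    "load_checkpoint",
    "get_translator",
]


@dataclass
class TranslationModel:
    """The two generators and discriminators plus the cycle weight lambda."""

    G_FH: object
    G_HF: object
    D_FH: object
    D_HF: object
    lam: float = 10.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class TranslateConfig:
    """Training configuration.

    Defaults keep the published operating point — batch size 16, 50 epochs,
    256-pixel inputs, cycle weight 10 — while ``width``/``n_res`` scale the
    network capacity down for CPU-sized experiments.  Histology inputs are
    randomly cropped at sizes between ``min_crop`` and the full image, resized
    to ``image_size``, and background-masked by default.
    """

    batch_size: int = 16
    epochs: int = 50
    image_size: int = 256
    width: int = 8
    n_res: int = 1
    lam: float = 10.0
    lr: float = 2e-4
    seed: int = 0
    mask_histology: bool = True
    min_crop: int | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _to_tensor(batch: np.ndarray) -> Tensor:
    """(N, H, W, C) images in [0, 1] -> (N, C, H, W) Tensor in [-1, 1]."""
    arr = np.asarray(batch, dtype=float)
    if arr.ndim != 4:
        raise ValueError("batch must be (N, H, W, C)")
    return Tensor(arr.transpose(0, 3, 1, 2) * 2.0 - 1.0)


def _from_tensor(t: Tensor) -> np.ndarray:
    return np.clip((t.data.transpose(0, 2, 3, 1) + 1.0) / 2.0, 0.0, 1.0)


def _lsgan_real(pred: Tensor) -> Tensor:
    return ag.mean(ag.square(ag.add_scalar(pred, -1.0)))


def _lsgan_fake(pred: Tensor) -> Tensor:
    return ag.mean(ag.square(pred))


def _l1(a: Tensor, b: Tensor) -> Tensor:
    return ag.mean(ag.abs_(ag.sub(a, b)))


def cycle_objective(model: TranslationModel, batch_F: np.ndarray, batch_H: np.ndarray):
    """Evaluate the full objective L = L_FH + L_HF + lambda * L_cyc on two batches.

    Returns ``(total, components)`` where components holds the two adversarial
    terms and the cycle term as floats.  Batches are (N, H, W, C) in [0, 1].
    """
    if len(batch_F) == 0 or len(batch_H) == 0:
        raise ValueError("batches must be non-empty")
    F = _to_tensor(batch_F)
    H = _to_tensor(batch_H)
    fake_H = model.G_FH(F)
    fake_F = model.G_HF(H)
    L_FH = ag.add(_lsgan_real(model.D_FH(H)), _lsgan_fake(model.D_FH(fake_H)))
    L_HF = ag.add(_lsgan_real(model.D_HF(F)), _lsgan_fake(model.D_HF(fake_F)))
    L_cyc = ag.add(_l1(model.G_HF(fake_H), F), _l1(model.G_FH(fake_F), H))
    total = ag.add(ag.add(L_FH, L_HF), ag.scale(L_cyc, model.lam))
    return total.item(), {
        "L_FH": L_FH.item(),
        "L_HF": L_HF.item(),
        "L_cyc": L_cyc.item(),
    }


def _random_histology_view(img: np.ndarray, size: int, rng: np.random.Generator, min_crop: int | None):
    """Random square crop (any position, a range of sizes) resized to ``size``."""
    h, w = img.shape[:2]
    lo = min(min_crop or size, h, w)
    hi = min(h, w)
    cs = int(rng.integers(lo, hi + 1)) if hi > lo else hi
    y = int(rng.integers(0, h - cs + 1))
    x = int(rng.integers(0, w - cs + 1))
    crop = img[y : y + cs, x : x + cs]
    if crop.shape[:2] != (size, size):
        crop = _sk_resize(crop, (size, size), anti_aliasing=True, preserve_range=True)
    return np.clip(crop, 0.0, 1.0)


def train(
    flim_images: list[np.ndarray],
    histo_patches: list[np.ndarray],
    config: TranslateConfig | None = None,
):
    """Train the translation model on unpaired FLIM renderings and histology patches.

    FLIM images (any wavelength, shuffled together) are resized to
    ``image_size``; histology patches are randomly cropped/resized each epoch
    and background-masked unless disabled.  Returns ``(model, history)`` where
    history records per-epoch mean generator and discriminator losses.
    Deterministic under a fixed config seed.
    """
    config = config or TranslateConfig()
    if not flim_images or not histo_patches:
        raise ValueError("need at least one image per domain")
    chans = {np.asarray(im).shape[-1] if np.asarray(im).ndim == 3 else 1 for im in flim_images + histo_patches}
    if chans != {3}:
        raise ValueError("all domain images must be 3-channel RGB")
    rng = np.random.default_rng(config.seed)
    size = config.image_size

    def prep_flim(im):
        im = np.asarray(im, dtype=float)
        if im.shape[:2] != (size, size):
            im = _sk_resize(im, (size, size), anti_aliasing=True, preserve_range=True)
        return np.clip(im, 0.0, 1.0)

    flim = np.stack([prep_flim(im) for im in flim_images])

    def prep_histo(im):
        view = _random_histology_view(np.asarray(im, dtype=float), size, rng, config.min_crop)
        if config.mask_histology:
            view = apply_mask(view, background_mask(view))
        return view

    G_FH = Generator(rng, width=config.width, n_res=config.n_res)
    G_HF = Generator(rng, width=config.width, n_res=config.n_res)
    D_FH = Discriminator(rng, width=config.width)
    D_HF = Discriminator(rng, width=config.width)
    model = TranslationModel(G_FH, G_HF, D_FH, D_HF, lam=config.lam)

    opt_G = Adam(G_FH.parameters() + G_HF.parameters(), lr=config.lr)
    opt_D = Adam(D_FH.parameters() + D_HF.parameters(), lr=config.lr)

    history = {"gen_loss": [], "disc_loss": []}
    n = len(flim)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_F = flim[idx]
            batch_H = np.stack([prep_histo(histo_patches[int(rng.integers(len(histo_patches)))]) for _ in idx])
            F = _to_tensor(batch_F)
            H = _to_tensor(batch_H)

            # generator step: fool both discriminators + cycle consistency
            fake_H = G_FH(F)
            fake_F = G_HF(H)
            adv = ag.add(_lsgan_real(D_FH(fake_H)), _lsgan_real(D_HF(fake_F)))
            cyc = ag.add(_l1(G_HF(fake_H), F), _l1(G_FH(fake_F), H))
            loss_G = ag.add(adv, ag.scale(cyc, config.lam))
            loss_G.backward()
            opt_G.step()

            # discriminator step on detached fakes
            loss_D = ag.scale(
                ag.add(
                    ag.add(_lsgan_real(D_FH(H.detach())), _lsgan_fake(D_FH(fake_H.detach()))),
                    ag.add(_lsgan_real(D_HF(F.detach())), _lsgan_fake(D_HF(fake_F.detach()))),
                ),
                0.5,
            )
            loss_D.backward()
            opt_D.step()

            g_losses.append(loss_G.item())
            d_losses.append(loss_D.item())
        history["gen_loss"].append(float(np.mean(g_losses)))
        history["disc_loss"].append(float(np.mean(d_losses)))
    return model, history


def translate(model: TranslationModel, flim_rgb: np.ndarray, intensity_mask: np.ndarray | None = None) -> np.ndarray:
    """Translate one FLIM rendering to a false-histology image.

    The generator is fully convolutional so any input size is accepted; the
    output keeps the input shape.  When an intensity mask is given, the
    generated image is multiplied by it — the standard fix for blurred
    backgrounds in renderings without a dark background.
    """
    img = np.asarray(flim_rgb, dtype=float)
    out = _from_tensor(model.G_FH(_to_tensor(img[None])))[0]
    if intensity_mask is not None:
        m = np.asarray(intensity_mask, dtype=float)
        if m.shape != out.shape[:2]:
            raise ValueError("mask shape must match image spatial shape")
        out = out * m[:, :, None]
    return out


# ---------------------------------------------------------------------------
# checkpoints and the translator registry

def save_checkpoint(path, model: TranslationModel, config: TranslateConfig) -> None:
    arrays = {"lam": np.array(model.lam), "width": np.array(config.width), "n_res": np.array(config.n_res)}
    for name, net in [("gfh", model.G_FH), ("ghf", model.G_HF), ("dfh", model.D_FH), ("dhf", model.D_HF)]:
        for i, p in enumerate(net.parameters()):
            arrays[f"{name}_{i}"] = p.data
    np.savez(path, **arrays)


def load_checkpoint(path) -> TranslationModel:
    z = np.load(path)
    rng = np.random.default_rng(0)
    width, n_res = int(z["width"]), int(z["n_res"])
    nets = {
        "gfh": Generator(rng, width=width, n_res=n_res),
        "ghf": Generator(rng, width=width, n_res=n_res),
        "dfh": Discriminator(rng, width=width),
        "dhf": Discriminator(rng, width=width),
    }
    for name, net in nets.items():
        for i, p in enumerate(net.parameters()):
            p.data = z[f"{name}_{i}"]
    return TranslationModel(nets["gfh"], nets["ghf"], nets["dfh"], nets["dhf"], lam=float(z["lam"]))


def _identity_translator(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    out = np.asarray(img, dtype=float).copy()
    if mask is not None:
        out = out * np.asarray(mask, dtype=float)[:, :, None]
    return out


def _equalise_translator(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    grey = to_grey(np.asarray(img, dtype=float))
    boosted = equalise(np.clip(grey, 0.0, 1.0))
    out = np.repeat(boosted[:, :, None], 3, axis=2)
    if mask is not None:
        out = out * np.asarray(mask, dtype=float)[:, :, None]
    return out


def get_translator(spec: str):
    """Resolve a translator by name: ``identity``, ``equalise`` or ``cyclegan:<ckpt>``.

    Every translator is a callable ``(rgb_image, intensity_mask=None) -> rgb``;
    the registration stage depends only on this interface.
    """
    if spec == "identity":
        return _identity_translator
    if spec == "equalise":
        return _equalise_translator
    if spec.startswith("cyclegan:"):
        model = load_checkpoint(spec.split(":", 1)[1])
        return lambda img, mask=None: translate(model, img, mask)
    raise ValueError(f"unknown translator {spec!r}")
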