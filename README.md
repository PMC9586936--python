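# flimcoreg

Co-registration of full-spectral autofluorescence lifetime microscopy
(FS-FLIM) images with H&E-stained histology.

## The problem

An FS-FLIM measurement of an unstained tissue section is a 4-D photon-count
hypercube — 256 × 256 pixels × 512 emission bands (500–780 nm) × 32 time
channels.  Per pixel and band, the time histogram is a fluorescence decay
whose characteristic time τ (the lifetime) is independent of intensity, so
lifetime images are flat and texture-poor, while the clinical gold standard —
the H&E-stained histology image of the same tissue — is richly structured.
Aligning the two modalities is what makes pixel-level interpretation of
lifetime contrast (e.g. lung adenocarcinoma at ~1.5 ns vs healthy alveoli at
~3 ns at 527 nm) possible, and it is exactly what conventional
intensity- or feature-based registration fails at: the two images share
almost no photometric statistics.

`flimcoreg` implements the full pipeline:

1. **Reconstruction** (`flimcoreg.hypercube`) — spectral moving mean (8
   bands), per-pixel/per-band mono-exponential least-squares lifetime fit
   `A·exp(−t/τ)`, intensity as the photon sum, a `√N̂` photon filter zeroing
   pixels with intensity ≤ √(mean concentration), and global intensity
   normalisation across a microarray.
2. **Rendering** (`flimcoreg.visual`) — false-colour lifetime (Jet palette,
   fixed [1 ns, 3 ns] window), intensity weighting, histogram equalisation.
3. **Histology preparation** (`flimcoreg.histoprep`) — background masking
   (grey → invert → equalise → Otsu → multiply) and patch cropping with
   recorded positions.
4. **Translation** (`flimcoreg.translate`) — unpaired FLIM → false-histology
   translation with a cycle-consistent adversarial objective
   `L = L_FH + L_HF + λ·L_cyc`, giving FLIM tiles a histology-like
   appearance so photometric registration becomes feasible.
5. **Registration** (`flimcoreg.register`) — the core: the 3 × 3 homography
   `H` is estimated by plain gradient descent on a *partial photometric*
   (PPM) L1 loss — the mean absolute difference between the warped moving
   image and the fixed patch, restricted to a centred window (default 200 px
   on 256-px images) that excludes the border frame the patch's larger field
   of view contaminates.  The bilinear warp provides the exact analytic
   gradient of the loss with respect to every entry of `H`.
6. **Stitching & profiling** (`flimcoreg.stitch`) — patch positions averaged
   onto a regular grid, overlap-averaged mosaics, and 5 × 5-pixel spectral
   lifetime profiles of annotated cells.
7. **Synthetic phantoms** (`flimcoreg.synthetic`) — Poisson decay hypercubes
   with region-wise lifetimes, H&E-like textures, warped pairs with known
   homographies and jittered tile grids, so the whole pipeline is testable
   with known ground truth and no external data.

## Worked example

```python
import numpy as np
from flimcoreg import synthetic as syn
from flimcoreg.hypercube import reconstruct, photon_filter
from flimcoreg.register import regress, RegressionConfig
from flimcoreg.evaluate import corner_error

# two-region phantom: tumour 1.5 ns (left), alveoli 3.0 ns (right)
cube, tau_map, histology = syn.make_phantom(syn.PhantomSpec(size=64, n_bands=16, seed=11))
stack = photon_filter(reconstruct(cube))
for tau in (1.5, 3.0):
    print(f"true {tau} ns -> fitted {stack.lifetime[tau_map == tau].mean():.3f} ns")

# registration: recover a known homography with the fixed schedule
img = syn.make_texture(256, seed=3, n_blobs=400, blob_radius=(4, 14), blur_sigma=2.0)
H_true = syn.random_homography(256, rng=0)
moving, fixed, _ = syn.make_warped_pair(img, H_true, noise_sd=0.01, rng=0)
res = regress(moving, fixed, RegressionConfig())   # 200 epochs, lr 0.01, window 200
print(f"corner reprojection error: {corner_error(res.H_final, H_true, 256):.3f} px")
```

prints

```
true 1.5 ns -> fitted 1.500 ns
true 3.0 ns -> fitted 3.000 ns
corner reprojection error: 0.007 px
```

— the filtered lifetime fit recovers both region lifetimes to a
thousandth of a nanosecond, and the gradient-descent
homography regression lands within a hundredth of a pixel of the ground
truth warp.

A CLI mirrors the library (`flimcoreg reconstruct / render / mask-histology /
crop / train-translate / translate / register / evaluate / stitch /
simulate`); see `flimcoreg --help`.

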