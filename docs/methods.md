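# Methods

## Lifetime reconstruction

Each pixel/band time histogram is modelled as a background-free
mono-exponential decay `y_t = A · exp(−t/τ)` evaluated at bin centres and
fitted by nonlinear least squares on the raw counts.  The fitter is a
vectorised Gauss–Newton iteration with Levenberg damping over all pixels
simultaneously, initialised from a count-weighted log-linear fit (the
standard initialiser for Poisson decays), and iterated to a relative step
tolerance of 1e−12 (max 100 iterations).  Noiseless decays are therefore
recovered to solver precision, and Poisson decays with 1e4 counts over 32
bins of 0.4 ns carry ~2 % RMS error in τ — comfortably inside the Cramér–Rao
scaling `σ_τ/τ ∝ 1/√N`.  A mono-exponential without additive background was
chosen because the upstream measurement is time-gated photon counting with
negligible dark counts; multi-exponential and phasor analyses are out of
scope.  Pixels with fewer than 25 total counts (`fit_floor`) cannot support
a two-parameter fit and get lifetime 0.

Intensity is the exact photon sum over time channels.  The spectral moving
mean (default 8 bands ≈ 4.5 nm) uses a centred window truncated at the
spectral edges — a shrinking window rather than padding, so no counts are
invented.

**Photon filter.**  With `N̂` the mean measured fluorescence concentration,
any pixel whose intensity is ≤ √N̂ has intensity *and* lifetime zeroed; the
inequality is deliberately non-strict so the boundary case is removed.  The
scope of `N̂` is per spectral band by default (each band has its own photon
budget; a single whole-stack mean would over-filter dim red bands), with a
per-stack option.  `N̂` is computed on the filter's input — i.e. after the
moving mean when the standard pipeline order is used — and can be frozen and
passed explicitly, which makes the filter idempotent.

**Global normalisation** divides all intensities of one microarray by the
single global maximum (per-band optional), mapping them to [0, 1] so that
brightness is comparable across tiles and wavelengths.  Lifetimes are never
rescaled; their display window (default [1 ns, 3 ns]) is purely a rendering
parameter.

## Rendering

Lifetime maps linearly through a named palette (Jet by default) within the
display window, values clamped at the ends; zero-intensity pixels render
black, giving the dark background that downstream stages rely on.
Intensity weighting multiplies the palette colour by the normalised
intensity (HSV value channel).  The published figures are ambiguous between
value- and saturation-scaling; both are implemented (`weight_channel`),
value being the default because it reproduces the dark-background look.
Histogram equalisation uses the classic 256-bin cumulative-histogram lookup
for integer images; float images are remapped through their exact empirical
CDF (no quantisation), which linearises the output CDF to machine precision
while preserving ranks.

## Histology background masking

grey (luma 0.299/0.587/0.114) → invert → global equalisation → Otsu →
pixel-wise multiplication.  Otsu's threshold is computed exactly by
exhaustive maximisation of the between-class variance over the 256 levels
(vectorised cumulative sums), with ties broken towards the lower level;
tests compare it against an independent brute-force loop.  Equalisation is
global (not tile-adaptive) and morphological cleanup is off by default, as
the pipeline defines no such steps.  Coordinates are 0-based, top-left
origin, half-open rectangles.

## Unpaired translation

The translation stage trains two generator/discriminator pairs on unaligned
image sets with the objective `L = L_FH + L_HF + λ·L_cyc`: least-squares
adversarial terms for both mappings plus an L1 cycle-consistency term,
λ = 10 by default.  Generators are fully convolutional residual networks
with tanh outputs; discriminators are strided patch classifiers; Adam with
betas (0.5, 0.999).  The production operating point keeps batch size 16 and
50 epochs on 256-px inputs; a width/depth scale shrinks the networks for
CPU-sized runs.  Histology inputs are randomly cropped at random sizes and
positions, resized to the network input size, and background-masked by
default.  All randomness flows through one seeded generator, so training is
bit-reproducible.

The whole stack is written against a *translator interface* — any callable
`(rgb, intensity_mask=None) → rgb`.  The registry provides `identity`,
`equalise` (greyscale contrast boost) and `cyclegan:<checkpoint>`, so every
downstream stage is testable without a trained model.

Smoke tests of training use deliberately tiny runs (16-px images, 8 images
per domain, batch 2, 2 epochs).  At that scale only 8 optimiser steps
happen, so the smoke configuration raises the learning rate to 5e−3: a
learning-rate choice matched to the number of steps, without which no
configuration could display a measurable loss trend.  Passing this smoke
test shows the objective, gradients and update loop are wired correctly; it
says nothing about translation fidelity on real tissue, which is explicitly
not the goal here.

## Homography regression

The moving (false-histology) image is aligned to the fixed histology patch
by minimising the windowed photometric L1 loss

    L(H) = mean over masked pixels and channels of | warp(I_moving, H) − I_fixed |

with plain gradient descent on all 9 entries of `H`, initialised at the
identity.  Design choices:

- **PPM mask.**  The loss is restricted to the centred `w × w` window
  (default 200 on 256-px images) in the *fixed* frame, where the excluded
  border lives; the surrounding hollow-rectangle frame is the region the
  patch's larger field of view contaminates.
- **Averaging.**  The loss is the *mean* (not sum) over masked pixels and
  channels, so learning rates transfer across window sizes and image
  formats; for colour inputs channels are averaged after the absolute value.
- **Warp.**  Inverse-mapped bilinear resampling with zero fill outside the
  source.  The implementation carries the exact analytic gradient: the
  gradient with respect to the sampling matrix `G = H⁻¹` is the standard
  spatial-transformer expression (bilinear interpolant derivative × the
  projective coordinate Jacobian), and the chain rule through matrix
  inversion gives `∂L/∂H = −Gᵀ (∂L/∂G) Gᵀ`.  Central finite differences
  confirm it to ~1e−7 relative error at step 1e−8; at larger steps the
  finite difference itself degrades by crossing bilinear-cell and L1-sign
  kinks, which is a property of the check, not the gradient.
- **Conditioning.**  Internally pixel coordinates are normalised to [−1, 1]
  (`H_norm = T H T⁻¹`), so all 9 entries have comparable gradient scales and
  one learning rate serves translations, rotations and perspective terms;
  the public matrix is always pixel-coordinate with `h₃₃ = 1`.
- **Schedule.**  Defaults are the fixed comparison schedule: 200 epochs,
  learning rate 0.01, ×0.1 at epoch 100.  The optimiser is plain gradient
  descent (no momentum); the L1 subgradient at 0 is 0 (no Huber smoothing).
- **Reporting.**  The returned homography is the epoch with minimum loss,
  not the last epoch, and the loss trace is returned in full.  The
  regression is fully deterministic.

On 256-px textured phantoms this recovers random mild homographies
(|t| ≤ 10 px, rotation ≤ 5°, scale 0.95–1.05, perspective ≤ 1e−4) with
~0.01 px mean corner reprojection error, ~5 s per case on one CPU core.

**Window/patch-size trade-off.**  The synthetic `make_fov_pair` experiment
reproduces the qualitative behaviour the window choice must balance: with a
*larger*-FOV patch, the border band the moving image cannot explain
(zero-fill vs real tissue) biases large windows — a 246-px window fails by
tens of pixels where a 196-px window inside the shared field converges; with
a *smaller*-FOV patch whose informative structure sits in an outer annulus,
a 196-px window sees only a uniform interior, has zero loss gradient, and
stalls at the identity, while a 246-px window sees the annulus and
converges.  The annulus interior is clamped exactly uniform because the L1
sign function gives full weight to arbitrarily small residuals — any blur
tail leaking into the window would re-supply gradient signal.

## Similarity metrics

MSE, Pearson normalised cross-correlation, and normalised mutual information
`2·I(A;B)/(H(A)+H(B))` on a 64-bin equal-width joint histogram (bin count
configurable), all computed on luma-converted greyscale.  These metrics are
reported for completeness but are documented as unreliable rankings for
multimodal pairs — a well-registered FLIM/histology pair can score worse
than a misregistered one — so recovery suites use the mean corner
reprojection error of the four image corners under estimated vs true
homography as the authoritative signal.

## Stitching

Patch positions are averaged onto a regular grid: mean horizontal and
vertical spacings from adjacent-tile displacements, anchored at the mean
origin ("simply averaging" the recorded positions).  A pass-through mode
keeps raw per-tile positions, used when individual placements are trusted —
e.g. the exact-reassembly round trip, where grid-snapping would necessarily
reintroduce the per-tile jitter it averages away.  Overlaps are combined by
unweighted mean with exactly-zero (photon-filtered) pixels excluded, so dark
backgrounds do not dim tissue; an optional whole-slide background is
composited beneath.  Cell profiles average the lifetime over a centred
5 × 5-pixel window per wavelength, matching the scale mismatch between
single cells and image pixels.

## Synthetic phantoms — what they do and do not show

The default desk-scale cube is 64 × 64 × 16 × 32 (spatial², spectral bands
over 500–780 nm, time channels of 0.4 ns) with ~1e4 expected counts per
pixel and the two-region lifetime contrast 1.5 ns vs 3.0 ns — the printed
adenocarcinoma/alveoli values; full 256 × 512 × 32 geometry is supported but
not default, keeping full-pipeline tests in seconds.  A logistic per-band
roll-off emulates the dim red end of the emission spectrum for stress tests.
Pseudo-histology textures share the exact region geometry of the lifetime
map but differ completely in appearance (purple nuclei blobs on pink stroma,
bright field), which is the statistical situation the registration faces.
Registration suites use 256-px phantoms with ~400 blobs of 4–14 px radius
blurred by σ = 2 px — smooth enough for a wide photometric basin, structured
enough to pin all 8 degrees of freedom.

Everything is a pure function of (spec, seed).  Passing on these phantoms
demonstrates correctness of the algorithms under the stated models
(mono-exponential decays, Poisson noise, exact homographies, shared
geometry); it does not demonstrate translation fidelity on patient tissue,
robustness to stain variation, sectioning distortion, or non-rigid tissue
deformation — the latter is explicitly out of scope for the homography
model.

## Numerical details and edge cases

- All-zero hypercubes reconstruct to all-zero stacks without error;
  non-finite counts are rejected at construction.
- `photon_filter` never leaves a pixel with positive lifetime and zero
  intensity; with frozen `N̂` it is idempotent.
- Degenerate inputs raise: constant images for Otsu/NCC/NMI, empty PPM
  masks, singular homographies, out-of-bounds crops, border cell locations.
- An all-zero stack collection is returned unchanged from normalisation with
  a `RuntimeWarning` rather than an exception.
- `regress` aborts with a diagnostic on non-finite loss rather than
  silently diverging.
- Problem sizes in the test and acceptance suites (20 recovery cases,
  100-pixel fit cohorts, 5-seed training smoke, 64-px cubes) were chosen so
  the statistical tolerances are meaningful while the whole suite runs in a
  few minutes on a single CPU core.
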