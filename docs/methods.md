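# Methods

This note records the models implemented in `seedhsi`, the choices made
where the underlying procedure is underdetermined, and what the synthetic
data can and cannot establish.

## Data model

A hypercube is a `(rows, cols, bands)` float32 array with a uniform
wavelength grid `λ(i) = start + i·step`. The emulated instrument samples
597.21–1703.93 nm every 4.14 nm, giving 268 bands; `WavelengthGrid.from_range`
derives the band count as `round((stop − start)/step) + 1`. Nearest-band
lookup rounds exact midpoints toward the lower index so that lookups are
deterministic. On disk, cubes are ENVI (text header + flat binary, BIL/BIP/BSQ
all normalised to `(rows, cols, bands)` on read) or HDF5 (`/data`,
`/wavelengths_nm`, metadata as attributes). ENVI was chosen as the default
dialect because it is the de facto convention for line-scan spectrographs;
the on-disk format of the original acquisitions is not documented anywhere
we could rely on.

## Calibration

Reflectance is the two-point (Shafer) normalisation
`I_c = (I − I_d)/(I_w − I_d)` against a white (nominally 100 %) and a dark
(0 %) reference. Consequences that the tests assert: the map is affine in
`I` (a pixel at `αI_w + (1−α)I_d` calibrates to exactly `α`) and invariant
to any gain/offset applied identically to all three cubes. References may
be full frames or reduced profiles (per-band spectrum, or column × band, the
line-scan geometry); anything broadcastable with a matching band axis is
accepted. Choices:

* **Clipping** to `[0, 1.2]` is on by default: specular glints exceed the
  Teflon tile slightly, and unbounded values destabilise training. The
  ceiling 1.2 keeps glints visible while bounding them.
* **Degenerate references** (`I_w = I_d`, e.g. dead pixels) raise by
  default, naming the offending bands. An optional epsilon guard
  (denominators below 1e−6 of the white dynamic range) masks such pixels to
  0 with a logged count instead — dead pixels are routine on real sensors.
* Repeated reference frames can be averaged (`average_reference`); whether
  the original acquisitions did so is unknown, so it is an optional step.
* Calibrating an already-calibrated cube is refused outright.

## Segmentation

No published algorithm accompanies the workflow this package reproduces,
so segmentation is deliberately standard and parameter-light: score image
= mean reflectance over a configurable band window (default all bands);
Otsu threshold; binary closing with a radius-2 disk; 8-connected
components; components below `min_area` (default 50 px) dropped; regions
touching the panel border discarded by default because clipped seeds bias
shape features. Regions are ordered by `(row_min, col_min)` and relabelled
1..n, making outputs deterministic. Per-seed sub-cubes are masked crops
centred and zero-padded into a canonical spatial size (default 64 × 32);
oversize seeds are band-wise bilinearly resized; the spectral axis is never
resampled. Touching-seed splitting (watershed) is out of scope.

## Shape descriptors

Seeds are treated as ellipses. The boundary is the set of mask pixels with
an 8-neighbour outside; the diameter is the maximum pairwise distance
between boundary pixel centers (ties resolved to the lexicographically
smallest index pair, verified against an O(n²) scan). The major half-axis
`a` is half that diameter; the minor half-axis `b` is half the mask's
extent projected on the perpendicular of the diameter direction — "the
perpendicular line" is not otherwise operationalised, and this projection
rule is the simplest measurable version. From `a ≥ b > 0`:

    eccentricity = √(1 − (b/a)²)
    area         = π a b
    perimeter    = π (a + b)
    compactness  = p² / A
    roundness    = 4 π A / p²

The perimeter is the coarse first-order approximation, kept deliberately
(fidelity to the descriptor set being reproduced) even though it
underestimates elongated ellipses; Ramanujan's approximation is available
via `perimeter_method="ramanujan"` for comparison. Note the algebraic
consequence `roundness × compactness = 4π`, which the tests assert across a
parameter grid — the two descriptors carry one degree of freedom between
them under this ellipse model. Mean intensity averages each pixel's
spectrum over bands first, then over masked pixels; the band-first
reduction is a documented choice (the scalar-pixel formulation needs one).
A collinear region (`b = 0`) is flagged degenerate rather than silently
producing infinities.

## Seed-level 3-D CNN

Topology: `[conv3d (valid) → ReLU → max-pool] × 2 → flatten → FC → softmax`.
The convolution is `O[c′,i,j,k] = Σ_{c,d,h,w} I[c,i+d,j+h,k+w]·K[c′,c,d,h,w] + b[c′]`
— the standard per-output-channel sum over input channels. The band axis is
mapped to convolution depth, since the spectral axis is the informative
one; seed chips provide H × W. Defaults (the depth of the network is fixed
by the reproduced design; the kernel sizes are not stated anywhere, so
these are this package's choices, sized for CPU training): block 1 has 8
channels, kernel (7,3,3), pool (2,2,2); block 2 has 16 channels, kernel
(5,3,3), pool (2,2,2); FC width 64. Pooling uses stride = window; ragged
dimensions are edge-replicated (implemented as −inf padding, which yields
identical maxima). Training: Adam (lr 1e−3), categorical cross-entropy,
batch 8, 50 epochs by default. One master seed drives the split,
augmentation order, batch shuffling, and He-style weight init, making runs
bit-reproducible at a fixed thread count.

Protocol: stratified 80/10/10 train/val/test split with largest-remainder
rounding (40 items → 32/4/4); augmentation grows the training split to a
fixed per-class total (default 40) with horizontal/vertical flips, 180°
rotation, and ±2 px shifts — spatial transforms only, spectra untouched,
originals preserved.

All layers, including backward passes, are NumPy (`sliding_window_view` +
`tensordot`); the forward kernels are verified against nested-loop oracles
and the gradients against central finite differences.

## Pixel-level DNN

Each masked seed pixel contributes its full spectrum as one row. The
network is 12 ReLU hidden layers (the depth is part of the reproduced
design) with softmax output; the widths are not stated anywhere, so the
default taper 256, 256, 128, 128, 128, 64, 64, 64, 32, 32, 32, 16 was
chosen to keep CPU cost low while leaving capacity at the input end.
Per-band standardisation (training-split mean/σ) is applied before the
network and stored with the model — unglamorous but necessary for stable
optimisation of a deep ReLU stack. Adam, lr 1e−3, batch 256, 30 epochs by
default; plain (unweighted) cross-entropy.

The 70/30 pixel split is per-seed — every seed contributes pixels to both
sides — because the phrase it implements ("70 % of the pixels of each
seed") reads most naturally that way; a global split is available via
`per_seed=False`. A seed with fewer than 2 pixels goes wholly to train,
logged.

## Evaluation

OA = trace/total. Per-class precision/recall/F1 are one-vs-rest, with
macro and support-weighted averages. AA is the mean per-class one-vs-rest
accuracy `(TP+TN)/(TP+TN+FP+FN)`. Kappa = `(Po − Pe)/(1 − Pe)` with
`Po = OA` and `Pe = Σ_i row_i·col_i / total²`. These are the standard
multi-class generalisations of the binary formulas and reduce to them
exactly at k = 2 (asserted); they are also cross-checked against
scikit-learn. Zero-denominator metrics report 0 with an `undefined` flag
rather than NaN, keeping tabular output stable. The embedding is PCA to 50
components (reduced with a warning when n is small) followed by 2-D t-SNE
(perplexity 30, fixed seed); "50 components" is the deliberate reading of
an ambiguous phrasing that could also mean 50 original bands — a flag-level
alternative was considered and rejected as less informative.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* Class mean spectra = shared baseline (0.30) + class-specific slope and
  three Gaussian bumps (centers uniform over the sampled range, widths
  40–90 nm, amplitudes 0.05–0.12 × `separation`). All class-specific terms
  scale with `separation`, so pairwise mean distances are exactly
  proportional to it and `separation = 0` collapses the classes.
* Exposure duration (168–240 h) modulates bump amplitude by ±3 % — a
  within-class effect an order smaller than the between-class one.
* Noise is i.i.d. Gaussian per pixel-band, σ = 0.02 reflectance by default.
* The raw cube is `dark + reflectance·(white − dark)` with a smooth
  Gaussian lamp spectrum peaking at 1100 nm at 0.9 of sensor range and a
  dark level of 0.05, so calibration is a non-trivial exact inversion at
  zero noise.
* Panels place elliptical seeds (half-axes ~9–12 × 5–7 px) on a jittered
  grid with ≥ 2 px clearance; chips centre one ellipse per frame.

Test fixtures run at reduced scale — 16 × 16 px chips with 32 bands,
40 seeds per class, 128–160 px panels — sizes chosen so the full suite and
the acceptance script complete quickly on a single CPU while preserving
every structural property of full-scale acquisitions (268-band, 1250 × 450 panels
are available by passing the default grid).

What the generator does **not** emulate, and hence what passing tests do
not show: biophysical absorption features (water/starch bands), spatially
correlated noise and illumination gradients, touching or overlapping
seeds, within-seed spectral texture, and class differences in seed shape.
High synthetic accuracies demonstrate that the pipeline is implemented
correctly and can recover structure it was designed for — not that any
particular accuracy will be reached on real seed acquisitions.

## Numerical and degenerate-input policy

* float32 storage, float64 arithmetic inside calibration and the networks.
* Constant panels segment to zero regions (not an error); empty masks,
  empty point sets, single-class training sets, and non-finite losses
  raise typed errors.
* Tie-breaks are fixed everywhere (lowest class index at equal softmax,
  lexicographic region ordering, lowest index pair for the diameter,
  midpoint wavelengths round down) so repeated runs are identical.

## Known limitations

* The NumPy networks are CPU-scale: suitable for hundreds of seed cubes
  and tens of thousands of pixel spectra, not for GPU-scale corpora.
* The crude perimeter approximation propagates into compactness and
  roundness for elongated seeds (by design; see above).
* Segmentation assumes non-touching seeds on a dark background.
* t-SNE coordinates are comparable only within one run/seed.
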