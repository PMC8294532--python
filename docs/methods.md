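# Methods

## Pipeline model

`srscount` treats cell counting as a two-stage problem: per-pixel
semantic segmentation (cell / non-cell), followed by morphological
instance identification.  This matches how SRS images present cells —
protein-rich (blue-channel) bodies on a lipid (green-channel) background
with too little contrast for classical thresholding tools, but enough
for a small convolutional network trained on limited annotation.

### Reduced U-Net

The segmentation network is a symmetric encoder/decoder with skip
connections and **half the kernel budget of the original U-Net**:
16/32/64/128/256 kernels over five levels by default.  Each level is two
same-padding 3×3 convolutions with ReLU; 2×2 max pooling connects
encoder levels; the decoder uses 2×2 stride-2 transposed convolutions
(ReLU), concatenation with the same-resolution encoder feature map, and
two more 3×3 convolutions; a single-kernel 1×1 convolution with a
sigmoid yields the per-pixel cell probability.  Inputs are the two
informative SRS channels (green, blue); the decision rule is strictly
`p > 0.5`.

Same-padding convolutions (the original U-Net uses valid convolutions
and crops) keep the output the size of the input, which is what makes
the split-and-combine tiling exact: images are partitioned into
non-overlapping 256×256 patches, zero-padded at the bottom/right edges,
segmented independently, and reassembled losslessly.  Zero padding is
background-like in both SRS channels.  No batch normalisation, no data
augmentation, no tile blending.

Training minimises mean pixel-wise binary cross-entropy with Adam
(α = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, batch 16).  A random 20% of
the patches (drawn once per run from the run seed) form a validation
split; training stops when the validation loss has not strictly improved
for 25 epochs (cap 300), and the best-epoch weights are restored.
Weights are He-initialised; every random draw (init, split, shuffling)
flows from explicit seeds, so runs are bit-reproducible on a machine.

The backend is pure NumPy (`srscount.nn`): convolutions are lowered to
BLAS matmuls via im2col, the data gradient of a same-padding convolution
is computed as a convolution with the spatially flipped in/out-swapped
kernel, and the backward pass is verified against central finite
differences in the test suite.

### H&E reference segmentation

H&E frames are segmented without annotation: each 500×500 patch is
clustered in RGB space by Lloyd's algorithm (K = 6, k-means++ seeding,
Euclidean objective).  Exactly one cluster per patch — the one whose
centroid is nearest a configurable dark hematoxylin blue, default
RGB (0.15, 0.15, 0.45) — is labelled cell; ties break to the lowest
cluster index.  Clustering is per patch, so centroids (and hence the
mask) may be inconsistent across patch boundaries; this is accepted.
The Lloyd loop records the objective after every assignment step (it is
non-increasing by construction, and asserted so in tests).  Degenerate
patches with fewer distinct colours than K — uniform padding or
noise-free background — are clustered with K clamped to the number of
distinct colours.  Colour space: raw RGB; no stain deconvolution.

### Instance identification and counting

Given a binary mask: one iteration of 3×3 morphological opening removes
speck noise; 8-connected components become initial instances; each
component's exact Euclidean distance transform is rescaled by its
maximum, the connected components of {rescaled > 0.5} become markers,
and marker-based watershed on the negated (unscaled) distance map
assigns every region pixel to exactly one marker.  A region with a
single marker is returned intact, so the output always partitions the
input region.

Two micron-calibrated filters then run (pixel areas × resolution²):

* **too_small** — equivalent circular diameter 2·√(area/π) < 0.37 µm.
  The bound is a length, so diameter is the reading used; at
  0.37 µm/pixel it removes only sub-pixel debris, at 0.18 µm/pixel also
  few-pixel specks.
* **vessel_like** — ellipse-fit major axis > 100 µm *or* area > 500 µm²
  (blood vessels and microhemorrhages mimic cell colour but are far
  larger than any cell).

Finally, the upper-inner-fence rule recovers merged cells the watershed
could not split: with ≥ 4 instances, the fence is Q3 + 1.5·IQR of the
instance areas (linear-interpolation quartiles); an instance above the
fence counts as `max(2, round(area / mean area of ordinary instances))`
cells.  With < 4 instances the quartiles are unstable and the rule is
disabled.  The per-label multiplicities are retained so that per-FOV and
heat-map counts conserve the total.

A note on reach: for two equal discs of radius r, the neck of the fused
region has distance-transform value √(r² − (d/2)²) at centre distance d,
so the 0.5-of-maximum marker threshold only separates pairs with
d ≳ 1.8 r (slightly worse in pixelated geometry, where the cusp between
the discs fills in).  More deeply merged pairs are single instances and
are recovered — as a count, not a boundary — by the fence rule.

### Evaluation

Pixel metrics: accuracy, sensitivity, specificity, DICE
2TP/(2TP+FP+FN); AUC by the rank (Mann–Whitney) formulation with ties
counted ½, which equals the trapezoidal ROC area (asserted to 1e-10
against an independent implementation).  Ratios with empty denominators
are reported as missing, never as 0.  Count agreement across modalities
is **count-level only**: cells shift and vanish between SRS and H&E
frames of one specimen, so instance matching is not attempted.  Images
are partitioned into non-overlapping FOVs (8×8 patches of 256 px, i.e.
2048 px, by default; trailing partial FOVs dropped); an instance belongs
to the FOV containing its centroid.  Agreement reports Pearson r of the
per-FOV counts, the percentage error of the totals, and Bland–Altman
mean difference with 95% limits of agreement at mean ± 1.96·sd.
Density heat-maps count centroids per 512×512 cell.

## Synthetic scenes

No public SRS/H&E counting data exist, so the generator is first-class.
A scene places `n_cells` elliptical cells: equivalent radius m uniform
in (3, 4) µm, axes m/√q and m·√q with aspect ratio q ~ U(0.6, 1) — so
the area is exactly πm², keeping the single-cell area distribution
bounded and unimodal, which is what lets the fence rule separate genuine
cells from merged pairs.  A fraction `overlap_fraction` of cells is
placed against an anchor at centre distance (0.90–0.99)·(r₁+r₂):
shallowly abutting nuclei, the regime in which watershed splitting and
the fence rule are both exercised.  Isolated cells keep ≥ 3 px clearance
so they stay distinct under 8-connectivity.  Vessel-like artifacts
(elongated, > 500 µm²) are rendered with cell-like colour but never
labelled.  Rendering: smooth green lipid texture (Gaussian-filtered
noise), suppressed green / elevated blue inside bodies, additive
Gaussian sensor noise, clipped to [0, 1].  The paired H&E frame drops
each cell with probability `he_dropout_prob`, shifts survivors by a
rounded Gaussian (`he_shift_px_sd`), and renders dark hematoxylin-blue
nuclei on an eosin-pink background; it returns its own post-shift
ground truth.

The default scene is 4608² px at 0.37 µm/px with 3000 cells (~4% cell
pixels — strong class imbalance, as in tissue), 20% overlap, three
artifacts, noise sd 0.05, H&E shift sd 3 px and dropout 5%.

**What the generator does not emulate:** Raman spectral physics,
intensity gradients from tissue depth, staining variability, densely
clustered cell sheets, or non-elliptical morphology.  Passing tests
demonstrate the pipeline's correctness and its behaviour under the
stated noise/overlap regime — not performance on real specimens.

## Scaled study profile and problem sizes

The reference studies (`srscount.study`, rerun by
`scripts/acceptance.py`) use a scaled single-CPU profile chosen once:
kernels (8, 16, 32), batch 8, epoch cap 6 (under this cap any early-
stopping patience ≥ 6 is equivalent to the default 25, since stopping
cannot trigger before the cap).  Training uses ~270 of the default
scene's 324 patches with 50 held out; counting studies use ten 1024² /
50-cell clean scenes per condition; agreement uses a 2048² paired scene
(~590 cells) with 512-px FOVs.  The full-size configuration (16..256
kernels, 300-epoch cap, 2048-px FOVs) remains the package default for
real data.

## Numerical choices and edge cases

* Coordinates are 0-based row-major, origin top-left, rectangles
  half-open; SRS channel order is (green = lipid, blue = protein); an
  SRS file with a non-zero red channel logs a warning and the channel is
  dropped.  Resolution comes from configuration, not TIFF tags.
* Integer rasters are scaled to [0, 1] by the dtype maximum; the loader
  is bit-depth-agnostic.  Instance maps are 16-bit single-channel TIFF.
* Thresholds are strict: probability 0.5 is non-cell; marker threshold
  is rescaled distance > 0.5.
* Quartiles by linear interpolation; fence rule needs ≥ 4 instances;
  multiplicity floor is 2 (an instance above the fence is at least a
  doublet).
* Empty masks count 0 cells (not an error); empty K-means clusters are
  re-seeded to the worst-fit pixel; K > distinct pixels is an error at
  the `kmeans_fit` level.
* Pearson r is reported missing when either count list has zero
  variance; sensitivity/specificity likewise when undefined.

## Known limitations

* Watershed cannot split pairs merged beyond d ≈ 1.8 r (see above); the
  fence rule recovers the count but not the instance boundaries.
* The maximum observed cell area is reported, not enforced as a cap.
* Per-patch K-means can disagree across patch boundaries, fragmenting
  cells that straddle them; fragments below the size filter are lost.
* The NumPy backend is CPU-bound; full-size training on real
  whole-slide regions is practical but slow (minutes per epoch on
  hundreds of 256² patches).
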