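# Methods

## Problem and approach

Small tissue lesions — lung nodules, liver tumours — cover a few percent
of the pixels of a CT slice at most, so a segmentation network trained
on such slices sees a background:lesion pixel ratio on the order of 98:2
to 89:11 and learns to favour the background class. `mofaug` prepares
training data that counteracts this imbalance in two complementary ways:

1. **data-level**: copy-paste oversampling of real lesion patches into
   the training images, optionally with a random affine transform per
   paste ("multiple oversampling fusion", MOF), which raises both the
   minority-class pixel fraction and the lesion object count without
   adding images;
2. **loss-level**: median-frequency class weights for a weighted
   cross-entropy loss, computed over the (augmented) training corpus.

The package prepares data and computes weights; network training itself
is out of scope.

## Preprocessing

Raw slices arrive in Hounsfield units (HU; water 0, air −1000). The
chain is:

1. **Windowing** — clip to a tissue window and rescale linearly so the
   lower bound maps to 0 and the upper to 1. Defaults: lung
   (−1000, 250), liver (−100, 250). The mapping is monotone, idempotent
   on re-windowed data, and removes bone (> 400 HU) and other
   irrelevant structures by saturation.
2. **Organ-centred cropping** — the smallest axis-aligned square
   containing the organ mask's bounding box (side = max of the bbox
   extents), clamped to the image. When the square exceeds the image
   bounds, the image is padded symmetrically with its post-clip
   minimum, which keeps the organ centred. Cropping runs before
   resizing (flagged in the config as `resize_order:
   crop_then_resize`); the alternative order would resample twice.
3. **Resize** to `out_size`² (default 512²): bilinear for intensities
   (anti-aliased only when downscaling), nearest-neighbour for masks so
   they stay binary. All masks of a slice undergo the identical
   geometric transform, so image, organ mask and label mask stay
   co-registered.

Coordinates are 0-based `(row, col)`, origin top-left, throughout.

## Augmentation operators

A *lesion patch* is one 8-connected component of the label mask, cut to
its bounding box, carrying its intensities and binary footprint.

Transforms, applied per paste in the fixed order rotate → enlarge →
mirror:

* **rotate(θ)** — about the patch centre on an expanded canvas, then
  trimmed back to the footprint's bounding box; bilinear for
  intensities, nearest for the footprint. θ = 0 is the exact identity
  (short-circuited), so the group identity holds bitwise.
* **enlarge(ω)** — output dims `round(ω·dims)` (min 1), ω ∈ [0.5, 2.0];
  new pixels filled by interpolation, footprint nearest-neighbour.
  ω = 1 short-circuits to an exact copy.
* **mirror(τ)** — column reversal (`horizontal`) or row reversal
  (`vertical`); an involution.

Degenerate case: a rotation or shrink can in principle annihilate a
sub-pixel footprint under nearest-neighbour resampling; the operators
then keep the canvas centre pixel so a patch never loses its footprint.

### Placement constraints

A candidate paste at anchor `(row, col)` is accepted iff

1. **margin** — the pasted bounding box lies ≥ `border_margin` pixels
   (default 5) from every image edge;
2. **containment** — default `full_footprint`: every footprint pixel
   lies inside the organ region, because a lesion must sit on its host
   tissue. `anchor_only` (just the anchor pixel inside the organ) is
   selectable, matching a literal membership test of the anchor
   coordinates;
3. **non-overlap** — the footprint, dilated by `min_separation` pixels
   (default 1, 8-connected), intersects no existing lesion pixel.
   Footprints, not bounding boxes, are compared: stricter and
   unambiguous. The 1-pixel clearance is a deliberate strengthening of
   plain non-overlap: without it a paste could land 8-adjacent to an
   existing lesion, the two would merge into one connected component,
   and the bookkeeping "new components = accepted pastes" (which the
   constraint-soundness checks rely on) would fail. `min_separation: 0`
   restores plain footprint non-overlap.

Anchors are drawn uniformly over the whole image; each patch gets a
retry budget of `retry_budget` = 100 placement draws, after which it is
skipped and the shortfall is reported (the result records accepted
placements and rejection reasons per draw). Newly pasted lesions
immediately count as existing for subsequent overlap checks, so pastes
within one call can never overlap each other.

### Drivers

* **`oversample`** (plain): patches come from the image's own lesions
  and are pasted untransformed. An image without lesions is an error.
* **`mof_augment`**: patches are drawn uniformly from a *bank* pooled
  over the training set; each paste samples θ ~ U(0, π),
  ω ~ U(0.5, 2.0) and a uniformly chosen mirror axis. The per-paste
  draw order is fixed — patch index, θ, ω, τ, then placement draws —
  from a single seeded `numpy.random.Generator`, so identical seed +
  inputs give bitwise-identical outputs. The target image's existing
  lesions are kept; pasted lesions are not fed back into the bank.

Pasting is hard replacement of intensities on footprint pixels only —
no blending or feathering — so every pixel outside accepted footprints
is bitwise unchanged.

## Class weighting and loss

Over a corpus with per-class pixel counts `N_c` (background, lesion) and
total `T`, frequencies are `F_c = N_c / T` and weights

    W_c = median(F_c) / F_c .

With two classes the median is the mean of the two frequencies
(standard even-length convention), so a balanced corpus gets unit
weights, the rarer class always gets the strictly larger weight, and
the weighted pixel mass `W_c · N_c` is exactly equal across classes. A
class absent from the corpus (`F_c = 0`) has no defined weight and is
rejected. Weights are computed once over the augmented training corpus,
not per image.

The weighted cross-entropy over predicted lesion probabilities `P_i`
and binary targets `T_i` is

    WCE = −(1/n) Σ_i W_{c(i)} [ T_i log P_i + (1 − T_i) log(1 − P_i) ]

with `W_{c(i)}` the weight of pixel *i*'s **target** class (the
standard indexing when prediction and target disagree) and `n` the
number of summed pixels, making the loss scale resolution-independent.
Probabilities are clipped to `[eps, 1 − eps]`, `eps = 1e−7` by default.

## Metrics and split

Pixelwise `TP`, `FP`, `FN` feed precision, recall, Dice and the
volumetric overlap error `VOE = 1 − TP/(TP+FP+FN)`; zero denominators
yield NaN markers rather than exceptions. Algebraically
`VOE = 1 − Dice/(2 − Dice)` and Dice is the harmonic mean of precision
and recall — both identities are asserted in the test suite.

The split utility shuffles indices with a seeded generator and cuts at
`round(0.8·n)` (half-up): 1186 → (949, 237) and 201 → (161, 40), the
only rounding rule consistent with both pairs. The shuffle is
unstratified. A k-fold mode (`kfold_split`) provides disjoint,
exhaustive folds for cross-validation-style partitioning; no training
harness is included.

## Phantom generator

The generator emulates the one structural property the method needs: a
large homogeneous organ containing few small high-contrast lesions.
Each phantom is an elliptical organ (default semi-axes 0.38/0.32 of the
image side) of liver-like tissue (uniform 40–70 HU plus Gaussian noise,
sd 5 HU, clipped back to range) on an air background (−1000 HU), with
`n_lesions` discs (default 3) of radius 3–20 px at organ HU + 60,
placed fully inside the organ, ≥ 5 px from the image border, and
mutually separated — i.e. the generator obeys the same constraint
system the augmentation operators enforce. Defaults reproduce the small-
nodule imbalance regime: one radius-8 disc in a 512² frame is ≈ 0.08 %
lesion pixels; three 3–8 px discs in a 128² frame give ~1–3 %.

What the phantoms do **not** model: lesion morphology (real nodules are
not discs and vary far more in texture and shape), organ anatomy,
partial-volume effects, scanner noise spectra, or 3D context. Passing
tests therefore demonstrate the correctness of the geometric/label-level
mechanics — which are morphology-agnostic — not segmentation performance
on clinical data.

Corpus generation derives per-image seeds from a master seed
(`numpy SeedSequence`, reduced below 2³¹) and records every parameter in
a JSON manifest, so a corpus is reproducible from its manifest alone.

## Problem sizes in tests and reports

The test suite and the reproduction script run on 128² phantoms with
3 lesions of radius 3–8 px and corpora of 8–100 images — small enough to
iterate on quickly while preserving the imbalance regime; the operators
are resolution-independent, and the 512² default remains the production
setting.

## Known limitations

* Binary (background/lesion) labels only; no multi-class taxonomy.
* 2D slices only; a 3D volume is consumed one z-plane at a time.
* No lesion blending/synthesis — pastes are hard replacements, so a
  paste boundary can be sharp against its new surroundings.
* Organ masks are inputs; no lung/liver auto-segmentation.
* PNG storage of HU data uses a fixed +1024 offset (16-bit unsigned);
  HU below −1024 would clip — use NIfTI/MetaImage/TIFF for such data.
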