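# Methods

## Problem

Barley seed coats accumulate two pigment groups: anthocyanins (blue/purple
flavonoids) and melanin (a dark polymer). Both darken the grain, so their
presence cannot be distinguished reliably by eye; chemical assays are
accurate but expensive. `grainpigment` classifies RGB photographs of grains
in a Petri dish into four pigment-composition classes — NP (no pigments),
A (anthocyanins), M (melanin), AM (both) — equivalently a pair of binary
presence flags per image.

## Pipeline

1. **Grain-region segmentation.** A U-Net separates the grain-filled dish
   region from the background. Its mask restricts descriptor extraction to
   grain pixels and its bounding box provides the dish crop fed to the CNN
   classifier.
2. **Color descriptors.** Each image is summarized by 2,380 descriptors
   over grain pixels: for the 12 channels of RGB, HSV, Lab, and YCrCb —
   channel mean, channel SD, and a 196-bin normalized histogram
   (12 × 198 = 2,376) — plus grayscale mean, grayscale SD, the dark-pixel
   fraction (gray < 0.1), and the grain-area fraction of the frame. All
   channels are rescaled to [0, 1] first so thresholds are comparable
   across spaces. The registry is configuration-driven (`hist_bins`), so an
   alternative decomposition with the same total can be swapped in.
3. **Filtering.** Three rules in fixed order: drop columns identical across
   all images; drop columns whose value is ≤ 0.01 in strictly more than
   20 % of images (removes uninformative near-empty histogram bins); then a
   greedy scan in descriptor order that drops any column with
   |Spearman ρ| ≥ 0.97 against an already-retained column
   (first-retained-wins, average ranks for ties). The retained set is a
   deterministic function of column order and data, and the filter is
   idempotent. The retained count is dataset-specific, not an invariant.
4. **Classifiers.** Four models map an image to the two presence flags:
   - **RF13** — filtered descriptors → z-normalization (training statistics
     only) → PCA to 13 components → random forest (500 trees), 4-class.
   - **CNN classifier** — a residual network over the dish crop: stacked
     3×3 convolution blocks with additive skips, channel doubling at each
     of 3 downsampling stages, global average pooling, one fully connected
     layer with two sigmoid outputs.
   - **U-Net + classification head** — one forward pass yields the grain
     mask and the two scores; the head is a pooled linear readout of the
     encoder bottleneck; joint loss = segmentation (BCE + soft Dice) +
     λ·classification BCE with λ = 1 by default (λ = 0 degenerates to pure
     segmentation and freezes the head).
   - **2-channel segmentation** — a U-Net whose two output channels
     segment anthocyanin- and melanin-carrying pixels. Supervision is
     label-broadcast (every grain pixel inherits its accession's flags), a
     deliberate weak-label scheme since per-pixel chemical truth does not
     exist. The image label uses the any-pixel rule: a pigment is present
     iff its channel's positive-pixel fraction exceeds `min_fraction`
     (default 0 — one positive pixel suffices). The fraction knob exists
     because the literal rule is noise-fragile; the default preserves it.

   Score-emitting models decide presence by a strict threshold: pigment
   present iff score > 0.5, both at or below → NP.

## Network engine

The networks run on a small NumPy engine written for this package:
im2col-based 3×3/1×1 convolutions, 2×2 max pooling, nearest-neighbor
upsampling, instance normalization, residual double-conv blocks, Adam, and
BCE/soft-Dice losses, with manual backprop verified against finite
differences in the test suite. Encoder "families" are reduced-width
analogues of the named reference topologies (`resnet18`-style: one residual
block per stage; `resnet34`-style: two; `efficientnet-b0`-style: wider
single blocks); they set block count and width multiplier, not the exact
reference layer inventory.

Two engine-level choices matter for convergence at small step budgets:
instance normalization (stateless across batches, so train and eval paths
are identical) keeps training stable at learning rate 10⁻², and the U-Net
output convolution sees the raw input channels next to the decoder features
(a full-resolution input skip), so pixel-wise color rules are directly
expressible. The networks consume a 6-channel color stack (RGB + HSV):
hue and saturation carry the pigment distinctions (purple anthocyanin vs
near-achromatic melanin), and providing them at the input avoids spending
optimization steps re-deriving them from RGB. The U-Net output convolution
starts at zero so the first steps move the whole logit map coherently.

Defaults (all configurable): segmenter — 128 px input, depth 5, base width
8, 5 epochs, Adam lr 10⁻², batch 1, BCE + Dice, best epoch by validation
loss; CNN classifier — 64 px, 3 stages, 20 epochs; multi-task and 2-channel
U-Nets — 64 px, depth 4 (a 4×4 bottleneck at 64 px keeps the pooled head
informative; at depth 5 the 2×2 bottleneck starved it), 15 and 25 epochs.
All training is a pure function of (data, config, seed).

## Evaluation

ACC pools the two binary decisions of every image into one contingency:
ACC = (TP + TN)/(P + N) with P + N = 2 × images. Per-pigment tallies and
the 4-class error matrix are always reported alongside, so the
per-pigment-averaged reading is also available (the two coincide when both
pigments cover the same image count — an identity asserted in the tests).
The hulled-vs-hulless comparison is a two-sided Mann–Whitney rank-sum test
on per-image correctness indicators per pigment: correctness indicators are
heavily tied, so for total samples ≤ 20 the permutation null is enumerated
exactly; larger samples use the tie-corrected normal approximation.

## Synthetic data

The generator emulates the acquisition protocol the pipeline assumes: a
circular dish densely packed with 100–160 convex grains on a light
background, 9 replicates per accession obtained by re-randomizing grain
placement. Grains are filled ellipses placed largest-first by rejection
sampling with bounded overlap (≤ 15 % of a grain's area against already
painted grains, with a bounded shrink for late placements in a crowded
dish); an impossible packing raises an explicit error rather than silently
dropping grains. Physical contact mechanics are not simulated — the
classifiers consume region color statistics, not individual grain geometry.

Class palettes are HSV distributions chosen to match the qualitative
descriptions of the four classes: NP tan-yellow (high value, mid
saturation), A purple-blue, M near-achromatic dark, AM sharing A's hue
support at M's dark value range — so AM overlaps both parents, the
confusion structure real grains show. The hull factor raises value and
lowers saturation within class, affecting within-class variation more than
class separation. Per-accession palette jitter, per-grain color spread,
per-grain linear shading, and per-pixel Gaussian noise (σ = 3 on 8-bit
values) are calibration knobs, not measured values: no quantitative
within-class color variance for real accessions is available. A hard-mode
configuration narrows the A–AM and M–AM gaps to reproduce the hardest
confusions qualitatively.

Masks are exact by construction (the mask is the set of painted grain
pixels), so segmentation and extraction are tested against ground truth
rather than estimates. What passing tests on this data do **not** show:
robustness to real grain texture, specular highlights, camera optics,
JPEG artifacts, or chemically mislabeled accessions. The synthetic task is
closer to linear pixel-wise separability than real photographs are, which
is why scaled-down training recovers high accuracy quickly.

## Splitting

The accession is the unit of labeling and splitting: all replicates follow
their accession, so no accession leaks across splits. Stratification is by
pigment class × hull status — the two factors the analysis compares. Global
bin sizes follow largest-remainder apportionment of the accession total
(79 accessions at 60/20/20 give exactly 47/16/16 for any seed); seats are
dealt to strata by remainder size under the global per-bin targets, and
accessions are shuffled within strata by seed. The holdout set is an input
designation (a named accession list), not a fourth random fraction.

## Problem sizes

The test suite and the acceptance script train at desk scale: 96 px
benchmark images, 24 accessions × 3 replicates for classification, ~20
images at 128 px for segmentation, 5–25 epochs. Full-resolution operation
is a configuration change, not a code change.

## Known limitations

- The descriptor decomposition reproduces the documented total (2,380) and
  ingredient kinds; the original itemization is not public, so the exact
  histogram bin count per channel is this package's choice.
- The any-pixel rule makes 2-channel predictions sensitive to single stray
  pixels; `min_fraction` exists as the documented mitigation.
- Encoder families are reduced-width analogues, not the reference layer
  inventories; at these image sizes and data volumes the full topologies
  would be unjustifiable.
- The rank-sum test on binary indicators has low power at small n; exact
  enumeration only guarantees correctness of the p-value, not power.
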