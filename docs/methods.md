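# Methods

## Problem and model

Nuclei detection in H&E-stained histopathology is confounded by non-nuclei
signal — fibrous stroma, tissue folds, interstitial texture — that survives
stain deconvolution and produces spurious blob responses in classic
detectors. `hescrub` removes that signal before detection by learning a
texture vocabulary in the noiselet domain:

1. **Stain separation.** The RGB field is converted to optical density
   (Beer–Lambert, `od = -log((I + ε)/I0)`, ε = 1e-6) and unmixed into
   hematoxylin/eosin concentrations with a Macenko-style estimate: the
   foreground OD cloud (norm > 0.15) is projected onto its top-2 singular
   plane and the 1st/99th angular percentile directions are taken as the
   stain vectors. Concentrations come from the pseudo-inverse, clamped at
   0 (physical non-negativity). The column with the larger blue OD
   component is hematoxylin (blue-purple chromatin stain). If the second
   singular direction carries less than 1% of the leading variance the
   image is declared achromatic/single-stain and estimation is refused;
   the full pipeline then falls back to the conventional H&E matrix
   H = (0.65, 0.70, 0.29), E = (0.07, 0.99, 0.11) (unit-normalized),
   which yields an empty segmentation on unstained fields.

2. **Noiselet patch coding.** The hematoxylin channel is cut into
   non-overlapping m×m patches (m ∈ {2, 4, 8}). Each patch is projected
   onto the discrete noiselet basis built from the recursion
   f₁ = χ[0,1), f₂ₙ = (1−i)fₙ(2x) + (1+i)fₙ(2x−1),
   f₂ₙ₊₁ = (1+i)fₙ(2x) + (1−i)fₙ(2x−1), sampled on the m dyadic
   subintervals and scaled by 1/m so the matrix is unitary (Parseval
   holds; distances are scale-free). The 2D transform is separable
   (C = M P Mᵀ). Features are the real parts followed by the imaginary
   parts of the 2D coefficients — length 2m² (8 features for 2×2
   patches). Noiselets spread localized signals flat across the spectrum
   and place low- vs high-frequency content 90° apart in phase, which is
   what lets smooth chromatin and oscillatory stroma separate.

3. **Code-book.** Patch features are clustered by k-means under
   city-block distance with coordinate-wise **median** updates — the L1
   minimizer, so the clustering objective is provably non-increasing.
   Initialization is k-means++ seeding adapted to L1 with a seeded RNG;
   emptied clusters are re-seeded from the farthest point. Defaults:
   K ∈ {2, 4, 8, 16}, max 100 iterations, convergence at an assignment
   fixpoint.

4. **Tile classification and removal.** The image is tiled (t ∈ {8, 12,
   16, 20, 24}, remainder pixels pass through untouched) and each tile
   summarized by its codeword-occurrence histogram (counts sum to
   (t/m)²; raw counts, since the sum is constant per configuration).
   Training tiles are labeled nuclei when ≥ 50% of their pixels lie in
   the ground-truth mask (configurable). A discrete AdaBoost ensemble of
   depth-1 stumps (default 50 rounds; a round halts training when its
   best weighted error reaches 0.5, or immediately after a perfect
   stump) votes nuclei vs non-nuclei; non-nuclei tiles are blanked
   (0 in the hematoxylin channel, white in RGB).

5. **Detection/segmentation.** The (optionally denoised) hematoxylin
   channel is smoothed (Gaussian σ = 1), negated (the detector's
   dark-blob convention; concentration maps have nuclei bright) and fed
   to a Loy–Zelinsky fast radial symmetry transform: above-threshold
   gradient pixels (5% of the max magnitude) vote r pixels toward the
   putative center for r ∈ {5, 10, 15, 20, 25, 30, 35}; the per-radius
   response (O/κ)^α·M/κ (κ = 9.9, α = 2) is Gaussian-smoothed with
   σ = r/2 and averaged. Markers are the suppressed local maxima (min
   distance 10 px, relative threshold 0.2) that sit on at least 0.1 OD
   of hematoxylin — an absolute floor that keeps unstained fields
   detection-free. Marker-controlled watershed runs on the negated
   channel with a background basin seeded below half the Otsu threshold
   (eroded by a radius-3 disk). Regions outside 314–4900 px² area,
   below 0.4 roundness (4π·area/perimeter²) or 0.7 solidity are
   discarded.

The nucleus-geometry defaults (radii 5–35 px, area window 314–4900 px²)
assume nuclei of roughly 20×20 to 70×70 px at 40× magnification; all are
configurable per tissue.

## Evaluation

* **Dice** on the pooled nucleus foreground, 2|A∩B|/(|A|+|B|);
  per-image scores are reported both as plain means and means weighted
  by annotated-nucleus count (the "pooled" variant).
* **Detection F-score** F1 = TP/(TP + (FP+FN)/2), where a detection is a
  true positive iff its mask intersects a ground-truth nucleus (≥ 1 px)
  **and** the centroid distance is strictly below 12 px. Matching is
  greedy one-to-one in ascending centroid distance — deterministic and
  near-optimal at this scale.
* **Count correlation**: Pearson r between annotated and detected
  nucleus counts across images; undefined (and refused) for constant
  count vectors, which is why evaluation datasets vary the per-image
  count.

A configuration is a (patch, tile, codes) triple; patch must divide
tile, which leaves 52 valid cells of the 3×5×4 grid. `grid_search`
evaluates each by leave-one-image-out and ranks by mean method F-score
(ties: Dice, then lexicographic config).

## Synthetic data

The generator renders fields of view physically: per-pixel hematoxylin
and eosin concentrations pass through Beer–Lambert with the conventional
stain matrix, so the output round-trips through the deconvolution module
(estimated stain vectors land within ~3° of the truth). Content:

* **Nuclei**: non-overlapping soft-edged ellipses (semi-major axis
  10–35 px by default, axis ratio 0.75–1.0), hematoxylin-dominant with a
  per-nucleus mean ~N(0.85, 0.08); half the nuclei get a chromatin
  speckle component (+0.35) giving a bimodal intensity histogram.
  Placement is rejection sampling with a bounded attempt budget;
  infeasible packings raise an error rather than silently under-filling.
* **Background**: eosin-dominant (~0.3) with preset textures —
  `fibrous_stroma` (oriented sinusoidal fiber bands, wavelength 4–9 px,
  carrying ~0.4 hematoxylin), `fold_artifact` (a large blobby smudge
  piling ~0.55 hematoxylin and 0.35 eosin with internal speckle),
  `mixed`, or `flat`.
* iid Gaussian concentration noise (default 0.02) and 8-bit
  quantization.

All randomness flows from one seed; samples are bit-reproducible.
Dataset generation derives per-image seeds from a master seed and can
vary the per-image nucleus count over a range.

What the generator does **not** emulate: real chromatin substructure,
out-of-focus blur, scanner/compression artifacts, stain variation across
institutes, touching/overlapping nuclei, and the full diversity of
stromal morphologies. Passing tests therefore demonstrate that the
pipeline exploits the intended texture/frequency contrast and that the
implementation is internally correct — not that the reported scores
transfer to clinical material.

## Study conditions used by the acceptance run

`scripts/acceptance.py` re-derives its numbers from scratch at each run:
8 synthetic fields of 512×512 px, 20–40 nuclei each (semi-major axis
12–20 px, within the 20–70 px diameter regime the detector defaults
assume), `mixed` background; pipeline configuration patch 2 / tile 12 /
8 codes (the configuration class that dominates the soft-tissue optima),
leave-one-image-out. Field size and count are a deliberate desk-scale
choice; the per-patch codebook subsample is capped at 20 000 features.
The script also reports: worst-case noiselet unitarity/round-trip error,
the 52-cell grid count, two-codeword purity on nucleus-vs-stroma patches
(4 000 patches), and detection F on a clean 12-nucleus field.

## Numerical choices and edge cases

* Noiselet bases are built by explicit recursion and applied as dense
  matrix products — exact and trivially fast at m ≤ 16; no butterfly.
* k-means ties in assignment go to the lowest centroid index; stump
  candidate thresholds are midpoints of consecutive distinct feature
  values plus sentinels outside the range; ties resolve to the lowest
  feature index, then lowest threshold, then polarity +1.
* AdaBoost on single-class input, empty histograms, or zero rounds is a
  parameter error; fully contradictory data degrades to a majority-vote
  stump with negligible weight rather than crashing.
* Dice of two empty masks and Pearson of constant vectors are refused
  explicitly (degenerate-input errors), not silently defined.
* The stain matrix is estimated per image by default (config switch for
  a fixed matrix); estimation failure falls back to the conventional
  matrix inside the segmentation pipeline only.

## Known limitations

* The watershed basin of a nucleus includes part of its soft skirt, so
  Dice saturates around 0.85 even on clean renders.
* Tile removal is hard (all-or-nothing per tile); partially nuclear
  tiles below the label threshold can clip nucleus borders — the reason
  the paired evaluation tracks Dice as well as F.
* The greedy matcher is not globally optimal (Hungarian), though at a
  12-px gate on non-overlapping nuclei the difference is negligible.
* City-block k-means cost is O(N·K·D) per iteration with dense
  distances; fine for desk-scale vocabularies (K ≤ 16, N ≤ 2·10⁴).
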