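# hescrub

Removing non-nuclei signal from H&E histopathology images before nuclei
detection.

Reliable nuclei detection and segmentation in hematoxylin & eosin (H&E)
images is confounded by background structure — fibrous stroma, tissue
folds, interstitial texture — that survives stain separation and
produces spurious blob responses. `hescrub` implements a preprocessing
method that *learns what the noise looks like* and removes it:

1. the hematoxylin channel is recovered by Macenko-style color
   deconvolution (Beer–Lambert optical density, per-image stain-vector
   estimation);
2. small patches (2×2 to 8×8 px) are projected onto the **noiselet**
   basis — a complex Haar–Walsh-derived family, built from the recursion
   f₁ = χ[0,1), f₂ₙ = (1−i)fₙ(2x) + (1+i)fₙ(2x−1),
   f₂ₙ₊₁ = (1+i)fₙ(2x) + (1−i)fₙ(2x−1) — whose coefficients spread
   localized signals across the whole spectrum and separate low from
   high frequencies by a 90° phase shift;
3. patch features are clustered by k-means under city-block distance
   into a **code-book**; every image tile (8×8 to 24×24 px) becomes a
   bag-of-codewords histogram;
4. an AdaBoost ensemble of decision stumps classifies tiles as nuclei
   vs non-nuclei, and non-nuclei tiles are blanked out;
5. a classic detector — fast radial symmetry transform for markers,
   marker-controlled watershed, area/roundness/solidity filtering —
   runs on the cleaned channel.

Evaluation uses the Dice score DSC = 2|A∩B|/(|A|+|B|), the detection
F-score F1 = TP/(TP + (FP+FN)/2) under a 12-px centroid matching rule,
and the Pearson correlation between annotated and detected nucleus
counts. A seeded synthetic H&E generator (blob-like hematoxylin nuclei
over textured eosin stroma and fold artifacts, rendered through
Beer–Lambert) provides ground-truthed fields so the whole pipeline is
testable without any external dataset. See `docs/methods.md` for the
model details and design choices.

## Worked example

Train on three synthetic noisy fields, evaluate on the held-out fourth,
rotating leave-one-out:

```python
import hescrub as h

params = h.SyntheticParams(image_size=(320, 320), n_nuclei=12,
                           radius_range=(12.0, 18.0),
                           background_preset="mixed", seed=0)
samples = h.generate_dataset(4, params, seed=0, n_nuclei_range=(8, 16))

cfg = h.PipelineConfig(patch_size=2, tile_size=12, n_codes=8, seed=0)
df = h.leave_one_out(samples, cfg)
for key, value in df.attrs["summary"].items():
    print(f"{key:22s} {value:.3f}")
```

prints

```
f1_baseline            0.761
f1_method              0.967
dice_baseline          0.582
dice_method            0.807
dice_baseline_pooled   0.564
dice_method_pooled     0.801
count_correlation      0.999
```

The baseline columns are plain watershed detection on the raw
hematoxylin channel; the method columns repeat it after tile denoising.
On these fields the fibrous stroma and fold artifacts cost the baseline
about 0.2 in detection F-score, which tile removal recovers, and the
detected counts track the annotated counts almost perfectly.

The same pipeline is scriptable from the shell:

```sh
hescrub simulate --out ds --n-images 4 --n-nuclei 20 --preset mixed --seed 0
hescrub train ds --codebook-out book.json --model-out model.json
hescrub segment ds/images/img_000.png --out seg.tif \
        --codebook book.json --model model.json
hescrub evaluate ds --out report.json
hescrub grid-search ds --out ranked.csv   # all 52 valid (patch, tile, codes)
```

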