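# dabquant

Block-based classification and quantification of a cytoplasmic DAB-stained
immunohistochemistry (IHC) biomarker in brightfield tissue-microarray (TMA)
core images, with Allred scoring and the agreement statistics used to
validate automated scoring against expert ratings.

Manual Allred scoring of IHC slides is subjective and slow; this package
automates it for cytoplasmic markers (where nucleus counting does not
apply) by quantifying the DAB signal at pixel level. It is aimed at
digital-pathology and image-analysis researchers working with
hematoxylin/eosin-counterstained, DAB-developed brightfield images.

## Method

For a core image *I* the pipeline is:

1. **Partition** *I* into an 8×8 grid of non-overlapping blocks *B<sub>ij</sub>*
   (64 blocks per core; block sizes within one pixel of each other).
2. **Colour deconvolution** (Ruifrok–Johnston): per-channel optical density
   OD<sub>c</sub> = −log₁₀((p<sub>c</sub>+1)/256) is linear in stain
   concentrations, so solving the 3×3 system against the unit stain vectors
   (H, E, DAB) gives per-pixel concentration maps; the tissue mask is
   H + E ≥ 0.15 OD.
3. **K-means (k = 4)** on the RGB values of the DAB single-stain rendering,
   from fixed seed centroids C₁=(64,32,21), C₂=(105,51,27), C₃=(124,87,45),
   C₄=(255,255,255) — high / medium / low DAB intensity and light regions.
   Lloyd iterations (nearest centroid in Euclidean distance, member-mean
   update) run to convergence; the procedure is fully deterministic.
4. **Allred scoring** per block: positive fraction = |labels ∈ {1,2,3}| over
   tissue ∪ positive pixels, binned to the proportion score
   (0; (0,1%]→1; (1,10%]→2; (10,33%]→3; (33,66%]→4; (66,100%]→5); intensity
   score = majority positive cluster (k=1→3 strong, k=2→2, k=3→1); Allred
   score = sum (0 or 2–8); risk class 0–1 / 2–3 / 4–6 / 7–8 rendered as a
   white / yellow / orange / red watermark.
5. **Core classification**: the 8×8 matrix of block risk classes plus the
   watermark overlay.

Evaluation utilities compute confusion matrices, per-class F-scores
(F = 2PR/(P+R), transpose-invariant) and the intraclass correlation
ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) with the
poor/moderate/good/excellent bands at 0.50/0.75/0.90.

A synthetic-image module renders cores with exact per-pixel ground truth by
Beer–Lambert forward mixing, so every stage is testable without any image
downloads.

## Worked example

```python
import numpy as np
from dabquant import SynthConfig, generate_core, classify_core, modal_risk_class

img, truth = generate_core(SynthConfig(height=256, width=256,
                                       tissue_fraction=0.8,
                                       dab_fraction_of_tissue=0.5,
                                       dab_level="high", noise_sd=0.02, seed=7))
result = classify_core(img)
print("block (0,0):", result.block_scores[0][0])
print("modal class:", modal_risk_class(result))
agree = np.mean([result.grid[i][j] == truth.block_risk[i][j]
                 for i in range(8) for j in range(8)])
print("agreement with ground truth:", agree)
```

prints

```
block (0,0): BlockScore(positive_fraction=0.22610015174506828, proportion_score=3,
                        intensity_score=3, allred_score=6, risk_class='4-6')
modal class: 7-8
agreement with ground truth: 1.0
```

Block (0,0) happens to contain ~23 % strongly stained tissue area —
proportion score 3, intensity score 3, Allred 6, risk class 4–6; most other
blocks of this strongly stained synthetic core score 7–8, so the
area-weighted modal class is 7–8, and all 64 recovered risk classes match
the generator's ground truth.

The same pipeline is available from the shell:

```bash
dabquant synth --size 256 --tissue 0.8 --dab 0.5 --level high --seed 7 --out core.png
dabquant score core.png --out results/      # block_scores.csv + overlay PNG
dabquant deconvolve core.png --out stains/  # H / E / DAB renderings
dabquant icc ratings.csv                    # ICC(2,1) + agreement band
```

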