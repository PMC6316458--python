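# Methods

## Model and assumptions

The pipeline treats a brightfield TMA core image as a Beer–Lambert mixture
of three stains. Per channel, optical density is
`OD_c = -log10((p_c + 1) / (bg + 1))` with background intensity `bg = 255`;
the `+1` offset keeps the log finite at `p = 0` and makes pure white exactly
OD 0. Stain concentrations add linearly in OD, so unmixing is the inversion
of the 3×3 row-normalised stain matrix. The default stain vectors are the
published Ruifrok–Johnston values for hematoxylin (0.650, 0.704, 0.286),
eosin (0.072, 0.990, 0.105) and DAB (0.268, 0.570, 0.776), L2-normalised;
they are configurable because stain vectors measured on control slides of a
particular scanner/staining protocol can differ. Negative unmixed
concentrations (pixels outside the stain span) are clipped to zero.

Assumptions inherited from this model: exactly three chromogens, spatially
uniform illumination and stain colour within a core, and a cytoplasmic
marker quantified by **pixel area**, not by cell counts — there is no cell
segmentation anywhere in the method, so "proportion of positive cells" is
operationalised as the DAB-positive pixel fraction.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid side | 8 | blocks | fixed 64-block partition of a core; remainder pixels go one-per-block to the earliest rows/columns (most even split, larger blocks first) |
| tissue OD threshold | 0.15 | OD (H+E) | separates counterstained tissue from glass/background; configurable |
| K-means seeds | (64,32,21), (105,51,27), (124,87,45), (255,255,255) | RGB | fixed domain seeds for high/medium/low DAB and light regions; make the clustering deterministic |
| K-means tolerance | 0.5 | RGB units (max centroid displacement) | sub-pixel convergence; iteration cap 100 |
| cluster input | DAB rendering | — | the single-stain DAB rendering isolates the chromogen from counterstain colour; a `raw` switch clusters the original block instead (different semantics: counterstained tissue itself lies nearest the low-DAB seed) |
| positive-fraction denominator | tissue ∪ positive pixels | — | strongly stained cytoplasm with little counterstain still counts as area; guarantees fractions ≤ 1 |
| block intensity | majority positive cluster, ties toward stronger | — | a deterministic pixel→block reduction of the three intensity levels |
| watermark alpha | 0.35 | blend weight | overlay remains readable over tissue texture; colours white/yellow/orange/red = (255,255,255)/(255,255,0)/(255,165,0)/(255,0,0) |

K-means details: assignment is Euclidean nearest centroid with ties broken
toward the smallest k; update is the arithmetic mean of member pixels; an
empty cluster retains its previous centroid so each k keeps its semantic
anchor. The within-cluster sum of squares is non-increasing across
iterations (asserted in tests). The centroid update uses member pixels
only; a literal reading of the published update formula would inject the
white fill value of the rendering step into the mean and drag every
centroid toward white.

Allred arithmetic: proportion bins are open on the left and closed on the
right, so a fraction of exactly 0.01 scores 1 and 0.0100…01 scores 2; the
proportion and intensity scores are zero together or nonzero together,
hence a total of 1 is impossible and the score range is {0} ∪ {2..8}.
ICC bands assign boundary values (0.50, 0.75, 0.90) to the upper band.

Per core, the full 8×8 risk-class matrix is the result; the area-weighted
modal class (`modal_risk_class`, ties toward higher risk) is offered as a
reporting convenience, clearly a convention of this package.

## Evaluation statistics

Per-class F-scores are computed from the K×K confusion matrix as
`F_i = 2 P_i R_i / (P_i + R_i)` with precision `TP_i / colsum_i` and recall
`TP_i / rowsum_i`, and `F_i = 0` when `TP_i = 0`. F is invariant to
transposing the matrix, so results do not depend on which rater indexes the
rows. ICC(2,1) — two-way random effects, absolute agreement, single rater —
is computed from the ANOVA mean squares
`(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`; degenerate tables
(zero total variance) raise an error rather than returning NaN.

## Synthetic data: what it emulates and what it does not

The generator draws blob-shaped tissue and DAB-positive footprints as upper
level sets of a smoothed random field, taking exactly the requested number
of pixels, so realised area fractions are exact counts. Tissue carries
H = 0.5 and E = 0.3 OD; DAB levels map to OD {low: 0.9, medium: 1.35,
high: 2.2}. These level ODs are calibrated so that a pure-DAB rendering at
each level falls nearest the corresponding K-means seed (low→C₃, medium→C₂,
high→C₁) under the default basis, with ≥ 10 RGB units of margin; the
calibration must be redone if the stain basis is changed (a test asserts
the property). Noise is additive Gaussian in OD space (multiplicative in
transmitted light), default SD 0.02, emulating stain/scanner variation;
masks and per-block truths are recorded pre-noise, and per-block truth
scores are derived from the masks by the same bin rules the pipeline uses.

What the synthetic images do **not** contain: nuclear/cytoplasmic texture,
stromal structures, debris and artifactual staining, stain-vector drift
between cores, or compression artefacts. Passing the recovery tests
therefore demonstrates the correctness of the arithmetic chain
(deconvolution → clustering → binning) under controlled mixing, not
clinical performance on real tissue, where stroma and debris are the known
confounders for the low-score classes.

## Numerical choices

- **8-bit quantisation bounds the deconvolution round trip.** The OD
  quantisation half-step at pixel value p is ≈ 0.217/(p+1), amplified by
  the inverse stain matrix (L1 column sums ≈ 2.3–2.6). Round-trip recovery
  to within 0.02 OD is therefore guaranteed only for mixtures whose
  rendered pixels stay above ≈ 20, i.e. concentrations up to about
  H ≤ 0.5, E ≤ 0.3, DAB ≤ 0.8 jointly; the round-trip tests sample that
  regime. Darker mixtures (e.g. the high DAB level inside tissue) unmix
  with larger absolute OD error yet classify correctly, because the
  nearest-centroid margins are far wider than the error.
- Determinism everywhere: fixed K-means seeds, lowest-k tie-breaks,
  empty-cluster retention, seeded generators; identical inputs give
  byte-identical CSV outputs.
- Degenerate inputs: images smaller than the grid, grayscale files,
  singular stain bases, inconsistent score pairs, out-of-range fractions
  and zero-variance rating tables all raise typed errors with the offending
  quantity named.
- Test problem sizes: synthetic blocks are 64×64 pixels and synthetic cores
  96–256 pixels square — large enough that pixel quantisation of area
  fractions (≤ 1/4096) is negligible next to every bin margin used, while
  keeping the full suite fast.

## Known limitations

- Pixel-area proportions are a proxy for the cell-based proportion score of
  clinical Allred grading; stromal exclusion and cell-level analysis are
  out of scope.
- The default stain vectors are literature values, not calibrated to any
  particular scanner.
- Whole-slide formats and TMA de-arraying are not handled; inputs are
  single-core 8-bit RGB images.
- ICC is reported as a point estimate only (no confidence intervals).
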