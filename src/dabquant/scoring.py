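"""Allred scoring of blocks and block-based classification of a whole core.

The Allred system combines two semi-quantitative scores:

* a proportion score in {0..5} from the fraction of positive signal —
  bins (0%,1%], (1%,10%], (10%,33%], (33%,66%], (66%,100%], open on the
  left and closed on the right, with 0 reserved for exactly no signal;
* an intensity score in {0..3} — 1 low, 2 intermediate, 3 strong.

Their sum is the Allred score, 0 (negative) or 2..8, grouped into four risk
classes rendered as watermark colours: 0-1 white, 2-3 yellow, 4-6 orange,
7-8 red.

Because the method has no cell segmentation, "proportion of positive cells"
is computed as a pixel-area fraction: DAB-positive pixels over the union of
tissue and positive pixels.  Block intensity is the majority positive
cluster, ties broken toward the stronger intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterState, cluster_block
from .config import PipelineConfig
from .imaging import BlockGrid, as_rgb_image, partition_blocks, stitch_blocks
from .stains import separate_stains, tissue_mask

#: Risk classes in ascending order with their watermark colours.
RISK_CLASSES = ("0-1", "2-3", "4-6", "7-8")
WATERMARK_COLORS = {
    "0-1": (255, 255, 255),  # white
    "2-3": (255, 255, 0),    # yellow
    "4-6": (255, 165, 0),    # orange
    "7-8": (255, 0, 0),      # red
}

#: Upper edges of the proportion bins for scores 1..5.
PROPORTION_BIN_EDGES = (0.01, 0.10, 0.33, 0.66, 1.00)

# cluster label -> intensity score (k=1 dark/strong ... k=3 light/low)
_LABEL_TO_INTENSITY = {1: 3, 2: 2, 3: 1}


def proportion_score(fraction: float) -> int:
    """Bin a positive-area fraction into the Allred proportion score 0..5.

    Intervals are open on the left and closed on the right, so a fraction of
    exactly 0.01 scores 1 while anything above it scores at least 2; exactly
    zero scores 0.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction == 0.0:
        return 0
    for score, edge in enumerate(PROPORTION_BIN_EDGES, start=1):
        if fraction <= edge:
            return score
    return 5  # unreachable: fraction <= 1.0 == last edge


def intensity_score(state: ClusterState, positive_mask: np.ndarray) -> int:
    """Majority-vote intensity score of the DAB-positive pixels.

    Counts positive pixels per cluster k in {1, 2, 3}, picks the majority
    and maps it to the intensity scale (k=1 -> 3 strong, k=2 -> 2, k=3 -> 1);
    ties go to the stronger intensity.  No positive pixels scores 0.
    """
    labels = state.labels[np.asarray(positive_mask, dtype=bool)]
    if labels.size == 0:
        return 0
    counts = [(labels == k).sum() for k in (1, 2, 3)]
    if sum(counts) == 0:
        return 0
    best_k = 1 + int(np.argmax(counts))  # argmax -> first max -> strongest wins ties
    return _LABEL_TO_INTENSITY[best_k]


def allred_score(proportion: int, intensity: int) -> int:
    """Sum of proportion and intensity scores; 0 or in 2..8.

    The two scores must be consistent: both zero (no signal) or both
    nonzero, hence the total can never be 1.
    """
    if proportion not in range(6):
        raise ValueError(f"proportion score must be in 0..5, got {proportion}")
    if intensity not in range(4):
        raise ValueError(f"intensity score must be in 0..3, got {intensity}")
    if (proportion == 0) != (intensity == 0):
        raise ValueError(
            f"inconsistent scores: proportion={proportion}, intensity={intensity} "
            "(must both be zero or both nonzero)"
        )
    return proportion + intensity


def risk_class(allred: int) -> tuple[str, tuple[int, int, int]]:
    """Map an Allred score to its risk class label and watermark RGB colour."""
    if allred == 1 or not 0 <= allred <= 8:
        raise ValueError(f"Allred score must be 0 or in 2..8, got {allred}")
    if allred <= 1:
        label = "0-1"
    elif allred <= 3:
        label = "2-3"
    elif allred <= 6:
        label = "4-6"
    else:
        label = "7-8"
    return label, WATERMARK_COLORS[label]


@dataclass(frozen=True)
class BlockScore:
    """Per-block quantification: positive fraction and derived scores."""

    positive_fraction: float
    proportion_score: int
    intensity_score: int
    allred_score: int
    risk_class: str


def score_block(block: np.ndarray, config: PipelineConfig | None = None) -> BlockScore:
    """Run the full pipeline on one block and return its scores.

    Stain separation -> tissue mask -> K-means on the DAB rendering (or the
    raw block, per config) -> pixel counting -> Allred scoring.  The
    positive fraction denominator is the union of tissue and positive
    pixels, so heavily stained cytoplasm with little counterstain still
    counts as area; a block with neither tissue nor positive pixels scores
    Allred 0.
    """
    config = config or PipelineConfig()
    block = as_rgb_image(block)
    channels = separate_stains(
        block, config.stain_basis(), config.background_intensity
    )
    tissue = tissue_mask(channels, config.tissue_od_threshold)
    cluster_src = channels.dab_rgb if config.cluster_input == "dab" else block
    state = cluster_block(
        cluster_src,
        max_iter=config.kmeans_max_iter,
        tol=config.kmeans_tol,
        centroids=np.array(config.kmeans_centroids, dtype=float),
    )
    positive = np.isin(state.labels, (1, 2, 3))
    denom = int(np.count_nonzero(tissue | positive))
    n_pos = int(np.count_nonzero(positive))
    fraction = n_pos / denom if denom else 0.0
    p = proportion_score(fraction)
    i = intensity_score(state, positive)
    if (p == 0) != (i == 0):
        # a nonzero fraction can bin to score 0 only when fraction == 0, so
        # the only possible mismatch is p > 0 with no intensity majority —
        # impossible since positive pixels carry labels 1..3; guard anyway
        p = i = 0
    a = allred_score(p, i)
    cls, _ = risk_class(a)
    return BlockScore(
        positive_fraction=fraction,
        proportion_score=p,
        intensity_score=i,
        allred_score=a,
        risk_class=cls,
    )


@dataclass(frozen=True)
class CoreClassification:
    """Block-based classification of a whole core.

    ``grid`` is the 8x8 matrix of risk-class labels (row-major, matching the
    block grid); ``block_scores`` the corresponding BlockScore matrix;
    ``overlay`` the watermarked core rendering.
    """

    grid: tuple[tuple[str, ...], ...]
    block_scores: tuple[tuple[BlockScore, ...], ...]
    overlay: np.ndarray
    block_grid: BlockGrid


def classify_core(
    core: np.ndarray,
    config: PipelineConfig | None = None,
    grid_side: int = 8,
) -> CoreClassification:
    """Partition a core into the block grid, score every block, render overlay."""
    config = config or PipelineConfig()
    grid = partition_blocks(core, grid_side)
    scores = []
    for i in range(grid.grid_side):
        row = [score_block(grid.blocks[i][j], config) for j in range(grid.grid_side)]
        scores.append(tuple(row))
    block_scores = tuple(scores)
    labels = tuple(tuple(s.risk_class for s in row) for row in block_scores)
    core_class = CoreClassification(
        grid=labels,
        block_scores=block_scores,
        overlay=None,  # filled below; dataclass frozen -> rebuild
        block_grid=grid,
    )
    overlay = render_watermark(core_class, core, config.watermark_alpha)
    return CoreClassification(
        grid=labels, block_scores=block_scores, overlay=overlay, block_grid=grid
    )


def render_watermark(
    core_class: CoreClassification, core: np.ndarray, alpha: float = 0.35
) -> np.ndarray:
    """Alpha-blend each block with its risk-class watermark colour.

    ``alpha = 0`` returns the core unchanged; ``alpha = 1`` paints each
    block uniformly in its class colour.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    core = as_rgb_image(core)
    grid = core_class.block_grid
    if (grid.source_height, grid.source_width) != core.shape[:2]:
        raise ValueError("core dimensions do not match the classified grid")
    out = core.astype(float).copy()
    for i, j, block in grid:
        r0, c0 = grid.offsets[i][j]
        bh, bw = block.shape[:2]
        color = np.array(WATERMARK_COLORS[core_class.grid[i][j]], dtype=float)
        region = out[r0 : r0 + bh, c0 : c0 + bw]
        out[r0 : r0 + bh, c0 : c0 + bw] = (1.0 - alpha) * region + alpha * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def modal_risk_class(core_class: CoreClassification) -> str:
    """Area-weighted modal risk class of the 8x8 grid (a reporting convenience).

    Each block votes with its pixel area; ties go to the higher-risk class.
    """
    votes: dict[str, int] = {c: 0 for c in RISK_CLASSES}
    grid = core_class.block_grid
    for i, j, block in grid:
        votes[core_class.grid[i][j]] += block.shape[0] * block.shape[1]
    # iterate high-risk first so ties resolve upward
    return max(reversed(RISK_CLASSES), key=lambda c: votes[c])
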