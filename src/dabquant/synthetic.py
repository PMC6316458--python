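"""Synthetic TMA-core images with exact per-pixel ground truth.

Images are built by Beer-Lambert forward rendering: per-pixel stain
concentrations (hematoxylin + eosin over a blob-shaped tissue footprint,
DAB over a blob-shaped positive footprint inside the tissue) are mixed
through the stain basis into per-channel optical density, optionally
perturbed with additive Gaussian OD noise (multiplicative in transmitted
light, mimicking stain and scanner variation), and quantised to 8-bit RGB.

Footprints are carved from a smoothed random field by taking exactly the
requested number of highest-field pixels, so the realised area fractions
are exact pixel counts, recorded in the ground truth together with the
per-block scores derived by the same Allred bin rules the pipeline uses.

The three DAB levels map to OD {low: 0.9, medium: 1.35, high: 2.2},
calibrated so that a pure-DAB rendering at each level falls nearest the
low/medium/high seed centroid of the intensity K-means under the default
stain basis (re-tune if the basis is changed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import split_lengths
from .scoring import allred_score, proportion_score, risk_class
from .stains import StainBasis, od_to_rgb

#: DAB level -> optical density of the positive footprint.
DAB_LEVEL_OD = {"low": 0.9, "medium": 1.35, "high": 2.2}

#: DAB level -> true intensity score (1 low, 2 intermediate, 3 strong).
DAB_LEVEL_INTENSITY = {"low": 1, "medium": 2, "high": 3}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic core (all fractions are of pixel area)."""

    height: int = 256
    width: int = 256
    tissue_fraction: float = 0.8
    dab_fraction_of_tissue: float = 0.5
    dab_level: str = "high"
    h_od: float = 0.5
    e_od: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("synthetic cores must be at least 8x8 pixels")
        for name in ("tissue_fraction", "dab_fraction_of_tissue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dab_level not in DAB_LEVEL_OD:
            raise ValueError(f"dab_level must be one of {sorted(DAB_LEVEL_OD)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.h_od < 0 or self.e_od < 0:
            raise ValueError("stain ODs must be >= 0")


@dataclass
class GroundTruth:
    """Exact (pre-noise) truth for a synthetic core.

    Pixel masks plus per-block (grid of the standard 8x8 partition) realised
    positive fractions and the scores they imply under the Allred bin rules.
    """

    tissue_mask: np.ndarray
    positive_mask: np.ndarray
    dab_level: str
    block_fraction: np.ndarray = field(default=None)
    block_proportion: np.ndarray = field(default=None)
    block_intensity: np.ndarray = field(default=None)
    block_allred: np.ndarray = field(default=None)
    block_risk: tuple = field(default=None)


def forward_render(
    concentrations: np.ndarray,
    basis: StainBasis | None = None,
    background_intensity: int = 255,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render per-pixel (H, E, DAB) concentrations to an 8-bit RGB image.

    ``concentrations`` has shape (h, w, 3); the OD vector of a pixel is its
    concentration triple times the stain matrix.  Gaussian noise of standard
    deviation *noise_sd* is added per channel in OD space when requested.
    Exact inverse of stain separation up to 8-bit rounding for images inside
    the stain span.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 3 or conc.shape[2] != 3:
        raise ValueError("concentrations must have shape (h, w, 3)")
    if (conc < 0).any():
        raise ValueError("concentrations must be nonnegative")
    basis = basis or StainBasis()
    od = conc @ basis.matrix
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        od = od + rng.normal(0.0, noise_sd, od.shape)
    return od_to_rgb(np.clip(od, 0.0, None), background_intensity)


def _blob_field(shape: tuple[int, int], rng: np.random.Generator, scale: int = 8) -> np.ndarray:
    """Smooth random field whose upper level sets are blob-shaped regions."""
    h, w = shape
    coarse = rng.standard_normal((max(1, -(-h // scale)), max(1, -(-w // scale))))
    fine = np.kron(coarse, np.ones((scale, scale)))[:h, :w]
    # two box-blur passes to round the blob edges
    for _ in range(2):
        fine = (
            fine
            + np.roll(fine, 1, 0) + np.roll(fine, -1, 0)
            + np.roll(fine, 1, 1) + np.roll(fine, -1, 1)
        ) / 5.0
    # infinitesimal jitter guarantees unique ordering for exact-count cuts
    return fine + rng.uniform(0.0, 1e-9, fine.shape)


def _top_n_mask(fieldvals: np.ndarray, n: int, within: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask selecting exactly the *n* largest field values.

    When *within* is given, selection is restricted to (and counted inside)
    that mask.
    """
    mask = np.zeros(fieldvals.shape, dtype=bool)
    if n <= 0:
        return mask
    if within is None:
        flat_idx = np.argpartition(fieldvals.ravel(), -n)[-n:]
        mask.ravel()[flat_idx] = True
    else:
        pool = np.flatnonzero(within.ravel())
        if n > pool.size:
            raise ValueError("requested region larger than the available area")
        vals = fieldvals.ravel()[pool]
        keep = pool[np.argpartition(vals, -n)[-n:]]
        mask.ravel()[keep] = True
    return mask


def _block_truth(truth: GroundTruth, shape: tuple[int, int], grid_side: int = 8) -> None:
    """Fill the per-block score matrices from the pixel masks."""
    h, w = shape
    heights, widths = split_lengths(h, grid_side), split_lengths(w, grid_side)
    rs = np.concatenate([[0], np.cumsum(heights)])
    cs = np.concatenate([[0], np.cumsum(widths)])
    frac = np.zeros((grid_side, grid_side))
    prop = np.zeros((grid_side, grid_side), dtype=int)
    inten = np.zeros((grid_side, grid_side), dtype=int)
    allred = np.zeros((grid_side, grid_side), dtype=int)
    risk = []
    level_intensity = DAB_LEVEL_INTENSITY[truth.dab_level]
    for i in range(grid_side):
        risk_row = []
        for j in range(grid_side):
            t = truth.tissue_mask[rs[i] : rs[i + 1], cs[j] : cs[j + 1]]
            p = truth.positive_mask[rs[i] : rs[i + 1], cs[j] : cs[j + 1]]
            denom = int(np.count_nonzero(t | p))
            npos = int(np.count_nonzero(p))
            f = npos / denom if denom else 0.0
            frac[i, j] = f
            prop[i, j] = proportion_score(f)
            inten[i, j] = level_intensity if npos else 0
            allred[i, j] = allred_score(prop[i, j], inten[i, j])
            risk_row.append(risk_class(allred[i, j])[0])
        risk.append(tuple(risk_row))
    truth.block_fraction = frac
    truth.block_proportion = prop
    truth.block_intensity = inten
    truth.block_allred = allred
    truth.block_risk = tuple(risk)


def generate_core(
    cfg: SynthConfig, basis: StainBasis | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Generate a synthetic core image and its exact ground truth.

    Deterministic given ``cfg.seed``.  Tissue covers exactly
    ``round(tissue_fraction * area)`` pixels; the DAB-positive footprint
    covers exactly ``round(dab_fraction_of_tissue * tissue pixels)`` pixels
    inside the tissue, all at the configured DAB level.  Masks are recorded
    pre-noise; the per-block fractions stored in the truth are the realised
    pixel counts, not the requested targets.
    """
    basis = basis or StainBasis()
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    area = cfg.height * cfg.width

    n_tissue = int(round(cfg.tissue_fraction * area))
    tissue = _top_n_mask(_blob_field(shape, rng), n_tissue)
    n_dab = int(round(cfg.dab_fraction_of_tissue * n_tissue))
    positive = _top_n_mask(_blob_field(shape, rng), n_dab, within=tissue)

    conc = np.zeros((cfg.height, cfg.width, 3))
    conc[..., 0] = np.where(tissue, cfg.h_od, 0.0)
    conc[..., 1] = np.where(tissue, cfg.e_od, 0.0)
    conc[..., 2] = np.where(positive, DAB_LEVEL_OD[cfg.dab_level], 0.0)
    img = forward_render(conc, basis, noise_sd=cfg.noise_sd, rng=rng)

    truth = GroundTruth(tissue_mask=tissue, positive_mask=positive, dab_level=cfg.dab_level)
    _block_truth(truth, shape)
    return img, truth


def generate_block(
    size: int,
    positive_fraction: float,
    dab_level: str = "high",
    h_od: float = 0.5,
    e_od: float = 0.3,
    noise_sd: float = 0.02,
    seed: int = 0,
    basis: StainBasis | None = None,
) -> tuple[np.ndarray, dict]:
    """One fully-tissue block with an exact DAB-positive area fraction.

    The positive footprint is a blob of exactly
    ``round(positive_fraction * size**2)`` pixels, so the realised fraction
    (returned in the truth dict together with the implied scores) differs
    from the request only by pixel quantisation.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if dab_level not in DAB_LEVEL_OD:
        raise ValueError(f"dab_level must be one of {sorted(DAB_LEVEL_OD)}")
    basis = basis or StainBasis()
    rng = np.random.default_rng(seed)
    shape = (size, size)
    tissue = np.ones(shape, dtype=bool)
    n_pos = int(round(positive_fraction * size * size))
    positive = _top_n_mask(_blob_field(shape, rng, scale=max(2, size // 8)), n_pos)

    conc = np.zeros((size, size, 3))
    conc[..., 0] = h_od
    conc[..., 1] = e_od
    conc[..., 2] = np.where(positive, DAB_LEVEL_OD[dab_level], 0.0)
    img = forward_render(conc, basis, noise_sd=noise_sd, rng=rng)

    frac = n_pos / (size * size)
    p = proportion_score(frac)
    i = DAB_LEVEL_INTENSITY[dab_level] if n_pos else 0
    a = allred_score(p, i)
    truth = {
        "tissue_mask": tissue,
        "positive_mask": positive,
        "positive_fraction": frac,
        "proportion_score": p,
        "intensity_score": i,
        "allred_score": a,
        "risk_class": risk_class(a)[0],
    }
    return img, truth


def mask_to_rle(mask: np.ndarray) -> list[int]:
    """Row-major run-length encoding; runs alternate 0s/1s starting with 0s."""
    flat = np.asarray(mask, dtype=np.uint8).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:  # encode a leading zero-run of length 0
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_to_mask(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`mask_to_rle`."""
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in runs:
        if val:
            out[pos : pos + run] = True
        pos += run
        val = not val
    if pos != out.size:
        raise ValueError("run lengths do not match the mask size")
    return out.reshape(shape)
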