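"""Colour deconvolution of hematoxylin, eosin and DAB.

Brightfield stains attenuate light multiplicatively, so per-channel optical
density (OD) is additive across co-localised stains (Beer-Lambert).  Each
stain contributes along a characteristic unit vector in OD space; unmixing a
pixel is solving the 3x3 linear system mapping its OD vector onto the three
stain axes (Ruifrok-Johnston colour deconvolution).

OD convention for 8-bit images: ``OD_c = -log10((p_c + 1) / (bg + 1))`` with
background intensity ``bg = 255`` by default; the +1 offset keeps the log
finite at p = 0 and makes white exactly OD 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import as_rgb_image

# Published Ruifrok-Johnston OD vectors for H&E + DAB (unnormalised).
RUIFROK_H = (0.650, 0.704, 0.286)
RUIFROK_E = (0.072, 0.990, 0.105)
RUIFROK_DAB = (0.268, 0.570, 0.776)

_MAX_CONDITION = 1e8


class SingularBasisError(ValueError):
    """Raised when stain vectors are (near-)collinear and cannot be unmixed."""


@dataclass(frozen=True)
class StainBasis:
    """Unit OD vectors for hematoxylin, eosin and DAB.

    Vectors are L2-normalised at construction; the stacked 3x3 matrix must
    be invertible (otherwise the stain pair closest to collinear is named in
    the error).
    """

    h: tuple[float, float, float] = RUIFROK_H
    e: tuple[float, float, float] = RUIFROK_E
    dab: tuple[float, float, float] = RUIFROK_DAB

    def __post_init__(self):
        mat = np.array([self.h, self.e, self.dab], dtype=float)
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms == 0):
            raise SingularBasisError("a stain vector is all zeros")
        mat = mat / norms[:, None]
        object.__setattr__(self, "h", tuple(mat[0]))
        object.__setattr__(self, "e", tuple(mat[1]))
        object.__setattr__(self, "dab", tuple(mat[2]))
        if np.linalg.cond(mat) > _MAX_CONDITION:
            names = ("hematoxylin", "eosin", "DAB")
            # identify the most collinear pair for the error message
            worst, pair = -1.0, (names[0], names[1])
            for a in range(3):
                for b in range(a + 1, 3):
                    c = abs(float(mat[a] @ mat[b]))
                    if c > worst:
                        worst, pair = c, (names[a], names[b])
            raise SingularBasisError(
                f"stain basis is singular: {pair[0]} and {pair[1]} vectors are collinear"
            )

    @property
    def matrix(self) -> np.ndarray:
        """Row-stacked 3x3 stain matrix (rows: H, E, DAB; columns: R, G, B)."""
        return np.array([self.h, self.e, self.dab], dtype=float)

    def vector(self, stain: str) -> np.ndarray:
        return {"h": np.array(self.h), "e": np.array(self.e), "dab": np.array(self.dab)}[stain]


def rgb_to_od(img: np.ndarray, background_intensity: int = 255) -> np.ndarray:
    """Convert an RGB image to per-channel optical density (``(h, w, 3)`` floats)."""
    if not 1 <= background_intensity <= 255:
        raise ValueError("background_intensity must be in [1, 255]")
    img = as_rgb_image(img)
    return -np.log10((img.astype(float) + 1.0) / (background_intensity + 1.0))


def od_to_rgb(od: np.ndarray, background_intensity: int = 255) -> np.ndarray:
    """Invert :func:`rgb_to_od`: render an OD array back to 8-bit RGB."""
    od = np.asarray(od, dtype=float)
    vals = np.rint((background_intensity + 1.0) * np.power(10.0, -od) - 1.0)
    return np.clip(vals, 0, 255).astype(np.uint8)


def make_deconvolution_matrix(basis: StainBasis) -> np.ndarray:
    """Inverse of the row-normalised stain matrix.

    Right-multiplying a pixel's OD row vector by this matrix yields its
    (H, E, DAB) concentrations; a pure unit-norm stain OD vector maps to the
    corresponding unit coordinate vector.
    """
    return np.linalg.inv(basis.matrix)


@dataclass
class StainChannels:
    """Per-pixel stain concentration maps plus single-stain renderings.

    Concentrations are in OD units, clipped at zero.  Each ``*_rgb``
    rendering shows what the image would look like under that stain alone:
    ``od_to_rgb(concentration * basis_vector)``.
    """

    h_map: np.ndarray
    e_map: np.ndarray
    dab_map: np.ndarray
    h_rgb: np.ndarray = field(repr=False, default=None)
    e_rgb: np.ndarray = field(repr=False, default=None)
    dab_rgb: np.ndarray = field(repr=False, default=None)


def separate_stains(
    img: np.ndarray,
    basis: StainBasis | None = None,
    background_intensity: int = 255,
) -> StainChannels:
    """Unmix an RGB image into H, E and DAB concentration maps.

    Negative concentrations (pixels outside the stain span, e.g. noise) are
    clipped to zero before rendering.
    """
    basis = basis or StainBasis()
    od = rgb_to_od(img, background_intensity)
    deconv = make_deconvolution_matrix(basis)
    conc = np.clip(od @ deconv, 0.0, None)
    h_map, e_map, dab_map = conc[..., 0], conc[..., 1], conc[..., 2]
    render = lambda c, v: od_to_rgb(c[..., None] * basis.vector(v), background_intensity)
    return StainChannels(
        h_map=h_map,
        e_map=e_map,
        dab_map=dab_map,
        h_rgb=render(h_map, "h"),
        e_rgb=render(e_map, "e"),
        dab_rgb=render(dab_map, "dab"),
    )


def tissue_mask(channels: StainChannels, od_threshold: float = 0.15) -> np.ndarray:
    """Boolean tissue footprint: pixels where H + E concentration >= threshold.

    Counterstain (hematoxylin + eosin) density separates tissue from the
    bright background and inter-core gaps.
    """
    if od_threshold <= 0:
        raise ValueError("od_threshold must be > 0")
    return (channels.h_map + channels.e_map) >= od_threshold
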