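"""Reading, writing and block partitioning of TMA core images.

A tissue-microarray (TMA) core image is analysed as a fixed grid of
``grid_side x grid_side`` non-overlapping blocks (64 blocks for the default
grid side of 8).  Block sizes follow the most even partition of each image
dimension: when a dimension is not divisible by the grid side, the remainder
pixels are distributed one per block to the earliest grid rows/columns, so
any two block heights (or widths) differ by at most one pixel.

Images are held as ``uint8`` numpy arrays of shape ``(height, width, 3)`` in
RGB channel order and are never resized or recompressed before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


class ImageFormatError(ValueError):
    """Raised when a file does not decode to an 8-bit RGB image."""


def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    """Validate and return *arr* as an ``(h, w, 3)`` uint8 RGB image."""
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"expected an (h, w, 3) RGB array, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ImageFormatError(
                f"expected 8-bit channel values in [0, 255], got dtype {arr.dtype}"
            )
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit colour image (JPG/PNG/TIFF) into an RGB array.

    Channels are returned in RGB order regardless of on-disk order.
    Grayscale images are rejected: the pipeline needs three colour channels
    to unmix stains.  An alpha channel, if present, is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("1", "L", "I", "I;16", "F", "LA"):
                raise ImageFormatError(
                    f"{path}: image is grayscale ({im.mode}); a 3-channel RGB image is required"
                )
            im = im.convert("RGB")
            return np.asarray(im, dtype=np.uint8)
    except ImageFormatError:
        raise
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB array to *path*; format inferred from the suffix."""
    img = as_rgb_image(img)
    Image.fromarray(img, mode="RGB").save(Path(path))


def split_lengths(total: int, parts: int) -> list[int]:
    """Most even split of *total* into *parts* positive lengths, larger first.

    ``total = parts*q + r`` gives ``r`` parts of ``q+1`` followed by
    ``parts - r`` parts of ``q``.
    """
    if total < parts:
        raise ValueError(f"cannot split {total} pixels into {parts} non-empty parts")
    q, r = divmod(total, parts)
    return [q + 1] * r + [q] * (parts - r)


@dataclass(frozen=True)
class BlockGrid:
    """An 8x8 (by default) tiling of a core image into blocks.

    ``blocks[i][j]`` is the RGB sub-image of grid row *i*, column *j*;
    ``offsets[i][j]`` its 0-based ``(row, col)`` top-left corner.  Extents
    are half-open: block (i, j) covers rows ``[r0, r0+h)`` and columns
    ``[c0, c0+w)``.
    """

    source_height: int
    source_width: int
    blocks: tuple[tuple[np.ndarray, ...], ...]
    offsets: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def grid_side(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        """Yield ``(i, j, block)`` row-major."""
        for i, row in enumerate(self.blocks):
            for j, block in enumerate(row):
                yield i, j, block


def partition_blocks(img: np.ndarray, grid_side: int = 8) -> BlockGrid:
    """Partition *img* into a ``grid_side x grid_side`` block grid.

    Raises ``ValueError`` if either image dimension is smaller than
    *grid_side* (every block must be non-empty).
    """
    img = as_rgb_image(img)
    h, w = img.shape[:2]
    if h < grid_side or w < grid_side:
        raise ValueError(
            f"image {h}x{w} too small for a {grid_side}x{grid_side} block grid"
        )
    heights = split_lengths(h, grid_side)
    widths = split_lengths(w, grid_side)
    row_starts = np.concatenate([[0], np.cumsum(heights)])
    col_starts = np.concatenate([[0], np.cumsum(widths)])

    blocks = []
    offsets = []
    for i in range(grid_side):
        brow, orow = [], []
        r0, r1 = row_starts[i], row_starts[i + 1]
        for j in range(grid_side):
            c0, c1 = col_starts[j], col_starts[j + 1]
            brow.append(img[r0:r1, c0:c1].copy())
            orow.append((int(r0), int(c0)))
        blocks.append(tuple(brow))
        offsets.append(tuple(orow))
    return BlockGrid(h, w, tuple(blocks), tuple(offsets))


def stitch_blocks(grid: BlockGrid) -> np.ndarray:
    """Reassemble a block grid into a single core-sized image.

    Exact inverse of :func:`partition_blocks`: stitching an unmodified grid
    reproduces the source image bit for bit.  Raises ``ValueError`` when the
    block shapes and offsets do not tile the declared source extent.
    """
    out = np.empty((grid.source_height, grid.source_width, 3), dtype=np.uint8)
    covered = np.zeros((grid.source_height, grid.source_width), dtype=bool)
    for i, j, block in grid:
        r0, c0 = grid.offsets[i][j]
        bh, bw = block.shape[:2]
        if r0 + bh > grid.source_height or c0 + bw > grid.source_width:
            raise ValueError(f"block ({i},{j}) exceeds the source extent")
        if covered[r0 : r0 + bh, c0 : c0 + bw].any():
            raise ValueError(f"block ({i},{j}) overlaps a previously placed block")
        out[r0 : r0 + bh, c0 : c0 + bw] = as_rgb_image(block)
        covered[r0 : r0 + bh, c0 : c0 + bw] = True
    if not covered.all():
        raise ValueError("blocks do not cover the full source extent")
    return out
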