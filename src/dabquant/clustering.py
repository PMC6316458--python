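"""Fixed-seed K-means classification of DAB staining intensity.

Every pixel of a block is assigned to one of four clusters in RGB space:
k=1 high DAB intensity, k=2 medium, k=3 low, k=4 light regions (background
and unstained tissue).  The initial centroids are fixed domain-knowledge
seeds — dark brown, mid brown, light brown and white — so the procedure is
fully deterministic: Lloyd iterations (nearest-centroid assignment, member
mean update) run from the same four seeds on every block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import as_rgb_image

#: Fixed initial centroids, k = 1..4 (high, medium, low DAB, light region).
INITIAL_CENTROIDS = (
    (64.0, 32.0, 21.0),
    (105.0, 51.0, 27.0),
    (124.0, 87.0, 45.0),
    (255.0, 255.0, 255.0),
)

WHITE = np.array([255, 255, 255], dtype=np.uint8)


def initial_centroids() -> np.ndarray:
    """The four fixed seed centroids as a (4, 3) float array."""
    return np.array(INITIAL_CENTROIDS, dtype=float)


@dataclass
class ClusterState:
    """Result of clustering one block.

    ``labels`` has the block's shape with values in {1, 2, 3, 4};
    ``centroids`` is the final (4, 3) centroid matrix; ``iteration`` the
    number of assign/update rounds executed.
    """

    centroids: np.ndarray
    labels: np.ndarray
    iteration: int
    converged: bool


def assign_step(pixels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Assign each pixel (rows of an (N, 3) array) to its nearest centroid.

    Returns 1-based labels; Euclidean distance, ties broken toward the
    smallest k (argmin returns the first minimum).
    """
    pixels = np.asarray(pixels, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (4, 3):
        raise ValueError("exactly four RGB centroids are required")
    d2 = ((pixels[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1


def update_step(
    pixels: np.ndarray, labels: np.ndarray, previous_centroids: np.ndarray
) -> np.ndarray:
    """Recompute each centroid as the mean of its member pixels.

    A cluster with no members keeps its previous centroid, preserving the
    semantic anchor of each k.
    """
    pixels = np.asarray(pixels, dtype=float)
    labels = np.asarray(labels)
    new = np.array(previous_centroids, dtype=float, copy=True)
    for k in range(1, 5):
        members = pixels[labels == k]
        if len(members):
            new[k - 1] = members.mean(axis=0)
    return new


def within_cluster_ss(pixels: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Total within-cluster sum of squared RGB distances (the K-means objective)."""
    pixels = np.asarray(pixels, dtype=float)
    return float(((pixels - np.asarray(centroids, dtype=float)[labels - 1]) ** 2).sum())


def cluster_block(
    dab_rgb: np.ndarray,
    max_iter: int = 100,
    tol: float = 0.5,
    centroids: np.ndarray | None = None,
) -> ClusterState:
    """Cluster a block's pixels into the four DAB-intensity classes.

    Alternates assignment and update from the fixed seeds until the largest
    centroid displacement falls below *tol* (RGB units) or *max_iter* rounds
    have run.  Deterministic: no randomness anywhere.
    """
    img = as_rgb_image(dab_rgb)
    if img.size == 0:
        raise ValueError("cannot cluster an empty block")
    shape = img.shape[:2]
    pixels = img.reshape(-1, 3).astype(float)
    cents = initial_centroids() if centroids is None else np.array(centroids, dtype=float)
    if cents.shape != (4, 3):
        raise ValueError("exactly four RGB centroids are required")

    labels = assign_step(pixels, cents)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_cents = update_step(pixels, labels, cents)
        shift = float(np.linalg.norm(new_cents - cents, axis=1).max())
        cents = new_cents
        labels = assign_step(pixels, cents)
        if shift < tol:
            converged = True
            break
    return ClusterState(
        centroids=cents,
        labels=labels.reshape(shape),
        iteration=it,
        converged=converged,
    )


@dataclass
class ClassImages:
    """Four per-class renderings O1..O4 of a clustered block.

    ``images[k-1]`` keeps the source pixel value where the label equals k
    and is white elsewhere, so overlaying the non-white pixels of all four
    reconstructs every non-white source pixel.
    """

    images: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]


def class_images(state: ClusterState, source: np.ndarray) -> ClassImages:
    """Render the per-class output images from a cluster state."""
    source = as_rgb_image(source)
    if source.shape[:2] != state.labels.shape:
        raise ValueError(
            f"source shape {source.shape[:2]} does not match labels {state.labels.shape}"
        )
    out = []
    for k in range(1, 5):
        img = np.full_like(source, 255)
        mask = state.labels == k
        img[mask] = source[mask]
        out.append(img)
    return ClassImages(images=tuple(out))
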