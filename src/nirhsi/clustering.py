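"""Unsupervised structure analysis and the pipeline's visual products.

K-means scans over k = 2..10 with silhouette scores, run-to-run
stability as mean pairwise adjusted Rand index (ARI), agreement between
sample-level clusters and tissue labels, and three image products:
false-color band composites, pixel-level cluster maps (k = 5 by default)
painted from patch-embedding clusters, and rendering of the classifier's
attention maps.

Cluster maps use nearest-neighbor upsampling (no smoothing) so cluster
boundaries stay faithful to the patch grid; silhouette on pixel-level
clusterings is computed on a seeded uniform subsample of at most 5000
patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .classifier import _upsample_nearest
from .cube_io import HyperCube
from .errors import ConfigError, ShapeMismatchError
from .features import EncoderModel, encode_patches, extract_patches

__all__ = [
    "ClusterResult",
    "kmeans_scan",
    "adjusted_rand_index",
    "cluster_stability",
    "pixel_cluster_map",
    "false_color",
    "save_image",
]

SILHOUETTE_SUBSAMPLE = 5000


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    inertia: float
    silhouette: float
    seed: int

    def __post_init__(self) -> None:
        used = np.unique(self.assignments)
        if used.min() < 0 or used.max() >= self.k:
            raise ConfigError("assignments must use ids in 0..k-1")


def _fit_kmeans(X: np.ndarray, k: int, n_init: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, init="k-means++", random_state=seed).fit(X)


def _safe_silhouette(X: np.ndarray, labels: np.ndarray, seed: int) -> float:
    if np.unique(labels).size < 2:
        return float("nan")
    n = X.shape[0]
    if n > SILHOUETTE_SUBSAMPLE:
        idx = np.random.default_rng(seed).choice(n, SILHOUETTE_SUBSAMPLE, replace=False)
        X, labels = X[idx], labels[idx]
        if np.unique(labels).size < 2:
            return float("nan")
    return float(silhouette_score(X, labels))


def kmeans_scan(
    items: np.ndarray,
    k_range: range | list[int] = range(2, 11),
    n_init: int = 10,
    seed: int = 0,
) -> list[ClusterResult]:
    """K-means for each k, keeping the best of ``n_init`` restarts."""
    X = np.asarray(items, dtype=np.float64)
    ks = list(k_range)
    if max(ks) > X.shape[0]:
        raise ConfigError(f"k={max(ks)} exceeds item count {X.shape[0]}")
    results = []
    for k in ks:
        km = _fit_kmeans(X, k, n_init, seed)
        sil = _safe_silhouette(X, km.labels_, seed) if k >= 2 else float("nan")
        results.append(
            ClusterResult(
                k=k,
                assignments=km.labels_.astype(int),
                inertia=float(km.inertia_),
                silhouette=sil,
                seed=seed,
            )
        )
    return results


def adjusted_rand_index(assignment_a, assignment_b) -> float:
    """Permutation-model-corrected Rand index; 1 for identical partitions."""
    a = np.asarray(assignment_a)
    b = np.asarray(assignment_b)
    if a.shape != b.shape:
        raise ShapeMismatchError("partitions differ in length")
    return float(adjusted_rand_score(a, b))


def cluster_stability(
    items: np.ndarray, k: int, n_runs: int = 20, n_init: int = 10, seed: int = 0
) -> tuple[float, list[float]]:
    """Run-to-run K-means consistency: mean pairwise ARI over n_runs seeds."""
    if n_runs < 2:
        raise ConfigError("n_runs must be >= 2")
    X = np.asarray(items, dtype=np.float64)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n_runs)]
    labelings = [_fit_kmeans(X, k, n_init, s).labels_ for s in seeds]
    pairs = [
        adjusted_rand_index(labelings[i], labelings[j])
        for i in range(n_runs)
        for j in range(i + 1, n_runs)
    ]
    return float(np.mean(pairs)), pairs


def pixel_cluster_map(
    cube: HyperCube,
    model: EncoderModel,
    k: int = 5,
    seed: int = 0,
    patch_size: int = 5,
    stride: int = 2,
    n_init: int = 10,
) -> np.ndarray:
    """Cluster the cube's patch embeddings and paint a spatial label image.

    Each patch-origin cell receives its cluster id (0..k-1); the map is
    upsampled nearest-neighbor to the cube's spatial size. The no-patch
    margin is covered by the nearest patch cell, so the returned image is
    a full (H, W) int map.
    """
    patches = extract_patches(cube, patch_size=patch_size, stride=stride)
    if k > len(patches):
        raise ConfigError(f"k={k} exceeds patch count {len(patches)}")
    emb = encode_patches(model, patches)
    km = _fit_kmeans(emb.vectors.astype(np.float64), k, n_init, seed)
    rows = np.unique(emb.origins[:, 0])
    cols = np.unique(emb.origins[:, 1])
    grid = np.zeros((len(rows), len(cols)), dtype=float)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for (r, c), lab in zip(emb.origins, km.labels_):
        grid[ri[r], ci[c]] = lab
    full = _upsample_nearest(grid, emb.origins, cube.data.shape[:2])
    return full.astype(int)


def false_color(
    cube: HyperCube,
    band_indices: tuple[int, int, int] = (2, 0, 1),
    weights: tuple[float, float, float] = (1.0, 0.8, 1.0),
) -> np.ndarray:
    """Weighted false-color composite of three bands, values in [0, 1].

    Channel c is ``weights[c]`` times the min-max-normalized band
    ``band_indices[c]``; defaults follow the standard rendering recipe
    (bands 2, 0, 1 weighted 1.0, 0.8, 1.0). A constant band renders at
    its full weight level.
    """
    B = cube.n_bands
    for b in band_indices:
        if not 0 <= b < B:
            raise IndexError(f"band index {b} out of range 0..{B - 1}")
    H, W, _ = cube.data.shape
    img = np.zeros((H, W, 3))
    for c, (b, w) in enumerate(zip(band_indices, weights)):
        band = cube.data[:, :, b].astype(np.float64)
        lo, hi = band.min(), band.max()
        norm = np.ones_like(band) if hi == lo else (band - lo) / (hi - lo)
        img[:, :, c] = w * norm
    return img


def save_image(img: np.ndarray, path) -> None:
    """Write a [0,1] float image (or an int label map) to disk.

    Float images go out as 8-bit PNG; integer label maps as integer TIFF.
    """
    from pathlib import Path

    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if np.issubdtype(img.dtype, np.integer):
        tifffile.imwrite(path, img.astype(np.int32))
    else:
        iio.imwrite(path, (np.clip(img, 0, 1) * 255).astype(np.uint8))
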