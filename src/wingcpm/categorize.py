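"""Wing extraction and colour categorization.

Converts an RGB wing photograph into a :class:`~wingcpm.io.ColourPattern` over
the three colour classes.  The pattern is what matters, not colorimetry:
pixels are assigned to the nearest class centroid in RGB space, with an
"unresolved" QC flag replacing interactive checking for pixels that sit far
from every centroid (wing damage, dust, compression artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import graph as skgraph
from skimage import measure
from skimage.transform import downscale_local_mean
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import CLASSES, CLASS_RGB, ColourPattern


@dataclass
class CategorizationConfig:
    """Parameters of the simplification and categorization stage.

    merge_threshold doubles as the region-merging colour distance and the
    unresolved-pixel flagging radius around class centroids (RGB units).
    """

    downscale_factor: int = 1
    merge_threshold: float = 60.0
    class_centroids: dict = field(
        default_factory=lambda: {c: CLASS_RGB[c] for c in CLASSES if c != "background"}
    )
    min_region_px: int = 0
    background_rgb: tuple[int, int, int] = CLASS_RGB["background"]
    background_tol: float = 60.0

    def __post_init__(self) -> None:
        if self.downscale_factor < 1:
            raise ValueError("downscale_factor must be >= 1")
        if self.merge_threshold < 0:
            raise ValueError("merge_threshold must be >= 0")
        cents = [tuple(v) for v in self.class_centroids.values()]
        if len(set(cents)) != len(cents):
            raise ValueError("class centroids must be pairwise distinct")


def extract_outline(
    image: np.ndarray,
    background_rgb: tuple[int, int, int] = CLASS_RGB["background"],
    background_tol: float = 60.0,
) -> np.ndarray:
    """Extract the binary wing mask: largest connected non-background component.

    The background is assumed distinguishable from the wing (standardized
    imaging); small off-wing specks are discarded, interior holes filled.
    """
    image = np.asarray(image, dtype=float)
    dist = np.linalg.norm(image - np.asarray(background_rgb, dtype=float), axis=-1)
    fg = dist > background_tol
    if not fg.any():
        raise ValueError("no wing detected: image is entirely background")
    labels = measure.label(fg, connectivity=1)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    return ndimage.binary_fill_holes(mask)


def simplify(image: np.ndarray, config: CategorizationConfig) -> np.ndarray:
    """Simplify an image by size reduction and region merging.

    Downscales by block averaging, then merges adjacent regions whose mean RGB
    distance falls below ``merge_threshold`` (region adjacency graph,
    hierarchical merging) and absorbs regions smaller than ``min_region_px``
    into the neighbour with the nearest mean colour.  With factor 1 and
    threshold 0 this is the identity.
    """
    img = np.asarray(image, dtype=float)
    f = config.downscale_factor
    if f > 1:
        h, w = (img.shape[0] // f) * f, (img.shape[1] // f) * f
        img = downscale_local_mean(img[:h, :w], (f, f, 1))
    if config.merge_threshold <= 0 and config.min_region_px <= 0:
        return img.astype(np.uint8) if image.dtype == np.uint8 else img

    labels = np.arange(img.shape[0] * img.shape[1]).reshape(img.shape[:2])
    if config.merge_threshold > 0:
        rag = skgraph.rag_mean_color(img, labels, connectivity=1)
        labels = skgraph.merge_hierarchical(
            labels, rag, thresh=config.merge_threshold, rag_copy=False,
            in_place_merge=True,
            merge_func=_merge_mean_color, weight_func=_weight_mean_color,
        )
    out = _paint_region_means(img, labels)
    if config.min_region_px > 0:
        labels = _absorb_small_regions(out, labels, config.min_region_px)
        out = _paint_region_means(img, labels)
    return out.astype(np.uint8) if image.dtype == np.uint8 else out


def _weight_mean_color(graph, src, dst, n):
    diff = graph.nodes[dst]["mean color"] - graph.nodes[n]["mean color"]
    return {"weight": float(np.linalg.norm(diff))}


def _merge_mean_color(graph, src, dst):
    graph.nodes[dst]["total color"] += graph.nodes[src]["total color"]
    graph.nodes[dst]["pixel count"] += graph.nodes[src]["pixel count"]
    graph.nodes[dst]["mean color"] = (
        graph.nodes[dst]["total color"] / graph.nodes[dst]["pixel count"]
    )


def _paint_region_means(img: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(img, dtype=float)
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(sorted_labels) != 0, True])
    pix = img.reshape(-1, img.shape[2])
    out_flat = out.reshape(-1, img.shape[2])
    for i in range(len(bounds) - 1):
        sel = order[bounds[i]:bounds[i + 1]]
        out_flat[sel] = pix[sel].mean(axis=0)
    return out


def _absorb_small_regions(img: np.ndarray, labels: np.ndarray, min_px: int) -> np.ndarray:
    labels = measure.label(labels + 1, connectivity=1)  # 0 would read as background
    while True:
        sizes = np.bincount(labels.ravel())
        small = [lab for lab in range(1, len(sizes)) if 0 < sizes[lab] < min_px]
        if not small:
            return labels
        changed = False
        for lab in small:
            sel = labels == lab
            ring = ndimage.binary_dilation(sel) & ~sel
            neigh = np.unique(labels[ring])
            neigh = neigh[neigh != lab]
            if len(neigh) == 0:
                continue
            mine = img[sel].reshape(-1, img.shape[2]).mean(axis=0)
            best = min(
                neigh,
                key=lambda nb: float(
                    np.linalg.norm(img[labels == nb].reshape(-1, img.shape[2]).mean(axis=0) - mine)
                ),
            )
            labels[sel] = best
            changed = True
        if not changed:
            return labels


def categorize(
    image: np.ndarray,
    mask: np.ndarray,
    config: CategorizationConfig | None = None,
) -> tuple[ColourPattern, dict]:
    """Assign every masked pixel to the nearest colour-class centroid.

    Pixels farther than ``merge_threshold`` from every centroid, or exactly
    tied between two centroids, are flagged unresolved (assigned anyway, to the
    nearest / earliest class) and counted in the QC dict — the deterministic
    stand-in for interactive correction of imputation errors.
    """
    config = config or CategorizationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty wing mask")
    colour_names = [c for c in CLASSES if c in config.class_centroids]
    cents = np.array([config.class_centroids[c] for c in colour_names], dtype=float)
    codes = np.array([CLASSES.index(c) for c in colour_names], dtype=np.int16)

    pix = np.asarray(image, dtype=float)[mask]
    d2 = ((pix[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)  # argmin takes the first (earlier class) on ties
    dmin = np.sqrt(d2[np.arange(len(pix)), nearest])
    part = np.partition(np.sqrt(d2), 1, axis=1)
    tied = np.isclose(part[:, 0], part[:, 1])
    unresolved = (dmin > config.merge_threshold) | tied

    grid = np.zeros(mask.shape, dtype=np.int16)
    grid[mask] = codes[nearest]
    qc = {
        "n_masked": int(mask.sum()),
        "n_unresolved": int(unresolved.sum()),
        "unresolved_fraction": float(unresolved.sum() / mask.sum()),
    }
    return ColourPattern(grid=grid, space="native"), qc


def categorize_image(
    image: np.ndarray, config: CategorizationConfig | None = None
) -> tuple[ColourPattern, dict]:
    """Convenience: extract the outline, then categorize (simplify if configured)."""
    config = config or CategorizationConfig()
    mask = extract_outline(image, config.background_rgb, config.background_tol)
    img = image
    if config.downscale_factor > 1:
        img = simplify(image, config)
        f = config.downscale_factor
        mask = mask[: (mask.shape[0] // f) * f, : (mask.shape[1] // f) * f]
        mask = mask.reshape(mask.shape[0] // f, f, mask.shape[1] // f, f).mean(axis=(1, 3)) > 0.5
    return categorize(img, mask, config)


def categorize_unsupervised(
    image: np.ndarray,
    mask: np.ndarray,
    k_range: tuple[int, int] = (2, 5),
    random_state: int = 0,
) -> tuple[np.ndarray, int]:
    """Unsupervised alternative: k-means over wing pixels, k by silhouette.

    Mirrors categorization "without constraining the number of colours".
    Returns integer cluster labels on the mask (0 = background) and the chosen
    k; clusters are not identified with named colour classes.
    """
    pix = np.asarray(image, dtype=float)[np.asarray(mask, bool)]
    if len(pix) < max(k_range) + 1:
        raise ValueError("too few wing pixels for unsupervised categorization")
    sub = pix[:: max(1, len(pix) // 5000)]
    best_k, best_score = None, -np.inf
    for k in range(k_range[0], k_range[1] + 1):
        km = KMeans(n_clusters=k, n_init=4, random_state=random_state).fit(sub)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(sub, km.labels_)
        if score > best_score:
            best_k, best_score = k, score
    km = KMeans(n_clusters=best_k, n_init=4, random_state=random_state).fit(pix)
    labels = np.zeros(np.asarray(mask).shape, dtype=np.int16)
    labels[np.asarray(mask, bool)] = km.labels_ + 1
    return labels, best_k
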