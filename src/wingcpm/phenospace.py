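"""Pixel-as-trait phenotype space: trait matrix, PCA summary, genotype
distances, modal patterns, and genotype classification checks.

Every model-space pixel that is non-background in all aligned wings is a
trait; colour classes are one-hot encoded so that Euclidean distance between
two specimens counts the pixels at which they disagree (times √2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import CLASSES, ColourPattern


@dataclass
class TraitMatrix:
    """Specimens x (common pixels x colour-class indicators)."""

    X: np.ndarray                 # (n_specimens, n_pixels * n_colours)
    pixel_index: np.ndarray       # flat model-space indices of retained pixels
    resolution: tuple[int, int]
    classes: tuple[str, ...]
    retained_fraction: float      # retained pixels / union of wing pixels

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_index)


def build_trait_matrix(aligned_patterns) -> TraitMatrix:
    """One-hot trait matrix over pixels common (non-background) to all wings."""
    grids = [p.grid if isinstance(p, ColourPattern) else np.asarray(p) for p in aligned_patterns]
    if not grids:
        raise ValueError("no patterns given")
    shape = grids[0].shape
    for p in aligned_patterns:
        if isinstance(p, ColourPattern) and p.space != "model":
            raise ValueError("trait matrix requires patterns in model space")
        if (p.grid if isinstance(p, ColourPattern) else np.asarray(p)).shape != shape:
            raise ValueError("all patterns must share one model-space resolution")
    stack = np.stack(grids)                       # (n, H, W)
    common = np.all(stack > 0, axis=0)
    union = np.any(stack > 0, axis=0)
    if not common.any():
        raise ValueError(
            "empty common-pixel set: no pixel is wing in every specimen "
            "(alignment failure signal)"
        )
    flat_idx = np.flatnonzero(common.ravel())
    vals = stack.reshape(len(grids), -1)[:, flat_idx]   # codes 1..K
    n_col = len(CLASSES) - 1
    onehot = (vals[:, :, None] == (np.arange(n_col) + 1)[None, None, :])
    X = onehot.reshape(len(grids), -1).astype(np.float64)
    return TraitMatrix(
        X=X, pixel_index=flat_idx, resolution=shape, classes=CLASSES,
        retained_fraction=float(common.sum() / union.sum()),
    )


def retained_components(variance_fractions, min_var_fraction: float = 0.01) -> int:
    """Number of leading components whose variance fraction exceeds the threshold."""
    vf = np.asarray(variance_fractions, dtype=float)
    return int(np.sum(vf > min_var_fraction))


@dataclass
class PCASummary:
    components: np.ndarray        # (n_retained, n_traits)
    scores: np.ndarray            # (n_specimens, n_retained)
    variance_fractions: np.ndarray  # all components
    n_retained: int

    def full_scores(self) -> np.ndarray:
        return self.scores


def pca_summary(matrix, min_var_fraction: float = 0.01) -> PCASummary:
    """Centred PCA keeping exactly the components above the variance threshold."""
    X = matrix.X if isinstance(matrix, TraitMatrix) else np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA summary needs at least 3 specimens")
    if np.allclose(X, X[0]):
        raise ValueError("no variance: all specimens identical")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    vf = pca.explained_variance_ratio_
    k = retained_components(vf, min_var_fraction)
    k = max(k, 1)
    return PCASummary(
        components=pca.components_[:k], scores=scores[:, :k],
        variance_fractions=vf, n_retained=k,
    )


def genotype_distance(scores: np.ndarray, labels, g_a, g_b) -> float:
    """Euclidean distance between genotype centroids in retained-component space."""
    labels = list(labels)
    for g in (g_a, g_b):
        if g not in labels:
            raise ValueError(f"unknown genotype label {g!r}")
    sel_a = np.array([lab == g_a for lab in labels])
    sel_b = np.array([lab == g_b for lab in labels])
    ca = np.asarray(scores)[sel_a].mean(axis=0)
    cb = np.asarray(scores)[sel_b].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


@dataclass
class ModalPattern:
    """Per-genotype modal (most frequent) colour class at each pixel."""

    genotype: tuple
    pattern: ColourPattern
    support: np.ndarray           # per-pixel count of non-background observations
    n: int
    tie_mask: np.ndarray

    @property
    def grid(self) -> np.ndarray:
        return self.pattern.grid


def modal_pattern(aligned_patterns, genotype=None) -> ModalPattern:
    """Per-pixel mode over specimens of one genotype.

    Background is excluded from the vote wherever any specimen shows colour;
    ties go to the class declared earlier and are flagged in ``tie_mask``.
    Invariant to specimen order.
    """
    grids = [p.grid if isinstance(p, ColourPattern) else np.asarray(p) for p in aligned_patterns]
    if len(grids) < 2:
        raise ValueError("modal pattern requires at least 2 specimens")
    stack = np.stack(grids)
    k = len(CLASSES)
    counts = (stack[:, None] == np.arange(k)[None, :, None, None]).sum(axis=0)  # (K, H, W)
    colour_counts = counts[1:]
    any_colour = colour_counts.sum(axis=0) > 0
    mode_colour = colour_counts.argmax(axis=0) + 1
    grid = np.where(any_colour, mode_colour, 0).astype(np.int16)
    top = np.sort(colour_counts, axis=0)[::-1]
    tie_mask = any_colour & (top[0] == top[1]) & (top[0] > 0)
    return ModalPattern(
        genotype=genotype,
        pattern=ColourPattern(grid=grid, space="model"),
        support=colour_counts.sum(axis=0),
        n=len(grids),
        tie_mask=tie_mask,
    )


def crossvalidate_genotypes(scores: np.ndarray, labels, k: int) -> float:
    """Leave-one-out accuracy of a linear discriminant classifier on the first
    k retained components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if k > scores.shape[1]:
        raise ValueError(f"k={k} exceeds the {scores.shape[1]} retained components")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every genotype class needs at least 2 members")
    X = scores[:, :k]
    correct = 0
    for i in range(len(X)):
        train = np.ones(len(X), dtype=bool)
        train[i] = False
        if len(np.unique(labels[train])) < 2:
            continue
        try:
            clf = LinearDiscriminantAnalysis(solver="svd")
            clf.fit(X[train], labels[train])
        except np.linalg.LinAlgError:  # singular scatter: ridge-regularized fallback
            warnings.warn("singular within-class scatter; using shrinkage LDA", stacklevel=2)
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.05)
            clf.fit(X[train], labels[train])
        correct += int(clf.predict(X[i:i + 1])[0] == labels[i])
    return correct / len(X)


def lda_trait(X_aa: np.ndarray, X_bb: np.ndarray, X_other: np.ndarray) -> np.ndarray:
    """Alternative trait estimate: position along the discriminant axis between
    the two homozygote groups, scaled so their means map to 1 (aa) and 0 (bb)."""
    X = np.vstack([X_aa, X_bb])
    y = np.array([1] * len(X_aa) + [0] * len(X_bb))
    clf = LinearDiscriminantAnalysis(solver="svd", n_components=1)
    clf.fit(X, y)
    proj = clf.transform(np.vstack([X_aa, X_bb, X_other]))[:, 0]
    m_aa = proj[: len(X_aa)].mean()
    m_bb = proj[len(X_aa): len(X_aa) + len(X_bb)].mean()
    if np.isclose(m_aa, m_bb):
        raise ValueError("homozygote groups indistinguishable on the LDA axis")
    return (proj[len(X_aa) + len(X_bb):] - m_bb) / (m_aa - m_bb)
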