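"""Pattern-based alignment of categorized wings into a common model space.

All wings of one type are registered to an average wing model — a per-pixel
stack of colour-class frequencies — which is rebuilt from the registered wings
and refined recursively.  The fixed point defines pixel-level positional
homology across specimens: after convergence, a pixel index means "the same
place on the wing" for every individual.

The similarity metric is categorical template matching: the score of a
transform is the mean, over supported model pixels, of the model frequency of
the class the transformed wing shows there.  It is 1 exactly when the wing
reproduces a consensus model, and it is maximized by deterministic coarse grid
search plus pattern-search refinement (no stochastic optimizer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import CLASSES, ColourPattern
from .transforms import SimilarityTransform


def _grid_of(pattern) -> np.ndarray:
    if isinstance(pattern, ColourPattern):
        return pattern.grid
    return np.asarray(pattern, dtype=np.int16)


# ---------------------------------------------------------------------------
# Wing model
# ---------------------------------------------------------------------------

@dataclass
class WingModel:
    """Per-pixel colour-class frequency raster used as the alignment template.

    freq has shape (K, H, W) over all classes including background; support
    counts the wings contributing at each pixel.  At every supported pixel the
    class frequencies sum to 1.
    """

    freq: np.ndarray
    support: np.ndarray
    iteration: int = 0
    classes: tuple[str, ...] = CLASSES

    @classmethod
    def from_patterns(
        cls,
        patterns,
        transforms=None,
        iteration: int = 0,
        shape: tuple[int, int] | None = None,
    ) -> "WingModel":
        grids = [_grid_of(p) for p in patterns]
        if len(grids) == 0:
            raise ValueError("cannot build a model from zero wings")
        shape = shape or grids[0].shape
        k = len(CLASSES)
        counts = np.zeros((k, *shape), dtype=np.float64)
        support = np.zeros(shape, dtype=np.int32)
        transforms = transforms or [SimilarityTransform()] * len(grids)
        for g, tf in zip(grids, transforms):
            warped = tf.warp_grid(g, fill=-1, shape_out=shape)
            valid = warped >= 0
            support += valid
            w = np.where(valid, warped, 0)
            for code in range(k):
                counts[code][valid & (w == code)] += 1.0
        freq = np.zeros_like(counts)
        np.divide(counts, support[None], out=freq, where=support[None] > 0)
        return cls(freq=freq.astype(np.float32), support=support, iteration=iteration)

    @property
    def shape(self) -> tuple[int, int]:
        return self.support.shape

    def consensus(self) -> ColourPattern:
        """Modal class per supported pixel (ties to the earlier class)."""
        grid = self.freq.argmax(axis=0).astype(np.int16)
        grid[self.support == 0] = 0
        return ColourPattern(grid=grid, space="model")

    def check_normalized(self, atol: float = 1e-9) -> bool:
        total = self.freq.sum(axis=0)
        sup = self.support > 0
        return bool(np.allclose(total[sup], 1.0, atol=atol))


# ---------------------------------------------------------------------------
# Similarity scoring
# ---------------------------------------------------------------------------

class _Scorer:
    """Pre-extracted supported model pixels for fast repeated scoring."""

    def __init__(self, model: WingModel, max_points: int | None = None):
        rr, cc = np.nonzero(model.support > 0)
        if len(rr) == 0:
            raise ValueError("model support is empty")
        if max_points is not None and len(rr) > max_points:
            idx = np.linspace(0, len(rr) - 1, max_points).astype(int)
            rr, cc = rr[idx], cc[idx]
        self.xy = np.stack([cc, rr], axis=1).astype(float)  # (n, 2) as (x, y)
        self.fflat = model.freq.reshape(model.freq.shape[0], -1)[
            :, rr * model.shape[1] + cc
        ].ravel()  # (K*n,)
        self.n = len(rr)
        self.shape = model.shape

    def score_coords(self, grid: np.ndarray, src_xy: np.ndarray) -> float:
        cols = np.rint(src_xy[:, 0]).astype(np.intp)
        rows = np.rint(src_xy[:, 1]).astype(np.intp)
        inb = (rows >= 0) & (rows < grid.shape[0]) & (cols >= 0) & (cols < grid.shape[1])
        cls = np.zeros(self.n, dtype=np.intp)
        cls[inb] = grid[rows[inb], cols[inb]]
        return float(self.fflat[cls * self.n + np.arange(self.n)].mean())

    def score_transform(self, grid: np.ndarray, tf: SimilarityTransform) -> float:
        src = tf.inverse().apply_points(self.xy, self.shape)
        return self.score_coords(grid, src)


def similarity_score(pattern, model: WingModel, transform: SimilarityTransform) -> float:
    """Mean model frequency of the class the transformed wing shows, in [0, 1]."""
    return _Scorer(model).score_transform(_grid_of(pattern), transform)


class _SoftScorer:
    """Continuous surrogate of the categorical score, used for refinement only.

    The pattern's class-indicator fields are lightly smoothed and sampled
    bilinearly, making the objective differentiable in the transform
    parameters so pattern search can localize the optimum to sub-pixel /
    sub-degree precision (the discrete score is piecewise constant at that
    scale).
    """

    def __init__(self, model: WingModel, grid: np.ndarray,
                 max_points: int | None = None, sigma: float = 1.0):
        from scipy import ndimage

        rr, cc = np.nonzero(model.support > 0)
        if max_points is not None and len(rr) > max_points:
            idx = np.linspace(0, len(rr) - 1, max_points).astype(int)
            rr, cc = rr[idx], cc[idx]
        self.xy = np.stack([cc, rr], axis=1).astype(float)
        self.F = model.freq.reshape(model.freq.shape[0], -1)[
            :, rr * model.shape[1] + cc
        ]  # (K, n)
        self.shape = model.shape
        self.k = model.freq.shape[0]
        self.channels = np.stack([
            ndimage.gaussian_filter((grid == c).astype(np.float32), sigma)
            for c in range(self.k)
        ])
        self._ndimage = ndimage

    def score_transform(self, grid_unused, tf: SimilarityTransform) -> float:
        src = tf.inverse().apply_points(self.xy, self.shape)
        coords = np.stack([src[:, 1], src[:, 0]])
        total = np.zeros(len(src))
        for c in range(self.k):
            v = self._ndimage.map_coordinates(
                self.channels[c], coords, order=1, mode="constant",
                cval=1.0 if c == 0 else 0.0,
            )
            total += self.F[c] * v
        return float(total.mean())


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpec:
    """Deterministic search strategy: coarse grid then shrinking pattern search."""

    t_range: float = 16.0
    t_step: float = 4.0
    theta_range: float = 16.0
    theta_step: float = 4.0
    s_range: float = 0.12
    s_step: float = 0.04
    refine_min_t: float = 0.02
    refine_min_theta: float = 0.02
    refine_min_s: float = 0.0005
    coarse_points: int = 3000
    refine_points: int = 10000

    def __post_init__(self) -> None:
        if self.t_step <= 0 or self.theta_step <= 0 or self.s_step <= 0:
            raise ValueError("search grid steps must be positive (empty grid)")

    def axis(self, rng: float, step: float) -> np.ndarray:
        n = int(np.floor(rng / step + 1e-9))
        return np.arange(-n, n + 1) * step

    def shrunk(self, factor: float = 0.5) -> "SearchSpec":
        return replace(
            self,
            t_range=max(self.t_range * factor, self.t_step),
            theta_range=max(self.theta_range * factor, self.theta_step),
            s_range=max(self.s_range * factor, self.s_step),
        )


def register_to_model(
    pattern,
    model: WingModel,
    search: SearchSpec | None = None,
    init: SimilarityTransform | None = None,
) -> SimilarityTransform:
    """Find the similarity transform maximizing the categorical match score.

    The search is over perturbations composed with ``init`` (identity by
    default): exhaustive coarse grid over translation, rotation and scale,
    then coordinate-wise pattern search with halving steps.  Deterministic;
    score ties are broken toward the smallest-magnitude perturbation.
    """
    search = search or SearchSpec()
    init = init or SimilarityTransform()
    grid = _grid_of(pattern)

    coarse = _Scorer(model, max_points=search.coarse_points)
    txs = search.axis(search.t_range, search.t_step)
    thetas = search.axis(search.theta_range, search.theta_step)
    ss = 1.0 + search.axis(search.s_range, search.s_step)

    c = np.array([(coarse.shape[1] - 1) / 2.0, (coarse.shape[0] - 1) / 2.0])
    q = coarse.xy
    cands: list[tuple[float, float, tuple]] = []  # (score, norm, delta params)
    inv0 = init.inverse()
    for th in thetas:
        for s in ss:
            th_abs = th + init.theta
            s_abs = s * init.s
            a = np.deg2rad(-th_abs)
            rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            base = (q - c) @ (rot.T / s_abs) + c
            ad = np.deg2rad(th)
            rot_d = np.array([[np.cos(ad), -np.sin(ad)], [np.sin(ad), np.cos(ad)]])
            t0 = s * rot_d @ np.array([init.tx, init.ty])
            for tx in txs:
                for ty in txs:
                    t_abs = t0 + np.array([tx, ty])
                    off = -(rot @ t_abs) / s_abs
                    score = coarse.score_coords(grid, base + off)
                    norm = abs(tx) + abs(ty) + abs(th) + 100 * abs(s - 1.0)
                    cands.append((score, norm, (tx, ty, th, s)))
    best_score = max(cand[0] for cand in cands)
    near = [cand for cand in cands if cand[0] >= best_score - 1e-12]
    _, _, (tx, ty, th, s) = min(near, key=lambda cand: cand[1])
    delta = np.array([tx, ty, th, s - 1.0])

    fine = _SoftScorer(model, grid, max_points=search.refine_points)

    def full_tf(d) -> SimilarityTransform:
        return SimilarityTransform(d[0], d[1], d[2], 1.0 + d[3]).compose(init)

    current = fine.score_transform(grid, full_tf(delta))
    steps = np.array([search.t_step / 2, search.t_step / 2,
                      search.theta_step / 2, search.s_step / 2])
    mins = np.array([search.refine_min_t, search.refine_min_t,
                     search.refine_min_theta, search.refine_min_s])
    while np.any(steps >= mins):
        improved = True
        moves = 0
        while improved and moves < 60:
            improved = False
            for i in range(4):
                if steps[i] < mins[i] / 2:
                    continue
                for sign in (1.0, -1.0):
                    trial = delta.copy()
                    trial[i] += sign * steps[i]
                    if trial[3] <= -0.9:
                        continue
                    sc = fine.score_transform(grid, full_tf(trial))
                    if sc > current + 1e-12:
                        delta, current = trial, sc
                        improved = True
                        moves += 1
                        break
        steps /= 2.0
    return full_tf(delta)


# ---------------------------------------------------------------------------
# Recursive alignment
# ---------------------------------------------------------------------------

def initial_outline_alignment(
    patterns, min_area: int = 32, target_area: float | None = None
):
    """Outline-based starting transforms: centre the mask centroid, scale to
    the median area, rotate every principal axis to the set's mean orientation.

    Aligning to the mean orientation (rather than an arbitrary axis) minimizes
    the total rotation applied, which keeps label-resampling artefacts small.
    Degenerate masks (area < min_area) map to None and are logged via warnings.
    """
    grids = [_grid_of(p) for p in patterns]
    if len(grids) < 2:
        raise ValueError("need at least 2 patterns of one wing type")
    stats = []
    for g in grids:
        m = g > 0
        area = float(m.sum())
        if area < min_area:
            stats.append(None)
            continue
        rr, cc = np.nonzero(m)
        cx, cy = cc.mean(), rr.mean()
        x, y = cc - cx, rr - cy
        mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
        angle = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
        stats.append((area, cx, cy, angle))
    valid = [st for st in stats if st is not None]
    if not valid:
        raise ValueError("all masks degenerate; no wing to align")
    target = target_area if target_area is not None else float(np.median([st[0] for st in valid]))
    # axis orientations are defined mod 180 deg: average on the doubled circle
    doubled = np.deg2rad([2 * st[3] for st in valid])
    mean_angle = 0.5 * np.degrees(np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean()))

    transforms = []
    for g, st in zip(grids, stats):
        if st is None:
            warnings.warn("degenerate wing mask excluded from alignment", stacklevel=2)
            transforms.append(None)
            continue
        area, cx, cy, angle = st
        rot = mean_angle - angle
        rot = (rot + 90.0) % 180.0 - 90.0  # axis ambiguity: smallest rotation
        h, w = g.shape
        centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        t0 = centre - np.array([cx, cy])
        s = float(np.sqrt(target / area))
        rs = SimilarityTransform(0.0, 0.0, rot, s)
        transforms.append(rs.compose(SimilarityTransform(float(t0[0]), float(t0[1]), 0.0, 1.0)))
    return transforms


def _frame_stats(transforms) -> tuple[float, float, float, float]:
    return (
        float(np.mean([t.theta for t in transforms])),
        float(np.mean([np.log(t.s) for t in transforms])),
        float(np.mean([t.tx for t in transforms])),
        float(np.mean([t.ty for t in transforms])),
    )


def _anchor_transforms(transforms, anchor) -> list:
    """Left-compose a common correction so the mean transform matches the anchor."""
    th, ls, tx, ty = _frame_stats(transforms)
    c_th = anchor[0] - th
    c_s = float(np.exp(anchor[1] - ls))
    a = np.deg2rad(c_th)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    mean_t = np.array([tx, ty])
    c_t = np.array([anchor[2], anchor[3]]) - c_s * rot @ mean_t
    corr = SimilarityTransform(float(c_t[0]), float(c_t[1]), c_th, c_s)
    return [corr.compose(t) for t in transforms]


@dataclass
class AlignmentResult:
    """Outcome of recursive alignment: the statsmodels-style results object."""

    aligned: list
    transforms: list
    model: WingModel
    trace: list
    scores: list
    kept_indices: list

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    def summary(self) -> str:
        lines = [
            "Recursive pattern alignment",
            f"  wings aligned : {len(self.aligned)}",
            f"  iterations    : {len(self.trace)}",
            f"  mean score    : {self.mean_score:.4f}",
            "  iter   mean_score   model_delta",
        ]
        for t in self.trace:
            lines.append(
                f"  {t['iteration']:4d}   {t['mean_score']:.6f}     {t['model_delta']:.2e}"
            )
        return "\n".join(lines)


def align_recursive(
    patterns,
    n_iter: int = 8,
    tol: float = 1e-3,
    search: SearchSpec | None = None,
) -> AlignmentResult:
    """Recursively register all wings to the average model until it stabilizes.

    Loop: build the model from current transforms, re-register every wing,
    rebuild — until the mean per-pixel absolute change in model frequencies
    drops below ``tol`` or ``n_iter`` is reached.  The mean similarity score
    is enforced non-decreasing: if an iteration lowers it, its transforms are
    discarded and the previous state is returned.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    search = search or SearchSpec()
    grids = [_grid_of(p) for p in patterns]
    init_tfs = initial_outline_alignment(grids)
    kept = [i for i, tf in enumerate(init_tfs) if tf is not None]
    grids = [grids[i] for i in kept]
    transforms = [init_tfs[i] for i in kept]

    model = WingModel.from_patterns(grids, transforms, iteration=0)
    anchor = _frame_stats(transforms)
    trace: list[dict] = []
    prev_mean = -np.inf
    scores = [similarity_score(g, model, tf) for g, tf in zip(grids, transforms)]

    for it in range(1, n_iter + 1):
        spec = search if it == 1 else search.shrunk(0.5)
        scorer = _Scorer(model)
        new_tfs, new_scores = [], []
        for g, tf in zip(grids, transforms):
            cand = register_to_model(g, model, search=spec, init=tf)
            s_cand = scorer.score_transform(g, cand)
            s_old = scorer.score_transform(g, tf)
            # per-wing guard: re-registration must not lower the match
            if s_cand > s_old:
                new_tfs.append(cand)
                new_scores.append(s_cand)
            else:
                new_tfs.append(tf)
                new_scores.append(s_old)
        mean_s = float(np.mean(new_scores))
        if mean_s < prev_mean - 1e-9:
            break  # keep previous transforms: mean score must not decrease
        # re-anchor the model frame: registration must refine mutual alignment,
        # not let the whole set drift in scale/rotation/position
        new_tfs = _anchor_transforms(new_tfs, anchor)
        new_model = WingModel.from_patterns(grids, new_tfs, iteration=it)
        delta = float(np.abs(new_model.freq - model.freq).mean())
        trace.append({"iteration": it, "mean_score": mean_s, "model_delta": delta})
        transforms, model, scores, prev_mean = new_tfs, new_model, new_scores, mean_s
        if delta < tol:
            break

    aligned = [
        ColourPattern(grid=tf.warp_grid(g, fill=0, shape_out=model.shape), space="model")
        for g, tf in zip(grids, transforms)
    ]
    return AlignmentResult(
        aligned=aligned, transforms=transforms, model=model,
        trace=trace, scores=scores, kept_indices=kept,
    )
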