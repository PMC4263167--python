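"""Dominance quantification at the wing-patterning supergene.

For each pair of alleles (a, b) the trait T of an individual is the fraction
of the wing surface at which its pattern matches the modal pattern of the aa
homozygotes while differing from that of the bb homozygotes.  The dominance
coefficient of a over b is the position of the heterozygote group mean between
the homozygote group means,

    h_raw = (T̄_ab − T̄_bb) / (T̄_aa − T̄_bb),

normalized to h = max(h_raw, 1 − h_raw) ∈ [0.5, 1] so that h is reported in
the direction of the more dominant allele (h = 1 strict dominance, h ≈ 0.5
co-dominance).  Dominance heat maps, colour hierarchy maps, conformity
statistics and permutation tests complete the analysis.

The statsmodels-style entry point is :class:`DominanceModel` /
:class:`DominanceResults`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CLASSES, ColourPattern, pair_key
from .synth import DEFAULT_HIERARCHY

_BG = 0


def _grid(p) -> np.ndarray:
    if isinstance(p, ColourPattern):
        return p.grid
    if hasattr(p, "grid"):  # ModalPattern
        return np.asarray(p.grid)
    return np.asarray(p)


# ---------------------------------------------------------------------------
# Trait T and the dominance coefficient
# ---------------------------------------------------------------------------

def trait_T(individual, modal_a, modal_b) -> tuple[float, float]:
    """Surface-based trait of one individual against the two homozygote modals.

    Returns ``(T, neither_fraction)`` where T is the fraction of the analysed
    wing surface matching modal_a and differing from modal_b, and
    neither_fraction the QC fraction matching neither modal.  Pixels where the
    two modals agree contribute to neither quantity's numerator.
    """
    ind, ma, mb = _grid(individual), _grid(modal_a), _grid(modal_b)
    region = (ind > _BG) & (ma > _BG) & (mb > _BG)
    surface = int(region.sum())
    if surface == 0:
        raise ValueError("empty wing surface: no pixel is wing in all three rasters")
    match_a = region & (ind == ma) & (ind != mb)
    neither = region & (ind != ma) & (ind != mb)
    return float(match_a.sum() / surface), float(neither.sum() / surface)


@dataclass
class DominanceResult:
    """Dominance of one allele pair."""

    pair: tuple[str, str]
    T_means: tuple[float, float, float]       # (T̄_aa, T̄_ab, T̄_bb)
    h_raw: float
    h: float
    dominant_allele: str
    T_values: dict                            # genotype key -> per-individual T
    n: dict                                   # genotype key -> group size
    pair_class: str = "NA"
    clipped: bool = False
    neither_fraction: float = float("nan")    # mean het fraction matching neither modal
    h_se: float = float("nan")
    h_ci: tuple[float, float] = (float("nan"), float("nan"))


def dominance_coefficient(
    T_aa, T_ab, T_bb, pair: tuple[str, str] = ("a", "b"), pair_class: str = "NA"
) -> DominanceResult:
    """Dominance coefficient h of allele pair[0] relative to pair[1].

    ``T_aa``/``T_ab``/``T_bb`` are per-individual trait values of the three
    genotype groups (scalars accepted).  h_raw is clipped to [0, 1] (logged);
    h is reported in the dominant direction, h ∈ [0.5, 1].
    """
    T_aa, T_ab, T_bb = (np.atleast_1d(np.asarray(v, dtype=float)) for v in (T_aa, T_ab, T_bb))
    for name, v in (("aa", T_aa), ("ab", T_ab), ("bb", T_bb)):
        if v.size == 0:
            raise ValueError(f"genotype group {name} is empty")
    m_aa, m_ab, m_bb = T_aa.mean(), T_ab.mean(), T_bb.mean()
    if math.isclose(m_aa, m_bb, abs_tol=1e-12):
        raise ValueError(
            f"uninformative pair {pair}: homozygote trait means are equal ({m_aa:g})"
        )
    h_raw = (m_ab - m_bb) / (m_aa - m_bb)
    clipped = not (0.0 <= h_raw <= 1.0)
    if clipped:
        warnings.warn(f"h_raw={h_raw:.3f} outside [0,1] for pair {pair}; clipped",
                      stacklevel=2)
    h_clipped = min(max(h_raw, 0.0), 1.0)
    h = max(h_clipped, 1.0 - h_clipped)
    dominant = pair[0] if h_raw >= 0.5 else pair[1]
    return DominanceResult(
        pair=pair,
        T_means=(float(m_aa), float(m_ab), float(m_bb)),
        h_raw=float(h_raw), h=float(h), dominant_allele=dominant,
        T_values={"aa": T_aa.tolist(), "ab": T_ab.tolist(), "bb": T_bb.tolist()},
        n={"aa": int(T_aa.size), "ab": int(T_ab.size), "bb": int(T_bb.size)},
        pair_class=pair_class, clipped=clipped,
    )


# ---------------------------------------------------------------------------
# Dominance heat maps
# ---------------------------------------------------------------------------

@dataclass
class DominanceHeatMap:
    """Per-pixel proportions of heterozygotes matching the dominant modal only,
    the recessive modal only, both, or neither."""

    props: np.ndarray             # (4, H, W): dom, rec, both, neither
    valid: np.ndarray             # pixels where both modals are wing
    n_het: int
    pair: tuple[str, str] | None = None

    CATEGORIES = ("dominant_only", "recessive_only", "both", "neither")

    def render(self) -> np.ndarray:
        """RGB rendering: red = dominant, blue = recessive, grey = both,
        white = neither, on a black background."""
        red = np.array([1.0, 0.1, 0.1])
        blue = np.array([0.15, 0.25, 1.0])
        grey = np.array([0.55, 0.55, 0.55])
        white = np.array([1.0, 1.0, 1.0])
        p = self.props
        img = (p[0, ..., None] * red + p[1, ..., None] * blue
               + p[2, ..., None] * grey + p[3, ..., None] * white)
        img[~self.valid] = 0.0
        return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def dominance_heatmap(het_patterns, modal_dom, modal_rec, pair=None) -> DominanceHeatMap:
    """Pixel-by-pixel agreement of heterozygotes with the two homozygote modals.

    Evaluated wherever both modal patterns are wing; a heterozygote showing
    background there (e.g. just outside its own outline) counts as matching
    neither.  The four proportions sum to 1 at every valid pixel.
    """
    md, mr = _grid(modal_dom), _grid(modal_rec)
    hets = [_grid(h) for h in het_patterns]
    if not hets:
        raise ValueError("need at least one heterozygote")
    valid = (md > _BG) & (mr > _BG)
    counts = np.zeros((4, *md.shape), dtype=np.float64)
    for h in hets:
        eq_d = (h == md) & valid
        eq_r = (h == mr) & valid
        counts[0] += eq_d & ~eq_r
        counts[1] += eq_r & ~eq_d
        counts[2] += eq_d & eq_r
        counts[3] += valid & ~eq_d & ~eq_r
    props = counts / len(hets)
    props[:, ~valid] = 0.0
    return DominanceHeatMap(props=props, valid=valid, n_het=len(hets), pair=pair)


# ---------------------------------------------------------------------------
# Colour hierarchy statistics
# ---------------------------------------------------------------------------

@dataclass
class PairObservations:
    """Heterozygote patterns of one allele pair with its homozygote modals."""

    pair: tuple[str, str]
    het_patterns: list
    modal_a: object
    modal_b: object
    pair_class: str = "NA"


def _informative(ma: np.ndarray, mb: np.ndarray) -> np.ndarray:
    return (ma > _BG) & (mb > _BG) & (ma != mb)


@dataclass
class ColourHierarchyMap:
    """Colour expressed by heterozygotes where homozygotes differ by a given
    colour pair, pooled over all contributing allele pairs."""

    colour_pair: tuple[str, str]
    props: np.ndarray             # (4, H, W): c1, c2, third colour, other/neither
    n_obs: np.ndarray             # heterozygote observations per pixel
    summary: dict                 # probabilities over all pixel-observations

    @property
    def empty(self) -> bool:
        return bool((self.n_obs == 0).all())

    def render(self) -> np.ndarray:
        """Gradient rendering in the wing colours; grey where no variation."""
        from .io import CLASS_RGB

        c1, c2 = self.colour_pair
        third = next(c for c in CLASSES[1:] if c not in self.colour_pair)
        cols = np.array([CLASS_RGB[c1], CLASS_RGB[c2], CLASS_RGB[third], (255, 255, 255)],
                        dtype=float) / 255.0
        img = np.tensordot(self.props.transpose(1, 2, 0), cols, axes=(2, 0))
        img[self.n_obs == 0] = 0.6
        return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def colour_hierarchy_map(pairs_data, colour_pair) -> ColourHierarchyMap:
    """Aggregate, over every allele pair whose homozygote modals differ by the
    two given colours at a pixel, the colours expressed by heterozygotes there.

    Each heterozygote individual contributes one observation per pixel (equal
    weight).  Returns per-pixel proportions of expressing colour 1, colour 2,
    the third colour, or anything else, plus pooled summary probabilities.
    """
    c1, c2 = colour_pair
    code1, code2 = CLASSES.index(c1), CLASSES.index(c2)
    third = next(c for c in CLASSES[1:] if c not in colour_pair)
    code3 = CLASSES.index(third)
    shape = _grid(pairs_data[0].modal_a).shape
    counts = np.zeros((4, *shape), dtype=np.float64)
    n_obs = np.zeros(shape, dtype=np.float64)
    for pd_ in pairs_data:
        ma, mb = _grid(pd_.modal_a), _grid(pd_.modal_b)
        sel = _informative(ma, mb) & (
            ((ma == code1) & (mb == code2)) | ((ma == code2) & (mb == code1))
        )
        if not sel.any():
            continue
        for h in pd_.het_patterns:
            hg = _grid(h)
            counts[0][sel & (hg == code1)] += 1
            counts[1][sel & (hg == code2)] += 1
            counts[2][sel & (hg == code3)] += 1
            counts[3][sel & (hg != code1) & (hg != code2) & (hg != code3)] += 1
            n_obs[sel] += 1
    if n_obs.sum() == 0:
        warnings.warn(
            f"no allele pair differs by colours {colour_pair}; empty hierarchy map",
            stacklevel=2,
        )
        summary = {c1: float("nan"), c2: float("nan"), third: float("nan"),
                   "other": float("nan"), "n_obs": 0}
        return ColourHierarchyMap(tuple(colour_pair), counts, n_obs, summary)
    props = np.zeros_like(counts)
    np.divide(counts, n_obs[None], out=props, where=n_obs[None] > 0)
    totals = counts.reshape(4, -1).sum(axis=1)
    grand = totals.sum()
    summary = {c1: totals[0] / grand, c2: totals[1] / grand,
               third: totals[2] / grand, "other": totals[3] / grand,
               "n_obs": int(grand)}
    return ColourHierarchyMap(tuple(colour_pair), props, n_obs, summary)


def hierarchy_conformity(pairs_data, hierarchy=DEFAULT_HIERARCHY) -> float:
    """Fraction of heterozygote pixel-observations expressing the
    hierarchy-dominant of the two colours shown by the homozygote modals,
    over all pixels where the modals differ in colour."""
    rank = np.full(len(CLASSES), len(CLASSES), dtype=np.int16)
    for i, c in enumerate(hierarchy):
        rank[CLASSES.index(c)] = i
    conform = 0.0
    total = 0.0
    for pd_ in pairs_data:
        ma, mb = _grid(pd_.modal_a), _grid(pd_.modal_b)
        sel = _informative(ma, mb)
        if not sel.any():
            continue
        ra = rank[ma[sel]]
        rb = rank[mb[sel]]
        dominant_colour = np.where(ra <= rb, ma[sel], mb[sel])
        for h in pd_.het_patterns:
            hg = _grid(h)[sel]
            conform += float((hg == dominant_colour).sum())
            total += hg.size
    if total == 0:
        raise ValueError("no informative pixels for hierarchy conformity")
    return conform / total


def full_dominance_conformity(het_patterns, modal_a, modal_b,
                              pair=("a", "b")) -> tuple[float, str]:
    """Fraction of informative heterozygote pixel-observations equal to one
    homozygote modal wholesale; the better direction is reported with its allele."""
    ma, mb = _grid(modal_a), _grid(modal_b)
    sel = _informative(ma, mb)
    if not sel.any():
        raise ValueError("no informative pixels for full-dominance conformity")
    n_a = n_b = total = 0.0
    for h in het_patterns:
        hg = _grid(h)[sel]
        n_a += float((hg == ma[sel]).sum())
        n_b += float((hg == mb[sel]).sum())
        total += hg.size
    if n_a >= n_b:
        return n_a / total, pair[0]
    return n_b / total, pair[1]


def colour_expression_probability(pairs_data, colour_pair) -> dict:
    """Probability of heterozygotes expressing each colour where homozygote
    modals differ by the given colour pair (pooled pixel-observations)."""
    chm = colour_hierarchy_map(pairs_data, colour_pair)
    return chm.summary


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 20000


def permutation_test_mean_difference(
    values, labels, n_perm: int = 999, seed: int = 0, exact: str | bool = "auto"
) -> tuple[float, float]:
    """Two-sided permutation test of a difference in group means.

    When the number of distinct group assignments C(n, n1) is small the null
    distribution is enumerated exhaustively and p is the exact tail fraction;
    otherwise ``n_perm`` random relabellings give
    p = (1 + #{|perm diff| >= |obs diff|}) / (1 + n_perm).  Deterministic for
    a fixed seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {len(groups)}")
    g1 = values[labels == groups[0]]
    g2 = values[labels == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    obs = float(g1.mean() - g2.mean())
    if np.allclose(values, values[0]):
        return obs, 1.0

    n, n1 = len(values), len(g1)
    n_comb = math.comb(n, n1)
    use_exact = exact is True or (exact == "auto" and n_comb <= _EXACT_LIMIT)
    if use_exact:
        hits = 0
        for idx in itertools.combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            d = values[sel].mean() - values[~sel].mean()
            if abs(d) >= abs(obs) - 1e-12:
                hits += 1
        return obs, hits / n_comb

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        d = perm[:n1].mean() - perm[n1:].mean()
        if abs(d) >= abs(obs) - 1e-12:
            hits += 1
    return obs, (1 + hits) / (1 + n_perm)


def correlate_h_distance(
    h_values, distances, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Pearson correlation between per-pair dominance and phenotypic distance,
    with significance by permutation of the pair labels."""
    h = np.asarray(h_values, dtype=float)
    d = np.asarray(distances, dtype=float)
    if len(h) != len(d) or len(h) < 3:
        raise ValueError("need matched h and distance values for at least 3 pairs")
    if np.std(h) < 1e-12 or np.std(d) < 1e-12:
        raise ValueError("zero variance in h or distance; correlation undefined")
    r = float(np.corrcoef(h, d)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rp = float(np.corrcoef(rng.permutation(h), d)[0, 1])
        if abs(rp) >= abs(r) - 1e-12:
            hits += 1
    return r, (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Model / Results API
# ---------------------------------------------------------------------------

class DominanceModel:
    """Dominance analysis over a set of aligned, categorized wings.

    Parameters
    ----------
    patterns : list of ColourPattern in model space (one wing surface each).
    genotypes : list of allele pairs, one per pattern (homozygotes as
        ``("a", "a")``); order matches ``patterns``.
    pair_class : optional dict mapping sorted allele pairs to
        sympatric/parapatric labels.
    hierarchy : colour dominance order used for conformity statistics.
    """

    def __init__(self, patterns, genotypes, pair_class=None,
                 hierarchy=DEFAULT_HIERARCHY):
        if len(patterns) != len(genotypes):
            raise ValueError("patterns and genotypes must match one-to-one")
        self.patterns = list(patterns)
        self.genotypes = [pair_key(*g) for g in genotypes]
        self.pair_class = {pair_key(*k): v for k, v in (pair_class or {}).items()}
        self.hierarchy = tuple(hierarchy)
        self._groups: dict[tuple, list] = {}
        for p, g in zip(self.patterns, self.genotypes):
            self._groups.setdefault(g, []).append(p)

    def group(self, genotype) -> list:
        return self._groups.get(pair_key(*genotype), [])

    def analysable_pairs(self) -> list[tuple[str, str]]:
        """Pairs with >= 2 specimens of each homozygote and >= 1 heterozygote."""
        alleles = sorted({a for g in self._groups for a in g})
        pairs = []
        for a, b in itertools.combinations(alleles, 2):
            if (
                len(self._groups.get((a, a), [])) >= 2
                and len(self._groups.get((b, b), [])) >= 2
                and len(self._groups.get(pair_key(a, b), [])) >= 1
            ):
                pairs.append((a, b))
        return pairs

    def fit(self, pairs=None, n_boot: int = 0, seed: int = 0) -> "DominanceResults":
        """Estimate h for every analysable pair (optionally bootstrap CIs)."""
        from .phenospace import modal_pattern

        pairs = [pair_key(*p) for p in pairs] if pairs else self.analysable_pairs()
        results: list[DominanceResult] = []
        observations: list[PairObservations] = []
        rng = np.random.default_rng(seed)
        for a, b in pairs:
            hom_a = self._groups[(a, a)]
            hom_b = self._groups[(b, b)]
            hets = self._groups[pair_key(a, b)]
            ma = modal_pattern(hom_a, genotype=(a, a))
            mb = modal_pattern(hom_b, genotype=(b, b))
            t_of = lambda grp: np.array([trait_T(p, ma, mb)[0] for p in grp])
            T_aa, T_bb, T_ab = t_of(hom_a), t_of(hom_b), t_of(hets)
            neither = float(np.mean([trait_T(p, ma, mb)[1] for p in hets]))
            res = dominance_coefficient(
                T_aa, T_ab, T_bb, pair=(a, b),
                pair_class=self.pair_class.get(pair_key(a, b), "NA"),
            )
            res.neither_fraction = neither
            if n_boot > 0:
                res.h_se, res.h_ci = self._bootstrap_h(T_aa, T_ab, T_bb, n_boot, rng)
            results.append(res)
            observations.append(PairObservations(
                pair=(a, b), het_patterns=hets, modal_a=ma, modal_b=mb,
                pair_class=res.pair_class,
            ))
        return DominanceResults(self, results, observations)

    @staticmethod
    def _bootstrap_h(T_aa, T_ab, T_bb, n_boot, rng):
        hs = []
        for _ in range(n_boot):
            try:
                r = dominance_coefficient(
                    rng.choice(T_aa, len(T_aa)), rng.choice(T_ab, len(T_ab)),
                    rng.choice(T_bb, len(T_bb)),
                )
            except ValueError:
                continue
            hs.append(r.h)
        if len(hs) < 2:
            return float("nan"), (float("nan"), float("nan"))
        hs = np.asarray(hs)
        return float(hs.std(ddof=1)), (
            float(np.percentile(hs, 2.5)), float(np.percentile(hs, 97.5))
        )


class DominanceResults:
    """Fitted dominance estimates with diagnostics and derived maps."""

    def __init__(self, model: DominanceModel, results, observations):
        self.model = model
        self.results: list[DominanceResult] = results
        self.observations: list[PairObservations] = observations

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "pair": "/".join(r.pair),
                "pair_class": r.pair_class,
                "n_aa": r.n["aa"], "n_ab": r.n["ab"], "n_bb": r.n["bb"],
                "T_aa": r.T_means[0], "T_ab": r.T_means[1], "T_bb": r.T_means[2],
                "h_raw": r.h_raw, "h": r.h,
                "dominant": r.dominant_allele,
                "h_se": r.h_se,
                "neither_fraction": r.neither_fraction,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.table
        lines = ["Dominance analysis", "=" * 78]
        lines.append(df.to_string(
            index=False,
            float_format=lambda v: f"{v:.3f}" if np.isfinite(v) else "nan",
        ))
        lines.append("=" * 78)
        lines.append(f"mean h: {df['h'].mean():.3f}   "
                     f"mean usable wing fraction: {1 - df['neither_fraction'].mean():.3f}")
        return "\n".join(lines)

    def __getitem__(self, pair) -> DominanceResult:
        key = pair_key(*pair)
        for r in self.results:
            if pair_key(*r.pair) == key:
                return r
        raise KeyError(f"pair {pair} not fitted")

    def _obs(self, pair) -> PairObservations:
        key = pair_key(*pair)
        for o in self.observations:
            if pair_key(*o.pair) == key:
                return o
        raise KeyError(f"pair {pair} not fitted")

    def heatmap(self, pair) -> DominanceHeatMap:
        r, o = self[pair], self._obs(pair)
        if r.dominant_allele == o.pair[0]:
            return dominance_heatmap(o.het_patterns, o.modal_a, o.modal_b, pair=o.pair)
        return dominance_heatmap(o.het_patterns, o.modal_b, o.modal_a,
                                 pair=o.pair[::-1])

    def hierarchy_map(self, colour_pair, pair_classes=None) -> ColourHierarchyMap:
        obs = self._filtered(pair_classes)
        return colour_hierarchy_map(obs, colour_pair)

    def hierarchy_conformity(self, pair_classes=None) -> float:
        return hierarchy_conformity(self._filtered(pair_classes), self.model.hierarchy)

    def full_dominance_conformity(self, pair) -> tuple[float, str]:
        o = self._obs(pair)
        return full_dominance_conformity(o.het_patterns, o.modal_a, o.modal_b, o.pair)

    def colour_expression(self, colour_pair, pair_classes=None) -> dict:
        return colour_expression_probability(self._filtered(pair_classes), colour_pair)

    def _filtered(self, pair_classes=None):
        if pair_classes is None:
            return self.observations
        wanted = {pair_classes} if isinstance(pair_classes, str) else set(pair_classes)
        obs = [o for o in self.observations if o.pair_class in wanted]
        if not obs:
            raise ValueError(f"no fitted pairs with pair_class in {sorted(wanted)}")
        return obs

    def compare_pair_classes(self, class_a="sympatric", class_b="parapatric",
                             n_perm: int = 999, seed: int = 0):
        """Permutation test of mean h between two pair classes."""
        hs, labs = [], []
        for r in self.results:
            if r.pair_class in (class_a, class_b):
                hs.append(r.h)
                labs.append(r.pair_class)
        return permutation_test_mean_difference(hs, labs, n_perm=n_perm, seed=seed)

    def correlate_distance(self, distances: dict, n_perm: int = 999, seed: int = 0):
        """Correlate per-pair h with phenotypic distances keyed by sorted pair."""
        hs, ds = [], []
        for r in self.results:
            key = pair_key(*r.pair)
            if key in distances:
                hs.append(r.h)
                ds.append(distances[key])
        return correlate_h_distance(hs, ds, n_perm=n_perm, seed=seed)
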