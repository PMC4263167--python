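"""Synthetic wing-pattern generator with known ground truth.

Emulates the phenotypes produced by alleles of a wing-patterning supergene:
each allele paints a fixed set of colour patches (black/orange/yellow) on a
canonical wing silhouette, heterozygotes are resolved pixel-by-pixel under a
configurable dominance mechanism, and individuals differ by smooth boundary
jitter, colorimetric noise, stray pixels and a random similarity transform
(placement of the wing in the photograph).

Every downstream stage of the package is benchmarked against the noise-free
truth returned alongside each render.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .io import (
    CLASSES,
    CLASS_RGB,
    ColourPattern,
    SpecimenRecord,
    pair_key,
    write_image,
    write_mask,
    write_specimen_table,
)
from .transforms import SimilarityTransform

COLOUR_CLASSES = tuple(c for c in CLASSES if c != "background")
DEFAULT_HIERARCHY = ("black", "orange", "yellow")
DEFAULT_RESOLUTION = 256


# ---------------------------------------------------------------------------
# Canonical wing silhouette
# ---------------------------------------------------------------------------

def wing_outline_mask(resolution: int = DEFAULT_RESOLUTION) -> np.ndarray:
    """Canonical forewing silhouette: a sheared superellipse, one connected blob.

    Defined parametrically on the unit square so the same shape renders at any
    resolution; the apex (pointed end) sits to the right, as in a spread
    forewing photographed costa-up.
    """
    r = resolution
    rr, cc = np.meshgrid(np.arange(r), np.arange(r), indexing="ij")
    u = 2.0 * cc / (r - 1) - 1.0
    v = 2.0 * rr / (r - 1) - 1.0
    vs = v + 0.22 * u  # shear: leading edge slopes like a costa
    n = 2.4
    body = (np.abs(u / 0.80) ** n + np.abs(vs / 0.52) ** n) <= 1.0
    return body


def _uv_to_px(u: float, v: float, resolution: int) -> tuple[float, float]:
    return ((v + 1.0) / 2.0 * (resolution - 1), (u + 1.0) / 2.0 * (resolution - 1))


# ---------------------------------------------------------------------------
# Allele patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    """A colour patch in canonical wing coordinates (u, v in [-1, 1]).

    kind "ellipse": params = (u_centre, v_centre, u_radius, v_radius, angle_deg)
    kind "polygon": params = ((u1, v1), (u2, v2), ...)
    """

    kind: str
    params: tuple
    colour: str

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "polygon"):
            raise ValueError(f"unknown patch kind {self.kind!r}")
        if self.colour not in COLOUR_CLASSES:
            raise ValueError(f"unknown patch colour {self.colour!r}")

    def rasterize(self, resolution: int) -> np.ndarray:
        shape = (resolution, resolution)
        if self.kind == "ellipse":
            uc, vc, ru, rv, ang = self.params
            rc, cc = _uv_to_px(uc, vc, resolution)
            r_rad = rv / 2.0 * (resolution - 1)
            c_rad = ru / 2.0 * (resolution - 1)
            rr, cc_ = skdraw.ellipse(rc, cc, r_rad, c_rad, shape=shape,
                                     rotation=np.deg2rad(ang))
        else:
            pts = [_uv_to_px(u, v, resolution) for u, v in self.params]
            rr, cc_ = skdraw.polygon([p[0] for p in pts], [p[1] for p in pts], shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc_] = True
        return out


@dataclass(frozen=True)
class AllelePattern:
    """The whole-wing pattern painted by one supergene allele.

    Patches are painted in list order over the base colour (later patches
    overwrite earlier ones) and clipped to the canonical wing outline.
    """

    allele_id: str
    allele_class: str  # "ancestral" | "derived"
    patches: tuple[Patch, ...]
    base_colour: str = "yellow"

    def __post_init__(self) -> None:
        if self.allele_class not in ("ancestral", "derived"):
            raise ValueError(f"allele class must be ancestral/derived, got {self.allele_class!r}")
        if self.base_colour not in COLOUR_CLASSES:
            raise ValueError(f"unknown base colour {self.base_colour!r}")

    def rasterize(self, resolution: int = DEFAULT_RESOLUTION) -> np.ndarray:
        """Class-code grid of the homozygous phenotype in canonical model space."""
        mask = wing_outline_mask(resolution)
        grid = np.zeros((resolution, resolution), dtype=np.int16)
        grid[mask] = CLASSES.index(self.base_colour)
        for patch in self.patches:
            pr = patch.rasterize(resolution) & mask
            grid[pr] = CLASSES.index(patch.colour)
        return grid

    def patch_index_map(self, resolution: int = DEFAULT_RESOLUTION) -> np.ndarray:
        """Topmost covering patch index per pixel (-1 where the base colour shows)."""
        mask = wing_outline_mask(resolution)
        idx = np.full((resolution, resolution), -1, dtype=np.int32)
        for i, patch in enumerate(self.patches):
            idx[patch.rasterize(resolution) & mask] = i
        idx[~mask] = -1
        return idx


# ---------------------------------------------------------------------------
# Dominance mechanisms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominanceMechanism:
    """How a heterozygote resolves pixels where its two allele patterns disagree.

    colour_hierarchy: the colour earlier in ``hierarchy`` is expressed
      (transitive colour dominance, default black > orange > yellow).
    full_dominance: ``dominant_allele``'s pattern is expressed wholesale,
      independent of colour.
    mosaic: each disagreement pixel is won by the allele named in
      ``patch_dominance_map`` for its controlling patch — the topmost covering
      patch of the pair's first allele, key "base" where that allele shows its
      base colour.
    """

    kind: str
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    dominant_allele: str | None = None
    patch_dominance_map: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("colour_hierarchy", "full_dominance", "mosaic"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if len(set(self.hierarchy)) != len(self.hierarchy):
            raise ValueError("hierarchy must be a strict total order (no repeats)")
        for c in self.hierarchy:
            if c not in COLOUR_CLASSES:
                raise ValueError(f"unknown colour {c!r} in hierarchy")
        if self.kind == "full_dominance" and not self.dominant_allele:
            raise ValueError("full_dominance requires dominant_allele")
        if self.kind == "mosaic" and self.patch_dominance_map is None:
            raise ValueError("mosaic requires patch_dominance_map")


def resolve_heterozygote(
    pattern_a: AllelePattern,
    pattern_b: AllelePattern,
    mechanism: DominanceMechanism,
    resolution: int = DEFAULT_RESOLUTION,
) -> np.ndarray:
    """Noise-free heterozygote class grid in canonical model space."""
    ga = pattern_a.rasterize(resolution)
    gb = pattern_b.rasterize(resolution)
    out = ga.copy()
    disagree = ga != gb
    if not disagree.any():
        return out
    if mechanism.kind == "colour_hierarchy":
        rank = np.full(len(CLASSES), len(CLASSES), dtype=np.int16)
        for i, colour in enumerate(mechanism.hierarchy):
            rank[CLASSES.index(colour)] = i
        take_b = rank[gb] < rank[ga]
        out[disagree & take_b] = gb[disagree & take_b]
    elif mechanism.kind == "full_dominance":
        if mechanism.dominant_allele == pattern_a.allele_id:
            pass  # out already equals ga
        elif mechanism.dominant_allele == pattern_b.allele_id:
            out = gb.copy()
        else:
            raise ValueError(
                f"dominant allele {mechanism.dominant_allele!r} is not in the pair "
                f"({pattern_a.allele_id!r}, {pattern_b.allele_id!r})"
            )
    else:  # mosaic
        idx_map = pattern_a.patch_index_map(resolution)
        pdm = mechanism.patch_dominance_map
        keys = np.unique(idx_map[disagree])
        for k in keys:
            key = "base" if k == -1 else int(k)
            if key not in pdm:
                raise ValueError(f"mosaic patch_dominance_map is missing patch index {key!r}")
            winner = pdm[key]
            sel = disagree & (idx_map == k)
            if winner == pattern_a.allele_id:
                pass  # keep allele a's colour
            elif winner == pattern_b.allele_id:
                out[sel] = gb[sel]
            else:
                raise ValueError(f"mosaic winner {winner!r} is not an allele of the pair")
    return out


def programmed_dominance(
    pattern_a: AllelePattern,
    pattern_b: AllelePattern,
    mechanism: DominanceMechanism,
    resolution: int = DEFAULT_RESOLUTION,
) -> dict:
    """Brute-force pixel count of the dominance programmed into a heterozygote.

    Returns the fraction of disagreement pixels at which the noise-free
    heterozygote expresses allele a's colour, plus the normalized coefficient
    (the larger direction) and the corresponding dominant allele.
    """
    ga = pattern_a.rasterize(resolution)
    gb = pattern_b.rasterize(resolution)
    het = resolve_heterozygote(pattern_a, pattern_b, mechanism, resolution)
    disagree = ga != gb
    n = int(disagree.sum())
    if n == 0:
        return {"p_a": float("nan"), "h": float("nan"), "dominant_allele": None,
                "n_disagree": 0}
    p_a = float((het[disagree] == ga[disagree]).sum()) / n
    h = max(p_a, 1.0 - p_a)
    dom = pattern_a.allele_id if p_a >= 0.5 else pattern_b.allele_id
    return {"p_a": p_a, "h": h, "dominant_allele": dom, "n_disagree": n}


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Nuisance variation added to each rendered individual.

    boundary_jitter_sd : px — sd of a smooth random displacement field applied
        to the categorical pattern, wobbling all patch boundaries.
    colour_sd : RGB units — iid Gaussian noise on wing pixels.
    transform_ranges : (max |translation| px, max |rotation| deg, scale interval)
        of the uniform random similarity transform placing the wing.
    pixel_noise_rate : fraction of wing pixels flipped to a random colour class.
    """

    boundary_jitter_sd: float = 1.0
    colour_sd: float = 8.0
    transform_ranges: tuple = (8.0, 8.0, (0.95, 1.05))
    pixel_noise_rate: float = 0.002
    jitter_smoothness: float = 8.0  # px, correlation length of the jitter field

    def __post_init__(self) -> None:
        if min(self.boundary_jitter_sd, self.colour_sd, self.pixel_noise_rate) < 0:
            raise ValueError("noise parameters must be non-negative")
        max_t, max_r, (s_lo, s_hi) = self.transform_ranges
        if max_t < 0 or max_r < 0:
            raise ValueError("transform ranges must be non-negative")
        if not (s_lo <= 1.0 <= s_hi):
            raise ValueError("scale interval must contain 1")


NO_NOISE = NoiseModel(boundary_jitter_sd=0.0, colour_sd=0.0,
                      transform_ranges=(0.0, 0.0, (1.0, 1.0)), pixel_noise_rate=0.0)


def _jitter_grid(grid: np.ndarray, sd: float, smoothness: float, rng) -> np.ndarray:
    if sd == 0:
        return grid
    h, w = grid.shape
    field_ = rng.standard_normal((2, h, w))
    field_ = ndimage.gaussian_filter(field_, sigma=(0, smoothness, smoothness))
    std = field_.reshape(2, -1).std(axis=1, keepdims=True).reshape(2, 1, 1)
    std[std == 0] = 1.0
    disp = field_ / std * sd
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr + disp[0], cc + disp[1]])
    return ndimage.map_coordinates(grid, coords, order=0, mode="constant", cval=0)


def render_individual(
    genotype: tuple[str, str],
    alleles: dict[str, AllelePattern],
    mechanism: DominanceMechanism,
    noise: NoiseModel = NoiseModel(),
    seed: int | list[int] = 0,
    resolution: int = DEFAULT_RESOLUTION,
) -> tuple[np.ndarray, ColourPattern, SimilarityTransform]:
    """Render one individual's wing photograph.

    Returns the RGB image (native frame), the noise-free categorized truth in
    model space, and the similarity transform that was applied (model→native).
    Deterministic given the seed.
    """
    for aid in genotype:
        if aid not in alleles:
            raise KeyError(f"unknown allele id {aid!r}")
    a, b = alleles[genotype[0]], alleles[genotype[1]]
    rng = np.random.default_rng(seed)

    if genotype[0] == genotype[1]:
        truth_grid = a.rasterize(resolution)
    else:
        truth_grid = resolve_heterozygote(a, b, mechanism, resolution)
    truth = ColourPattern(grid=truth_grid, space="model")

    grid = _jitter_grid(truth_grid, noise.boundary_jitter_sd, noise.jitter_smoothness, rng)

    max_t, max_r, (s_lo, s_hi) = noise.transform_ranges
    transform = SimilarityTransform(
        tx=float(rng.uniform(-max_t, max_t)),
        ty=float(rng.uniform(-max_t, max_t)),
        theta=float(rng.uniform(-max_r, max_r)),
        s=float(rng.uniform(s_lo, s_hi)),
    )
    native = transform.warp_grid(grid, fill=0)

    palette = np.array([CLASS_RGB[c] for c in CLASSES], dtype=float)
    rgb = palette[native]
    wing = native > 0
    if noise.pixel_noise_rate > 0:
        flip = wing & (rng.random(native.shape) < noise.pixel_noise_rate)
        random_class = rng.integers(1, len(CLASSES), size=native.shape)
        rgb[flip] = palette[random_class[flip]]
    if noise.colour_sd > 0:
        rgb[wing] += rng.normal(0.0, noise.colour_sd, size=(int(wing.sum()), 3))
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    return rgb, truth, transform


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class CrossConfig:
    """Study design for a simulated set of crosses.

    ``genotypes`` lists the allele pairs to raise (homozygotes as ("a", "a"));
    by default every homozygote and heterozygote combination of ``alleles``.
    ``mechanism`` may be a single mechanism or a per-pair dict keyed by the
    sorted pair tuple.
    """

    alleles: dict[str, AllelePattern]
    n_per_genotype: int = 10
    genotypes: list[tuple[str, str]] | None = None
    mechanism: DominanceMechanism | dict = field(
        default_factory=lambda: DominanceMechanism(kind="colour_hierarchy")
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    pair_class: dict | None = None  # sorted pair tuple -> sympatric/parapatric/NA
    resolution: int = DEFAULT_RESOLUTION
    wing: str = "forewing"
    side: str = "dorsal"

    def all_genotypes(self) -> list[tuple[str, str]]:
        if self.genotypes is not None:
            return [pair_key(*g) for g in self.genotypes]
        ids = sorted(self.alleles)
        gts = [(a, a) for a in ids]
        gts += [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        return gts

    def mechanism_for(self, pair: tuple[str, str]) -> DominanceMechanism:
        if isinstance(self.mechanism, dict):
            if pair[0] == pair[1]:  # homozygotes never need conflict resolution
                return DominanceMechanism(kind="colour_hierarchy")
            return self.mechanism[pair_key(*pair)]
        return self.mechanism


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_cross_dataset`."""

    records: list[SpecimenRecord]
    images: dict[str, np.ndarray]
    truths: dict[str, ColourPattern]
    transforms: dict[str, SimilarityTransform]
    truth_bundle: dict
    config: CrossConfig


def specimen_rng_seed(master_seed: int, specimen_id: str) -> list[int]:
    """One RNG stream per specimen: reproducible and order-independent."""
    return [int(master_seed) & 0x7FFFFFFF, zlib.crc32(specimen_id.encode())]


def simulate_cross_dataset(
    config: CrossConfig,
    master_seed: int = 0,
    outdir: str | Path | None = None,
) -> SimulatedDataset:
    """Simulate a full cross dataset; optionally write it to disk.

    The on-disk layout is images/ + masks/ + specimens.tsv + truth.json.
    Re-running with the same master seed reproduces every file bit-exactly.
    """
    genotypes = config.all_genotypes()
    if config.n_per_genotype < 2:
        raise ValueError("need at least 2 individuals per genotype")

    records: list[SpecimenRecord] = []
    images: dict[str, np.ndarray] = {}
    truths: dict[str, ColourPattern] = {}
    transforms: dict[str, SimilarityTransform] = {}
    programmed: dict[str, dict] = {}

    for a, b in genotypes:
        pk = pair_key(a, b)
        mech = config.mechanism_for(pk)
        if a != b:
            programmed["/".join(pk)] = programmed_dominance(
                config.alleles[pk[0]], config.alleles[pk[1]], mech, config.resolution
            )
        for k in range(config.n_per_genotype):
            sid = f"{a}-{b}_{k:03d}"
            rgb, truth, tf = render_individual(
                (a, b), config.alleles, mech, config.noise,
                seed=specimen_rng_seed(master_seed, sid),
                resolution=config.resolution,
            )
            pc = "NA"
            if config.pair_class and a != b:
                pc = config.pair_class.get(pk, "NA")
            records.append(
                SpecimenRecord(
                    specimen_id=sid, wing=config.wing, side=config.side,
                    genotype=pk, pair_class=pc,
                    image_path=f"images/{sid}.png",
                )
            )
            images[sid] = rgb
            truths[sid] = truth
            transforms[sid] = tf

    truth_bundle = {
        "master_seed": int(master_seed),
        "resolution": config.resolution,
        "mechanism": _mechanism_meta(config),
        "programmed_dominance": programmed,
        "transforms": {sid: tf.as_dict() for sid, tf in sorted(transforms.items())},
    }

    ds = SimulatedDataset(records, images, truths, transforms, truth_bundle, config)
    if outdir is not None:
        _write_dataset(ds, Path(outdir))
    return ds


def _mechanism_meta(config: CrossConfig) -> dict:
    def one(m: DominanceMechanism) -> dict:
        return {
            "kind": m.kind,
            "hierarchy": list(m.hierarchy),
            "dominant_allele": m.dominant_allele,
            "patch_dominance_map": (
                {str(k): v for k, v in m.patch_dominance_map.items()}
                if m.patch_dominance_map else None
            ),
        }

    if isinstance(config.mechanism, dict):
        return {"/".join(k): one(m) for k, m in sorted(config.mechanism.items())}
    return one(config.mechanism)


def _write_dataset(ds: SimulatedDataset, outdir: Path) -> None:
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    for sid, rgb in sorted(ds.images.items()):
        write_image(rgb, outdir / "images" / f"{sid}.png")
        bg = np.array(CLASS_RGB["background"])
        write_mask(~np.all(rgb == bg, axis=-1), outdir / "masks" / f"{sid}.png")
    write_specimen_table(ds.records, outdir / "specimens.tsv")
    (outdir / "truth.json").write_text(json.dumps(ds.truth_bundle, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Built-in allele library and factories
# ---------------------------------------------------------------------------

def example_alleles() -> dict[str, AllelePattern]:
    """A small library of allele patterns emulating mimetic forms.

    Three derived alleles with distinct patch layouts plus one ancestral
    allele; names follow the three-letter convention for mimetic forms.
    """
    band = Patch("polygon", ((-0.55, -0.45), (0.15, -0.50), (0.25, 0.35), (-0.45, 0.40)),
                 colour="black")
    tip = Patch("ellipse", (0.52, -0.12, 0.42, 0.30, -20.0), colour="black")
    disc = Patch("ellipse", (-0.25, 0.05, 0.40, 0.34, 10.0), colour="orange")
    spot = Patch("ellipse", (0.30, 0.18, 0.26, 0.20, 0.0), colour="orange")
    bar = Patch("polygon", ((-0.70, -0.30), (-0.10, -0.38), (-0.05, 0.02), (-0.62, 0.08)),
                colour="black")
    return {
        "tar": AllelePattern("tar", "derived", (disc, tip), base_colour="yellow"),
        "arc": AllelePattern("arc", "derived", (band, spot), base_colour="yellow"),
        "ele": AllelePattern("ele", "derived", (bar, tip, spot), base_colour="orange"),
        "sil": AllelePattern("sil", "ancestral", (tip,), base_colour="yellow"),
    }


def mosaic_stripe_pair(
    p: float,
    n_stripes: int = 40,
    resolution: int = DEFAULT_RESOLUTION,
    colour_a: str = "black",
    base: str = "yellow",
) -> tuple[dict[str, AllelePattern], DominanceMechanism]:
    """Construct an allele pair with mosaic dominance programmed to ≈ p.

    Allele "a" paints a broad band split into thin vertical stripes (separate
    patches, one colour, visually contiguous); allele "b" is the plain base.
    Disagreement pixels are exactly the band; stripes are greedily assigned to
    "a" until the area fraction of a-won pixels best approximates p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    u_lo, u_hi, v_lo, v_hi = -0.62, 0.50, -0.34, 0.34
    edges = np.linspace(u_lo, u_hi, n_stripes + 1)
    stripes = tuple(
        Patch("polygon", ((edges[i], v_lo), (edges[i + 1], v_lo),
                          (edges[i + 1], v_hi), (edges[i], v_hi)), colour=colour_a)
        for i in range(n_stripes)
    )
    a = AllelePattern("a", "derived", stripes, base_colour=base)
    b = AllelePattern("b", "derived", (), base_colour=base)

    # stripes can overlap by a pixel column at shared edges; use exclusive areas
    idx_map = a.patch_index_map(resolution)
    areas = np.array([float((idx_map == i).sum()) for i in range(n_stripes)])
    total = areas.sum()
    pdm: dict = {"base": "b"}
    won = 0.0
    for i in range(n_stripes):
        take = abs((won + areas[i]) / total - p) <= abs(won / total - p)
        if take:
            pdm[i] = "a"
            won += areas[i]
        else:
            pdm[i] = "b"
    mech = DominanceMechanism(kind="mosaic", patch_dominance_map=pdm)
    return {"a": a, "b": b}, mech
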