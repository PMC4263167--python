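"""Ground-truth validation studies on synthetic wings.

Each function runs one self-contained study — generate synthetic specimens
with known truth, push them through the pipeline, measure recovery — and
returns a plain dict of the quantities measured.  The test suite asserts
properties of these dicts; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np

from .align import SearchSpec, align_recursive, register_to_model
from .categorize import categorize, extract_outline
from .dominance import (
    DominanceModel,
    full_dominance_conformity,
    hierarchy_conformity,
    permutation_test_mean_difference,
)
from .io import ColourPattern
from .phenospace import build_trait_matrix, crossvalidate_genotypes, pca_summary
from .align import WingModel
from .synth import (
    NO_NOISE,
    AllelePattern,
    CrossConfig,
    DominanceMechanism,
    NoiseModel,
    Patch,
    example_alleles,
    mosaic_stripe_pair,
    simulate_cross_dataset,
)
from .transforms import SimilarityTransform

#: Search strategy used by the studies: outline alignment removes most of the
#: placement, so a modest residual grid suffices and keeps runtimes short.
STUDY_SEARCH = SearchSpec(t_range=8, t_step=4, theta_range=8, theta_step=4,
                          s_range=0.08, s_step=0.04)


def _categorize_all(ds):
    patterns = []
    for r in ds.records:
        img = ds.images[r.specimen_id]
        pat, _ = categorize(img, extract_outline(img))
        patterns.append(pat)
    return patterns


def analyse_dataset(ds, n_iter: int = 3, tol: float = 1e-3,
                    search: SearchSpec = STUDY_SEARCH):
    """categorize -> align -> DominanceModel.fit on a simulated dataset."""
    patterns = _categorize_all(ds)
    result = align_recursive(patterns, n_iter=n_iter, tol=tol, search=search)
    records = [ds.records[i] for i in result.kept_indices]
    pair_class = {r.genotype: r.pair_class for r in records if r.pair_class != "NA"}
    model = DominanceModel(result.aligned, [r.genotype for r in records],
                           pair_class=pair_class)
    return result, records, model.fit()


# ---------------------------------------------------------------------------

def categorization_recovery(n: int = 20, resolution: int = 128, seed: int = 0) -> dict:
    """Zero-noise renders must categorize back to the exact true pattern."""
    from .synth import render_individual

    alleles = example_alleles()
    ids = sorted(alleles)
    mech = DominanceMechanism(kind="colour_hierarchy")
    genotypes = [(a, b) for a in ids for b in ids]
    exact = 0
    for i in range(n):
        g = genotypes[i % len(genotypes)]
        rgb, truth, _ = render_individual(g, alleles, mech, noise=NO_NOISE,
                                          seed=seed + i, resolution=resolution)
        pat, _ = categorize(rgb, extract_outline(rgb))
        exact += int(np.array_equal(pat.grid, truth.grid))
    return {"exact_fraction": exact / n, "n": n}


def transform_recovery(
    n: int = 50, resolution: int = 128, seed: int = 0,
    max_t: float = 15.0, max_theta: float = 15.0, s_interval=(0.9, 1.1),
    tol=(0.5, 0.5, 0.01),
) -> dict:
    """Known similarity transforms recovered by registration to the
    untransformed twin's model."""
    alleles = example_alleles()
    ids = sorted(alleles)
    rng = np.random.default_rng(seed)
    search = SearchSpec(t_range=16, t_step=4, theta_range=16, theta_step=4,
                        s_range=0.12, s_step=0.04)
    ok = 0
    for i in range(n):
        grid = alleles[ids[i % len(ids)]].rasterize(resolution)
        tf = SimilarityTransform(
            tx=float(rng.uniform(-max_t, max_t)),
            ty=float(rng.uniform(-max_t, max_t)),
            theta=float(rng.uniform(-max_theta, max_theta)),
            s=float(rng.uniform(*s_interval)),
        )
        native = tf.warp_grid(grid)
        model = WingModel.from_patterns([grid])
        rec = register_to_model(native, model, search=search)
        ok += int(rec.is_close(tf.inverse(), *tol))
    return {"recovered_fraction": ok / n, "n": n}


def alignment_convergence(
    n: int = 12, resolution: int = 256, seed: int = 0,
    max_t: float = 8.0, max_theta: float = 8.0, s_interval=(0.95, 1.05),
) -> dict:
    """Same-pattern wings under random transforms must realign to near-identity
    pairwise disagreement, with a non-decreasing mean similarity score."""
    alleles = example_alleles()
    grid = alleles["arc"].rasterize(resolution)
    rng = np.random.default_rng(seed)
    patterns = []
    for _ in range(n):
        tf = SimilarityTransform(
            tx=float(rng.uniform(-max_t, max_t)),
            ty=float(rng.uniform(-max_t, max_t)),
            theta=float(rng.uniform(-max_theta, max_theta)),
            s=float(rng.uniform(*s_interval)),
        )
        patterns.append(tf.warp_grid(grid))
    from dataclasses import replace

    search = replace(STUDY_SEARCH, refine_points=30000)
    result = align_recursive(patterns, n_iter=4, tol=1e-4, search=search)
    scores = [t["mean_score"] for t in result.trace]
    grids = [p.grid for p in result.aligned]
    areas = [float((g > 0).sum()) for g in grids]
    disagreements = []
    for i in range(len(grids)):
        for j in range(i + 1, len(grids)):
            d = float((grids[i] != grids[j]).sum())
            disagreements.append(d / ((areas[i] + areas[j]) / 2))
    return {
        "mean_scores": scores,
        "score_non_decreasing": all(
            b >= a - 1e-9 for a, b in zip(scores, scores[1:])
        ),
        "mean_pairwise_disagreement": float(np.mean(disagreements)),
        "max_pairwise_disagreement": float(np.max(disagreements)),
        "n": n,
    }


def mosaic_h_recovery(
    p_values=(0.5, 0.6, 0.75, 0.9, 1.0),
    n_het: int = 20, n_hom: int = 10, resolution: int = 128, seed: int = 0,
    noise: NoiseModel | None = None,
) -> dict:
    """Estimate h through the full pipeline on crosses with programmed mosaic
    dominance; truth is the brute-force pixel fraction in the truth bundle."""
    noise = noise or NoiseModel()
    out = {}
    for p in p_values:
        alleles, mech = mosaic_stripe_pair(p, resolution=resolution)
        cfg = CrossConfig(
            alleles=alleles, mechanism=mech, noise=noise, resolution=resolution,
            genotypes=[("a", "a"), ("a", "b"), ("b", "b")],
            n_per_genotype=n_hom,
        )
        # heterozygote group gets its own (larger) size
        ds = simulate_cross_dataset(cfg, master_seed=seed + int(round(p * 100)))
        extra = _extra_hets(cfg, n_het - n_hom, seed + int(round(p * 100)))
        ds.records.extend(extra[0])
        ds.images.update(extra[1])
        _, _, fit = analyse_dataset(ds)
        res = fit[("a", "b")]
        prog = ds.truth_bundle["programmed_dominance"]["a/b"]
        out[f"p={p:g}"] = {
            "h_hat": res.h, "h_raw": res.h_raw,
            "h_programmed": prog["h"], "h_nominal": max(p, 1 - p),
            "abs_error_vs_nominal": abs(res.h - max(p, 1 - p)),
            "n_het": res.n["ab"], "n_hom": res.n["aa"],
        }
    return out


def _extra_hets(cfg: CrossConfig, n_extra: int, master_seed: int):
    """Render additional heterozygotes beyond n_per_genotype."""
    from .io import SpecimenRecord
    from .synth import render_individual, specimen_rng_seed

    records, images = [], {}
    pk = ("a", "b")
    for k in range(cfg.n_per_genotype, cfg.n_per_genotype + n_extra):
        sid = f"a-b_{k:03d}"
        rgb, _, _ = render_individual(
            pk, cfg.alleles, cfg.mechanism_for(pk), cfg.noise,
            seed=specimen_rng_seed(master_seed, sid), resolution=cfg.resolution,
        )
        records.append(SpecimenRecord(specimen_id=sid, wing=cfg.wing, side=cfg.side,
                                      genotype=pk, image_path=""))
        images[sid] = rgb
    return records, images


def anti_hierarchy_alleles() -> dict[str, AllelePattern]:
    """A pair where the dominant allele's colours violate the colour hierarchy:
    the recessive homozygote shows black where the dominant shows yellow."""
    band = Patch("polygon", ((-0.55, -0.40), (0.30, -0.45), (0.38, 0.30), (-0.45, 0.36)),
                 colour="black")
    return {
        "dom": AllelePattern("dom", "derived", (), base_colour="yellow"),
        "rec": AllelePattern("rec", "ancestral", (band,), base_colour="yellow"),
    }


def mechanism_discrimination(resolution: int = 256, seed: int = 0,
                             n_per_genotype: int = 5) -> dict:
    """Hierarchy-generated crosses must conform to the colour hierarchy better
    than to whole-pattern dominance; anti-hierarchy full dominance reverses it."""
    out = {}

    alleles = {k: v for k, v in example_alleles().items() if k in ("tar", "arc", "ele")}
    cfg = CrossConfig(alleles=alleles, n_per_genotype=n_per_genotype,
                      mechanism=DominanceMechanism(kind="colour_hierarchy"),
                      resolution=resolution)
    ds = simulate_cross_dataset(cfg, master_seed=seed)
    _, _, fit = analyse_dataset(ds)
    fd = [fit.full_dominance_conformity(r.pair)[0] for r in fit.results]
    expr = {}
    for pair in (("black", "orange"), ("black", "yellow"), ("orange", "yellow")):
        try:
            s = fit.colour_expression(pair)
        except ValueError:
            continue
        expr["/".join(pair)] = {k: v for k, v in s.items()}
    out["hierarchy_mechanism"] = {
        "hierarchy_conformity": fit.hierarchy_conformity(),
        "full_dominance_conformity_mean": float(np.mean(fd)),
        "colour_expression": expr,
        "n_pairs": len(fit.results),
    }

    cfg2 = CrossConfig(alleles=anti_hierarchy_alleles(),
                       n_per_genotype=n_per_genotype + 2,
                       mechanism=DominanceMechanism(kind="full_dominance",
                                                    dominant_allele="dom"),
                       resolution=resolution)
    ds2 = simulate_cross_dataset(cfg2, master_seed=seed + 1)
    _, _, fit2 = analyse_dataset(ds2)
    conf, direction = fit2.full_dominance_conformity(("dom", "rec"))
    out["full_dominance_mechanism"] = {
        "hierarchy_conformity": fit2.hierarchy_conformity(),
        "full_dominance_conformity": conf,
        "direction": direction,
    }
    return out


def loo_classification(resolution: int = 96, seed: int = 0,
                       n_per_genotype: int = 5, k: int = 3) -> dict:
    """Well-separated synthetic homozygote genotypes must classify perfectly
    with a few components (LDA leave-one-out), matching a nearest-centroid
    oracle."""
    alleles = {k_: v for k_, v in example_alleles().items() if k_ in ("tar", "arc", "ele")}
    noise = NoiseModel(boundary_jitter_sd=1.0, colour_sd=8.0,
                       transform_ranges=(0.0, 0.0, (1.0, 1.0)), pixel_noise_rate=0.002)
    cfg = CrossConfig(alleles=alleles, n_per_genotype=n_per_genotype,
                      genotypes=[(a, a) for a in alleles], mechanism=DominanceMechanism(
                          kind="colour_hierarchy"), noise=noise, resolution=resolution)
    ds = simulate_cross_dataset(cfg, master_seed=seed)
    patterns = _categorize_all(ds)
    aligned = [ColourPattern(grid=p.grid, space="model") for p in patterns]
    tm = build_trait_matrix(aligned)
    pca = pca_summary(tm, min_var_fraction=0.01)
    labels = ["/".join(r.genotype) for r in ds.records]
    k_eff = min(k, pca.n_retained)
    acc = crossvalidate_genotypes(pca.scores, labels, k=k_eff)

    # independent oracle: nearest centroid in the same k-component space
    X = pca.scores[:, :k_eff]
    lab_arr = np.array(labels)
    correct = 0
    for i in range(len(X)):
        cents = {}
        for lab in np.unique(lab_arr):
            sel = (lab_arr == lab) & (np.arange(len(X)) != i)
            cents[lab] = X[sel].mean(axis=0)
        pred = min(cents, key=lambda lab: np.linalg.norm(X[i] - cents[lab]))
        correct += int(pred == lab_arr[i])
    return {
        "loo_accuracy": acc,
        "nearest_centroid_accuracy": correct / len(X),
        "n_retained": pca.n_retained,
        "k": k_eff,
        "n": len(X),
    }


def permutation_null_uniformity(n_rep: int = 1000, seed: int = 0,
                                n_perm: int = 199) -> dict:
    """Null p-values of the sampled permutation engine are uniform (KS check)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    labels = np.array([0] * 10 + [1] * 10)
    ps = []
    for i in range(n_rep):
        vals = rng.standard_normal(20)
        _, p = permutation_test_mean_difference(vals, labels, n_perm=n_perm,
                                                seed=seed + 1 + i, exact=False)
        ps.append(p)
    ks = stats.kstest(ps, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "n_rep": n_rep}


def local_adaptation_study(resolution: int = 128, seed: int = 0,
                           n_per_genotype: int = 5) -> dict:
    """Sympatric pairs simulated under coordinated full dominance, parapatric
    pairs under partial mosaic dominance: recovered mean h must separate the
    two classes, mirroring stronger dominance among co-occurring alleles."""
    base = example_alleles()
    alleles = {k: base[k] for k in ("tar", "arc", "ele")}
    mech = {
        ("arc", "tar"): DominanceMechanism(kind="full_dominance", dominant_allele="arc"),
        ("ele", "tar"): DominanceMechanism(kind="colour_hierarchy"),
        ("arc", "ele"): DominanceMechanism(kind="colour_hierarchy"),
    }
    pair_class = {("arc", "tar"): "sympatric",
                  ("ele", "tar"): "parapatric",
                  ("arc", "ele"): "parapatric"}
    cfg = CrossConfig(alleles=alleles, n_per_genotype=n_per_genotype,
                      mechanism=mech, pair_class=pair_class, resolution=resolution)
    ds = simulate_cross_dataset(cfg, master_seed=seed)
    _, _, fit = analyse_dataset(ds)
    tab = fit.table
    h_sym = float(tab.loc[tab.pair_class == "sympatric", "h"].mean())
    h_par = float(tab.loc[tab.pair_class == "parapatric", "h"].mean())
    usable = float(1 - tab["neither_fraction"].mean())
    return {
        "h_mean_sympatric": h_sym,
        "h_mean_parapatric": h_par,
        "usable_wing_fraction": usable,
        "neither_modal_fraction": float(tab["neither_fraction"].mean()),
        "n_pairs": len(tab),
        "table": tab.to_dict(orient="records"),
        "fit": fit,
    }
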