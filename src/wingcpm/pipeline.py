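"""End-to-end pipeline: simulate → categorize → align → phenospace → dominance.

Configuration is a YAML file validated against a pydantic schema (unknown keys
rejected); all randomness is routed through one master seed, so re-running an
identical config reproduces every tabular/JSON report bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .align import SearchSpec, align_recursive
from .categorize import CategorizationConfig, categorize, extract_outline
from .dominance import DominanceModel
from .io import (
    CLASSES,
    pair_key,
    read_image,
    read_specimen_table,
    write_image,
    write_pattern,
)
from .phenospace import build_trait_matrix, genotype_distance, pca_summary
from .synth import (
    CrossConfig,
    DominanceMechanism,
    NoiseModel,
    example_alleles,
    mosaic_stripe_pair,
    simulate_cross_dataset,
)

logger = logging.getLogger("wingcpm")

_forbid = ConfigDict(extra="forbid")


class SimulateBlock(BaseModel):
    model_config = _forbid
    preset: str = "three_allele_demo"      # or "mosaic_pair"
    n_per_genotype: int = 6
    resolution: int = 128
    mechanism: str = "colour_hierarchy"
    dominant_allele: str | None = None
    mosaic_p: float = 0.75
    boundary_jitter_sd: float = 1.0
    colour_sd: float = 8.0
    pixel_noise_rate: float = 0.002
    max_translation: float = 8.0
    max_rotation: float = 8.0
    scale_min: float = 0.95
    scale_max: float = 1.05
    pair_class: dict[str, str] = Field(default_factory=dict)  # "a/b" -> label


class CategorizationBlock(BaseModel):
    model_config = _forbid
    downscale_factor: int = 1
    merge_threshold: float = 60.0
    min_region_px: int = 0


class AlignmentBlock(BaseModel):
    model_config = _forbid
    n_iter: int = 5
    tol: float = 1.0e-3
    t_range: float = 12.0
    t_step: float = 4.0
    theta_range: float = 12.0
    theta_step: float = 4.0
    s_range: float = 0.08
    s_step: float = 0.04


class AnalysisBlock(BaseModel):
    model_config = _forbid
    min_var_fraction: float = 0.01
    n_perm: int = 999
    lda_components: int = 3
    n_boot: int = 0
    write_heatmaps: bool = True


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration."""

    model_config = _forbid
    outdir: str
    seed: int = 0
    wing: str = "forewing"
    side: str = "dorsal"
    input_table: str | None = None
    simulate: SimulateBlock | None = None
    categorization: CategorizationBlock
    alignment: AlignmentBlock
    analysis: AnalysisBlock


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return PipelineConfig(**raw)
    except ValidationError as e:
        missing = [str(err["loc"][0]) for err in e.errors() if err["type"] == "missing"]
        if missing:
            raise ValueError(
                f"config is missing required block(s): {', '.join(missing)}"
            ) from e
        raise


def _noise_from(block: SimulateBlock) -> NoiseModel:
    return NoiseModel(
        boundary_jitter_sd=block.boundary_jitter_sd,
        colour_sd=block.colour_sd,
        pixel_noise_rate=block.pixel_noise_rate,
        transform_ranges=(block.max_translation, block.max_rotation,
                          (block.scale_min, block.scale_max)),
    )


def _cross_config(block: SimulateBlock, wing: str, side: str) -> CrossConfig:
    if block.preset == "mosaic_pair":
        alleles, mech = mosaic_stripe_pair(block.mosaic_p, resolution=block.resolution)
    else:
        alleles = example_alleles()
        if block.preset == "three_allele_demo":
            alleles = {k: alleles[k] for k in ("tar", "arc", "ele")}
        if block.mechanism == "full_dominance":
            mech = DominanceMechanism(kind="full_dominance",
                                      dominant_allele=block.dominant_allele)
        elif block.mechanism == "colour_hierarchy":
            mech = DominanceMechanism(kind="colour_hierarchy")
        else:
            raise ValueError(f"preset {block.preset!r} does not support "
                             f"mechanism {block.mechanism!r}")
    pair_class = {pair_key(*k.split("/")): v for k, v in block.pair_class.items()}
    return CrossConfig(
        alleles=alleles, n_per_genotype=block.n_per_genotype, mechanism=mech,
        noise=_noise_from(block), pair_class=pair_class,
        resolution=block.resolution, wing=wing, side=side,
    )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory.

    Layout: data/ (simulated inputs), patterns/, aligned/, tables and JSON
    reports at the top level, provenance.json with the config hash and
    library versions.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("pipeline start (seed=%d)", config.seed)

    # -- stage 1: inputs -------------------------------------------------
    stage = "simulate/load"
    try:
        if config.simulate is not None:
            cross = _cross_config(config.simulate, config.wing, config.side)
            ds = simulate_cross_dataset(cross, master_seed=config.seed,
                                        outdir=outdir / "data")
            records = ds.records
            images = ds.images
        elif config.input_table:
            table = read_specimen_table(config.input_table, check_images=True)
            records = list(table)
            base = Path(config.input_table).parent
            images = {r.specimen_id: read_image(base / r.image_path, r.mirrored)
                      for r in records}
        else:
            raise ValueError("config needs either a simulate block or input_table")
        records = [r for r in records if r.wing == config.wing and r.side == config.side]
        logger.info("%d specimens loaded", len(records))

        # -- stage 2: categorization -------------------------------------
        stage = "categorize"
        cat_cfg = CategorizationConfig(
            downscale_factor=config.categorization.downscale_factor,
            merge_threshold=config.categorization.merge_threshold,
            min_region_px=config.categorization.min_region_px,
        )
        patterns, cat_qc = [], {}
        pat_dir = outdir / "patterns"
        pat_dir.mkdir(exist_ok=True)
        for r in records:
            mask = extract_outline(images[r.specimen_id])
            pat, qc = categorize(images[r.specimen_id], mask, cat_cfg)
            patterns.append(pat)
            cat_qc[r.specimen_id] = qc
            write_pattern(pat, pat_dir / f"{r.specimen_id}.png")

        # -- stage 3: alignment ------------------------------------------
        stage = "align"
        ab = config.alignment
        search = SearchSpec(t_range=ab.t_range, t_step=ab.t_step,
                            theta_range=ab.theta_range, theta_step=ab.theta_step,
                            s_range=ab.s_range, s_step=ab.s_step)
        result = align_recursive(patterns, n_iter=ab.n_iter, tol=ab.tol, search=search)
        records = [records[i] for i in result.kept_indices]
        aligned_dir = outdir / "aligned"
        aligned_dir.mkdir(exist_ok=True)
        tf_json = {}
        for r, pat, tf, score in zip(records, result.aligned, result.transforms,
                                     result.scores):
            write_pattern(pat, aligned_dir / f"{r.specimen_id}.png")
            tf_json[r.specimen_id] = {**tf.as_dict(), "score": score}
        (outdir / "transforms.json").write_text(json.dumps(tf_json, indent=1,
                                                           sort_keys=True))
        (outdir / "alignment_trace.json").write_text(json.dumps(result.trace, indent=1))
        logger.info("alignment done: %s", result.trace[-1] if result.trace else "n/a")

        # -- stage 4: phenotype space ------------------------------------
        stage = "phenospace"
        tm = build_trait_matrix(result.aligned)
        pca = pca_summary(tm, config.analysis.min_var_fraction)
        geno_labels = ["/".join(r.genotype) for r in records]
        scores_df = pd.DataFrame(
            pca.scores, columns=[f"PC{i+1}" for i in range(pca.n_retained)]
        )
        scores_df.insert(0, "specimen_id", [r.specimen_id for r in records])
        scores_df.insert(1, "genotype", geno_labels)
        scores_df.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False,
                         float_format="%.10g")

        # -- stage 5: dominance ------------------------------------------
        stage = "dominance"
        pair_class = {r.genotype: r.pair_class for r in records if r.pair_class != "NA"}
        model = DominanceModel([p for p in result.aligned],
                               [r.genotype for r in records], pair_class=pair_class)
        fit = model.fit(n_boot=config.analysis.n_boot, seed=config.seed)
        fit.table.to_csv(outdir / "dominance.tsv", sep="\t", index=False,
                         float_format="%.10g")

        analysis: dict = {"n_pairs": len(fit.results)}
        hom_alleles = sorted({g[0] for g in model._groups if g[0] == g[1]})
        distances = {}
        for i in range(len(hom_alleles)):
            for j in range(i + 1, len(hom_alleles)):
                a, b = hom_alleles[i], hom_alleles[j]
                ga, gb = f"{a}/{a}", f"{b}/{b}"
                if ga in geno_labels and gb in geno_labels:
                    distances[pair_key(a, b)] = genotype_distance(
                        pca.scores, geno_labels, ga, gb)
        if fit.results:
            try:
                analysis["hierarchy_conformity"] = fit.hierarchy_conformity()
            except ValueError:
                pass
            classes_present = {r.pair_class for r in fit.results}
            if {"sympatric", "parapatric"} <= classes_present:
                diff, p = fit.compare_pair_classes(n_perm=config.analysis.n_perm,
                                                   seed=config.seed)
                analysis["h_sympatric_minus_parapatric"] = diff
                analysis["h_pair_class_permutation_p"] = p
            if len(distances) >= 3 and len(fit.results) >= 3:
                try:
                    r_corr, p_corr = fit.correlate_distance(
                        distances, n_perm=config.analysis.n_perm, seed=config.seed)
                    analysis["h_distance_correlation"] = r_corr
                    analysis["h_distance_permutation_p"] = p_corr
                except ValueError:
                    pass
            if config.analysis.write_heatmaps:
                hm_dir = outdir / "heatmaps"
                hm_dir.mkdir(exist_ok=True)
                for r in fit.results:
                    hm = fit.heatmap(r.pair)
                    write_image(hm.render(), hm_dir / f"{'-'.join(r.pair)}.png")
        analysis["genotype_distances"] = {"/".join(k): v for k, v in distances.items()}
        (outdir / "analysis.json").write_text(
            json.dumps(analysis, indent=1, sort_keys=True))

        # -- QC + provenance ---------------------------------------------
        stage = "qc"
        from .dominance import trait_T

        het_neither = {"/".join(r.pair): r.neither_fraction for r in fit.results}
        fitted_pairs = {pair_key(*r.pair) for r in fit.results}
        per_specimen = {}
        for r, pat, score in zip(records, result.aligned, result.scores):
            entry = {
                "unresolved_fraction": cat_qc[r.specimen_id]["unresolved_fraction"],
                "alignment_score": score,
            }
            if r.is_heterozygote and r.genotype in fitted_pairs:
                obs = fit._obs(r.genotype)
                entry["neither_modal_fraction"] = trait_T(pat, obs.modal_a, obs.modal_b)[1]
            per_specimen[r.specimen_id] = entry
        qc = {
            "per_specimen": per_specimen,
            "het_neither_modal_fraction": het_neither,
            "retained_pixel_fraction": tm.retained_fraction,
        }
        (outdir / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
        provenance = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": _versions(),
            "config": config.model_dump(),
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=1, sort_keys=True))
    except Exception as e:
        logger.error("pipeline failed in stage %r: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    logger.info("pipeline complete: %s", outdir)
    return outdir


def _versions() -> dict:
    import skimage
    import sklearn

    return {
        "wingcpm": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler) for h in logger.handlers)
    if not have_file:
        fh = logging.FileHandler(outdir / "pipeline.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())


def qc_report(run_dir: str | Path, mad_threshold: float = 3.0) -> dict:
    """Compile the QC summary for a completed run; flags outliers > 3 MAD.

    Outlier flagging covers per-specimen unresolved-pixel fractions and
    alignment scores, plus per-pair neither-modal fractions.
    """
    run_dir = Path(run_dir)
    qc_path = run_dir / "qc.json"
    if not qc_path.exists():
        raise FileNotFoundError(f"{run_dir} holds no completed run (qc.json missing)")
    qc = json.loads(qc_path.read_text())
    report = {"outliers": [], "summary": {}}
    per = qc["per_specimen"]
    for metric, worse_high in (
        ("unresolved_fraction", True),
        ("alignment_score", False),
        ("neither_modal_fraction", True),
    ):
        items = {sid: v for sid, v in per.items() if metric in v}
        if not items:
            continue
        per_m = items
        vals = np.array([v[metric] for v in per_m.values()])
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        report["summary"][metric] = {"median": med, "mad": mad}
        if mad == 0:
            continue
        for sid, v in per_m.items():
            z = (v[metric] - med) / mad
            if (z > mad_threshold and worse_high) or (z < -mad_threshold and not worse_high):
                report["outliers"].append({"specimen_id": sid, "metric": metric,
                                           "value": v[metric], "robust_z": z})
    nf = qc.get("het_neither_modal_fraction", {})
    if nf:
        vals = np.array(list(nf.values()))
        report["summary"]["het_neither_modal_fraction"] = {
            "mean": float(vals.mean()), "max": float(vals.max())
        }
    report["summary"]["retained_pixel_fraction"] = qc.get("retained_pixel_fraction")
    (run_dir / "qc_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def qc_report_text(report: dict) -> str:
    lines = ["QC report", "---------"]
    for metric, s in report["summary"].items():
        lines.append(f"{metric}: " + ", ".join(
            f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in (s.items() if isinstance(s, dict) else [("value", s)])))
    if report["outliers"]:
        lines.append(f"{len(report['outliers'])} outlier(s):")
        for o in report["outliers"]:
            lines.append(f"  {o['specimen_id']}: {o['metric']}={o['value']:.4g} "
                         f"(robust z={o['robust_z']:.1f})")
    else:
        lines.append("no outliers flagged")
    return "\n".join(lines)
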