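# wingcpm — Colour Pattern Modelling for whole-wing phenotypes

`wingcpm` quantifies butterfly wing colour patterns over the *entire* wing
surface and uses that quantification to measure genetic dominance between
alleles of a wing-patterning supergene, as found in the Müllerian mimic
*Heliconius numata*.  It is aimed at evolutionary biologists studying
polymorphic mimicry, dominance evolution, or any system where the phenotype is
a spatial arrangement of discrete colours rather than a handful of landmarks.

The package implements:

- **Colour categorization** — wing extraction from standardized photographs and
  per-pixel assignment to discrete colour classes (black / orange / yellow),
  treating colours as classes independent of minor colorimetric variation.
- **Pattern-based alignment** — every categorized wing is registered
  (translation, rotation, isotropic scale) against an average *wing model*,
  a per-pixel stack of colour-class frequencies that is recursively rebuilt
  from the registered wings.  The fixed point defines pixel-level positional
  homology without landmarks or venation.
- **Phenotype space** — each common non-background pixel is a trait (one-hot
  over colour classes); PCA summarizes variation, linear discriminant analysis
  cross-validates genotype separation, and per-genotype *modal patterns* give
  consensus phenotypes.
- **Dominance analysis** — for an allele pair (a, b), the trait of an
  individual is the wing fraction matching the aa modal pattern while
  differing from the bb one,

  T = #{pixels ≡ modal_aa and ≠ modal_bb} / wing surface,

  and the dominance coefficient of a over b is

  h_raw = (T̄_ab − T̄_bb) / (T̄_aa − T̄_bb),  h = max(h_raw, 1 − h_raw) ∈ [0.5, 1]

  (h = 1 strict dominance, h ≈ 0.5 co-dominance; h is reported in the
  direction of the more dominant allele).  Dominance heat maps, colour
  hierarchy maps, conformity statistics and permutation tests complete the
  analysis.
- **Synthetic wings** — a generator that paints allele-specific patch patterns
  on a canonical wing silhouette, resolves heterozygotes under configurable
  dominance mechanisms (colour hierarchy, complete dominance, patchwise
  mosaic), and adds boundary jitter, colour noise and random placement.  Every
  downstream stage is validated against this ground truth.

## Worked example

```python
import numpy as np
from wingcpm import (CrossConfig, DominanceMechanism, DominanceModel,
                     align_recursive, categorize, extract_outline,
                     example_alleles, simulate_cross_dataset)

# simulate a cross between two mimetic alleles (10 wings per genotype)
alleles = {k: v for k, v in example_alleles().items() if k in ("tar", "arc")}
cfg = CrossConfig(alleles=alleles, n_per_genotype=6, resolution=128,
                  mechanism=DominanceMechanism(kind="colour_hierarchy"))
ds = simulate_cross_dataset(cfg, master_seed=3)

# categorize and align all wings into the common model space
patterns = []
for rec in ds.records:
    img = ds.images[rec.specimen_id]
    pat, qc = categorize(img, extract_outline(img))
    patterns.append(pat)
aligned = align_recursive(patterns, n_iter=5, tol=1e-3)

# estimate dominance for the pair
genotypes = [ds.records[i].genotype for i in aligned.kept_indices]
fit = DominanceModel(aligned.aligned, genotypes).fit()
print(fit.summary())
```

prints

```
Dominance analysis
==============================================================================
   pair pair_class  n_aa  n_ab  n_bb  T_aa  T_ab  T_bb  h_raw     h dominant  h_se  neither_fraction
arc/tar         NA     6     6     6 0.706 0.443 0.008  0.623 0.623      arc   NaN             0.018
==============================================================================
mean h: 0.623   mean usable wing fraction: 0.982
```

Reading the table: the two homozygote modal patterns differ over ~70% of the
wing (T̄_aa ≈ 0.71 versus T̄_bb ≈ 0.01); the heterozygote mean sits at
T̄_ab ≈ 0.44, i.e. h ≈ 0.62 — partial dominance of *arc*, matching the
dominance actually programmed into this simulated cross (0.614, from the
colour hierarchy applied to these two patch patterns).  About 2% of the
heterozygote wing matches neither modal pattern (boundary variability), so
~98% of the surface is usable for scoring.

A reproducible end-to-end run (images → tables → QC → heat maps) is also
available from the shell:

```bash
cpm run -c config.yaml     # simulate/categorize/align/phenospace/dominance
cpm qc <run-dir>           # QC summary with outlier flags
```

## Layout

```
src/wingcpm/
  synth.py        synthetic wing generator (ground truth)
  io.py           patterns (indexed PNG + sidecar), specimen tables, images
  categorize.py   wing extraction, simplification, colour categorization
  transforms.py   similarity transforms and categorical warping
  align.py        wing model, registration, recursive alignment
  phenospace.py   trait matrix, PCA, modal patterns, LDA cross-validation
  dominance.py    trait T, coefficient h, maps, conformity, permutation tests
  validation.py   ground-truth recovery studies
  pipeline.py     YAML-configured end-to-end pipeline + QC
  cli.py          `cpm` command-line interface
```

See `docs/methods.md` for the model, its assumptions, and numerical choices.
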