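# Methods

## The problem

Mimetic wing patterns are whole-surface phenotypes: discrete colours (here
black, orange, yellow) arranged in patches whose shapes and positions vary
continuously between individuals.  Quantifying dominance between the alleles
of a patterning supergene requires comparing heterozygote wings with both
homozygote forms *pixel by pixel*, which in turn requires (i) reducing each
photograph to a categorical colour raster and (ii) a positional homology
mapping every wing into one common frame.  This package implements both
steps (Colour Pattern Modelling), the dominance statistics built on them, and
a synthetic-wing generator that provides ground truth for every stage.

## Colour categorization

The wing is separated from the background (a reserved colour in synthetic
renders; the largest connected non-background component is kept, holes
filled).  Optionally the image is simplified by block-average downscaling and
hierarchical region merging on a region-adjacency graph (regions whose mean
RGB distance falls below `merge_threshold` are merged; regions below
`min_region_px` are absorbed into the neighbour of nearest mean colour).

Classification is nearest-centroid in RGB: every wing pixel is assigned the
colour class whose declared centroid is closest.  Pixels farther than
`merge_threshold` (default 60 RGB units) from every centroid, or exactly tied
between two, are flagged *unresolved* — they are still assigned (ties to the
class declared earlier, for determinism) but counted per specimen in the QC
report.  This replaces interactive correction of imputation errors with an
auditable, deterministic rule.  An unsupervised mode (k-means with k chosen
by silhouette) is available for images whose colour count is not known a
priori; it is a cross-check, not the default path.

## Similarity transforms and categorical resampling

Wings are aligned with similarity transforms (translation in px, rotation in
degrees, isotropic scale) acting about the raster centre, so composition and
inversion are resolution-independent within a run.  Rasters are categorical,
so resampling must not blend colours.  Plain nearest-neighbour label sampling
leaves a jagged, quantization-phase-dependent band along every class
boundary; when many wings are compared pixel-wise this band dominates the
disagreement budget.  We therefore resample labels by *smoothed-indicator
majority vote*: each class's indicator field is smoothed with a small
Gaussian (σ = 1.5 px), sampled bilinearly at the inverse-mapped position, and
the output pixel takes the argmax class (ties to the lower class code).  The
output is still strictly categorical; boundaries are localized to sub-pixel
accuracy because the smoothing averages the rasterization jags that carry the
sub-pixel boundary position.  Exactly-identity transforms return the input
unchanged, so zero-noise renders categorize back to their truth pixel-exactly.
The σ = 1.5 px kernel biases boundaries by ~σ²·curvature/2 (≈ 0.05 px for a
20 px-radius patch) and erodes features thinner than ~3 px; allele patches in
the generator are an order of magnitude larger.

## Recursive pattern alignment

**Initialization.** Each wing mask is centred on its centroid, scaled to the
median mask area, and rotated so its principal axis matches the *mean*
orientation of the set (orientations averaged on the doubled circle, since an
axis is defined modulo 180°).  Aligning to the mean rather than to an
arbitrary axis minimizes the total rotation applied and hence resampling
artefacts.  Masks below 32 px are excluded with a warning.

**Similarity metric.** The score of a transform is the mean, over supported
model pixels, of the model's frequency for the class the transformed wing
shows there.  It is 1 exactly when a wing reproduces a consensus model and
0 when it matches a class of frequency zero everywhere.  The metric rewards
matching of class labels directly — appropriate for categorical patterns —
and is bounded in [0, 1].

**Optimization.** Registration is an exhaustive coarse grid over
(tx, ty, θ, s) followed by coordinate-wise pattern search with halving steps
(down to 0.02 px / 0.02° / 0.05 % by default).  The refinement phase uses a
continuous surrogate of the score (smoothed pattern indicators sampled
bilinearly against the model frequencies): the discrete score is piecewise
constant below ~0.3 px, and the surrogate lets the search localize the
optimum to ~0.05 px / 0.1°.  Everything is deterministic; score ties in the
coarse grid break toward the smallest-magnitude perturbation, so an
already-registered wing returns the identity.

**Recursion.** The model — a per-pixel stack of class frequencies over all
contributing wings, normalized to sum to 1 wherever support is positive — is
rebuilt after each round of registrations, until its mean absolute frequency
change drops below `tol` or `n_iter` is reached.  Two safeguards keep the
iteration monotone: per wing, a re-registration that does not improve the
discrete score is discarded in favour of the previous transform; and an
iteration that lowers the mean score is discarded wholesale, ending the loop.
The transform set is re-anchored each iteration (a common correction keeps
the mean translation/rotation/log-scale at its initial value), so the wings
refine their *mutual* alignment instead of drifting collectively in scale or
orientation — collective drift de-phases boundary resampling across wings and
inflates pairwise disagreement without changing homology.

Forewings and hindwings are aligned in separate runs; the machinery is
wing-agnostic.

## Phenotype space

Pixels that are non-background in *every* aligned wing are traits; each is
one-hot encoded over the colour classes, so squared Euclidean distance
between two specimens is twice the count of disagreeing pixels — consistent
with the surface-based trait T.  PCA is centred, full-rank, and retains
exactly the components explaining more than `min_var_fraction` (default 1 %)
of variance.  Genotype distance is the Euclidean distance between genotype
centroids in the retained space.  Modal patterns set each pixel to the colour
class most frequent among a genotype's wings (background is outvoted wherever
any wing shows colour; ties go to the earlier class and are flagged).
Genotype separability is checked by leave-one-out linear discriminant
analysis on the first k components (singular scatter falls back to shrinkage
LDA with a warning) — on well-separated synthetic genotypes three components
classify 100 % of homozygotes, and a nearest-centroid oracle agrees.  An
alternative LDA-based trait (projection onto the discriminant axis between
the homozygote groups, scaled so the group means map to 0 and 1) is provided
as a cross-check of the surface-based T.

## Dominance quantification

For an allele pair (a, b), modal patterns are built from the aa and bb
homozygotes (n ≥ 2 each).  For any individual, the trait

T = #{pixels equal to modal_aa and different from modal_bb} / analysed surface

is computed over pixels that are wing in the individual and in both modals;
pixels matching both modals (where the modals agree) count in the
denominator only, and the fraction matching *neither* modal is reported as a
QC quantity (it concentrates along patch boundaries).  The dominance
coefficient is the linear interpolation position of the heterozygote group
mean between the homozygote means, h_raw = (T̄_ab − T̄_bb)/(T̄_aa − T̄_bb) —
the unique affine form with anchors h = 1 (heterozygote at the aa mean,
strict dominance) and h = 0.5 (midpoint, co-dominance).  h_raw is clipped to
[0, 1] (logged) and reported as h = max(h_raw, 1 − h_raw) with the dominant
allele named, so h ∈ [0.5, 1] regardless of labelling direction.  A pair with
equal homozygote means is uninformative and raises.  T is computed per
individual and then averaged, which enables per-individual QC and
bootstrapping (optional bootstrap over individuals within genotype groups
gives an SE and percentile CI for h).  When several wing surfaces per
specimen are analysed, each surface is processed in its own alignment run and
per-surface h values are averaged.

**Heat maps.** At every pixel where both modals are wing, the proportions of
heterozygotes matching the dominant modal only, the recessive only, both, or
neither are recorded (they sum to 1) and rendered red / blue / grey / white
on black.

**Colour hierarchy.** Statistics are pooled per *colour pair* rather than per
allele pair: at each pixel, every allele pair whose modals show that colour
difference contributes its heterozygote observations with equal weight per
individual.  The hierarchy map reports the proportions expressing each
colour; `hierarchy_conformity` is the fraction of informative observations
expressing the hierarchy-dominant colour (default order black > orange >
yellow); `full_dominance_conformity` is the fraction matching one modal
wholesale, reported in its better direction.  Comparing the two statistics
discriminates the mechanisms: hierarchy-generated crosses conform to the
colour hierarchy and not to whole-pattern dominance, and vice versa.

**Inference.** Group comparisons (e.g. mean h of sympatric versus parapatric
pairs) use a two-sided permutation test on the group-mean difference; the
engine enumerates all label assignments exhaustively whenever C(n, n₁) ≤
20 000 (exact p = tail fraction) and otherwise samples n_perm relabellings
with p = (1 + hits)/(1 + n_perm).  The h–distance relationship uses Pearson
correlation with permutation of the h vector.  Analyses of different allele
pairs are treated as independent; no multiple-testing correction is applied,
and the reports say so.

## Synthetic wings: what they emulate and what they do not

The generator paints each allele's patches (ellipses/polygons in canonical
wing coordinates, painted in order over a base colour, clipped to a fixed
sheared-superellipse forewing silhouette, default 256×256) and resolves
heterozygote disagreement pixels under one of three mechanisms: colour
hierarchy, complete dominance of one allele, or a mosaic keyed by the
controlling patch (the topmost covering patch of the pair's first allele,
"base" where that allele shows its base colour).  The truth bundle records,
per pair, the brute-force pixel fraction of disagreement won by each allele —
the programmed dominance against which estimates are scored.  The
`mosaic_stripe_pair` factory splits one broad band into thin stripes assigned
greedily to the two alleles, hitting any target dominance p to within stripe
granularity (~1 %).

Individual variation comprises: a smooth random displacement field
(Gaussian-filtered white noise, correlation length 8 px, amplitude
`boundary_jitter_sd`, default 1 px) that wobbles all patch boundaries; iid
RGB noise on wing pixels (default σ = 8); salt-noise flips of wing pixels to
random colour classes (rate 0.002); and a uniform random similarity transform
(default ±8 px, ±8°, scale 0.95–1.05) placing the wing in its "photograph".
These defaults were chosen once as plausible magnitudes for standardized
wing photography — boundary wobble well below patch size, colour noise well
below the ~100-unit centroid separations, placement within the registration
search range — and the unit tests sweep around them.  Each specimen draws
its noise from an RNG stream seeded by (master seed, specimen id), so
datasets are bit-reproducible and order-independent.

What the generator does *not* emulate: scale texture, venation, iridescence,
dorsal/ventral asymmetry, wing damage, photographic vignetting or colour
casts.  Passing tests therefore demonstrate correctness of the algorithms
under controlled variation, not robustness to every artefact of real
photographs; on real data the unresolved-pixel and neither-modal QC channels
are the guard rails.

## Validation studies and problem sizes

The studies in `wingcpm.validation` (run by the test suite and by
`scripts/acceptance.py`) use these designs, chosen to exercise each property
at meaningful but desk-scale sizes:

- categorization recovery: 20 zero-noise wings at 128 px — exact pixel
  identity required;
- transform recovery: 50 wings at 128 px, placements up to ±15 px / ±15° /
  scale 0.9–1.1, recovery within 0.5 px / 0.5° / 1 % (boundary jitter is
  excluded here so the target transform is exactly defined; jitter robustness
  is covered by the h-recovery study);
- alignment convergence: 12 copies of one wing at 256 px under random
  placements — non-decreasing mean score, all pairwise disagreements < 1 % of
  wing area.  256 px is used because pairwise disagreement on categorical
  rasters has a resampling floor proportional to boundary length over area;
- h recovery: programmed mosaic dominance p ∈ {0.5, 0.6, 0.75, 0.9, 1.0},
  20 heterozygotes and 10 homozygotes per genotype at 128 px with the full
  default noise model including placement, run through the complete
  categorize → align → modal → T → h pipeline; |ĥ − max(p, 1−p)| ≤ 0.05;
- mechanism discrimination: three-allele hierarchy cross and an
  anti-hierarchy complete-dominance cross (dominant allele yellow where the
  recessive is black) at 256 px;
- permutation calibration: exact enumeration cross-checked against an
  independent combinatorial oracle; null uniformity via KS at 500–1000
  replicates of a 10 v 10 test.

## Known limitations

- Similarity transforms only: shape change beyond translation/rotation/scale
  (allometry, wing damage) is absorbed into pattern disagreement, not
  corrected; non-rigid registration is out of scope.
- The registration objective is non-convex; the coarse grid must bracket the
  true placement (outline initialization plus the default ±16 px / ±16° /
  ±12 % grid covers the generator's defaults with margin).
- Categorical rasters impose a boundary-resampling floor on pixel-level
  agreement between wings (~0.5–1 % of wing area at 256 px); statements about
  finer agreement require higher resolution.
- Modal patterns need ≥ 2 wings per homozygote genotype; pairs whose
  homozygote modal patterns coincide are uninformative for h by construction.
- With few allele pairs, exact permutation p-values are coarse (e.g. three
  pairs give a minimum two-sided p of 1/3); the pipeline reports them as
  computed.
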