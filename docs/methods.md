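# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Embryo grading and agreement

A grade string is one expansion digit (1–4) followed by the ICM letter and
then the TE letter (the usual Gardner ordering). The embryo score is
ES = EXS + ICMS + TS with ICMS ∈ {A:3, B:2, C:1} and TS ∈ {A:2, B:2, C:1}:
ICM quality is weighted higher than TE because it is the stronger predictor
of live birth. A consequence of the TS map is that the maximum score 9 is
reached by both 4AA and 4AB, while the minimum 3 is unique to 1CC; the test
suite asserts exactly this. Improving any single component never lowers the
score.

Non-viability is operationalized per litter as (# embryos graded 1CC
post-culture whose ``changed_in_culture`` flag is false) / litter size. The
flag is supplied per embryo; the package does not infer growth from images.

Inter-rater agreement uses weighted Cohen's kappa,
κ = 1 − Σ wᵢⱼ Oᵢⱼ / Σ wᵢⱼ Eᵢⱼ, with disagreement weights
wᵢⱼ = |i − j| (linear, the default) or (i − j)² (quadratic), levels taken
from the union of observed numeric scores (unobserved levels contribute
nothing to either sum, so this equals using the full 3–9 scale), and Eᵢⱼ
the outer product of the two raters' marginals. When both raters are
constant and identical the chance disagreement is zero and kappa is
undefined; this is raised, not defaulted. Group comparisons of scores are
rank-based: Mann–Whitney U for two groups, Kruskal–Wallis beyond, with ties
handled by scipy's midrank machinery.

## Species demultiplexing

Each barcode carries mapping rates to the rat and the human genome. The
call is the genome with the higher rate provided the winner reaches
``min_rate`` (default 0.5) and the gap reaches ``margin`` (default 0.1);
otherwise the barcode is ambiguous, and exact ties are always ambiguous.
The thresholds are deliberately conservative defaults — the decision rule
(higher mapping rate wins) is the substantive part; both thresholds are
recorded in the output summary. Human and ambiguous barcodes are excluded
from all downstream analyses.

## QC, normalization and annotation

Retention requires mito fraction ≤ 0.25 **and** 500 ≤ detected genes
≤ 8000, all bounds inclusive on the retain side (exclusion requires *more
than* 25% mitochondrial reads). Mitochondrial genes are an explicit list
(default: the 13 mtDNA protein-coding genes); no name-prefix inference.
Every excluded cell carries its reasons; filtering is idempotent.

Normalization is a transparent two-step stand-in for variance-stabilizing
transforms: per-cell scaling to 10,000 counts followed by log(1+x), then a
per-gene ordinary least-squares regression on the per-cell ribosomal
expression fraction, returning residuals plus the gene mean (equivalently
y − β(x − x̄)). A zero-variance covariate makes the second step a no-op.
Downstream stages only require a monotone stabilized scale with the
ribosomal covariate removed, which this provides and which is fully
desk-verifiable. Which genes count as ribosomal is caller-supplied.

Cell typing assigns TE or ICM by the larger marker-panel mean of normalized
expression, requiring that mean to be positive; ties and all-zero panels
give "unassigned" (deterministic, never random). Sex is male iff any of the
three Y-chromosome markers has a raw count > 0; everything else is
"female/indeterminate", since so few sex-specific genes are expressed at
E4.5 that only the male call is confident.

## Gene-set scores

A score is the unweighted per-cell mean of normalized expression over the
set's genes — no control-gene-bin background subtraction, since none is
required by the downstream comparisons. Set genes absent from the matrix
are skipped with a warning rather than scored as zero (absence is a
detection artifact, not zero biology) and reported so callers can decide.
Packaged sets: mtDNA quantity (13 genes), oxidative-stress response (11),
base-excision repair (7). Scores are computed per cell and compared across
groups with the same rank tests as embryo scores, reporting per-group
medians and quartiles.

## Hurdle differential expression

Two parts per gene: (1) a two-sided Fisher exact test on the 2×2 table of
detection (raw count > 0) by group; (2) a two-sided Mann–Whitney test on
the normalized values of detected cells. The parts combine by Fisher's
method; a part with no data (no detected cells on either side, or constant
values) contributes p = 1, and a gene undetected everywhere gets p = 1.
P-values are clamped to (1e−300, 1]. The exact test's discreteness makes
the combination slightly conservative; measured type-I error at p ≤ 0.05
on a 2000-gene null with 100 cells/group sits near 0.03–0.05.

Fold change follows the single-cell avg-log2FC convention: group means are
taken on the de-logged normalized scale (expm1 of the normalized layer,
i.e. size-scaled counts), then log2((mean_A + 0.1)/(mean_B + 0.1)). The
pseudocount 0.1 is recorded in the result metadata. Means are floored at
zero because covariate regression can push individual values slightly
negative. On this scale a planted 4-fold shift in the NB mean reads as
log2 FC ≈ 2, as it should.

Significance is |log2 FC| > 1 (strict) with raw p ≤ 0.05; BH-adjusted
p-values over all tested genes are reported alongside but do not gate the
call — the headline DEG tables this mirrors are raw-p selected, with
adjusted p shown. Swapping the groups negates every fold change and
preserves every p-value exactly.

## Generational analyses

Embryo collections span years, so genes significant between the two
*control* generations (CON F2e vs CON F3e) are treated as environmental
confounders. The blacklist condition is |log2 FC| ≥ 1 (inclusive) with
p ≤ 0.05 — the printed form of the confounder rule — while the main DEG
call stays strict; blacklisted genes are removed from every other
comparison's results.

Directionality classifies each gene significant in at least one
within-generation exposure comparison by its (sign, significance) pair in
each generation: Up→Up, Up→Down, Up→NS, Down→Down, Down→Up, Down→NS,
NS→Up, NS→Down. Genes significant in neither generation are omitted.

Mitochondrial matching requires presence in **both** the mouse and human
catalog sets; categories (seven fixed labels: metabolism, mitoribosomes
and biosynthesis, cell signaling and cell fate, oxidative phosphorylation,
oxidative repair, dynamism (fission/fusion), structure/other) must agree
between the species entries or the row is flagged rather than silently
resolved. The real curated databases are not bundled; the catalog file
format (TSV: gene, species, category) and a small synthetic stand-in
generator are provided instead.

Fold enrichment is (k/n)/(K/N) with the hypergeometric upper tail
P(X ≥ k) as p-value (p = 1 when k = 0) and BH adjustment across pathways.
The universe defaults to all *tested* genes, not all annotated genes, and
is recorded in the output; pathway genes outside the universe are ignored.
The implementation is verified against exhaustive enumeration of the
hypergeometric tail on all instance sizes up to N = 50.

## Imaging

A ZStack is a set of equally shaped 3-D channels with a slice height
(default 1.675 µm) and a per-voxel ROI. Thresholding is either a fixed
value (mask = voxel ≥ t, intersected with the ROI) or Otsu's method on the
ROI histogram; for batches, one Otsu threshold from the pooled histogram is
applied to every stack so groups remain comparable. Total intensity is
Σ(integrated density) / (Σ(area) × slice height), with area the per-slice
mask voxel count in pixel units (physical pixel size is not modeled because
the quantity of interest is a ratio across groups under a shared
threshold); per-slice intensity is density/area without the height factor.
An empty mask is an error (no signal above threshold), not zero.

Nuclei are counted as 3-D connected components (26-connectivity) of the
thresholded nuclear channel with a minimum volume filter (default 27
voxels) to reject speckle — so a nucleus spanning several z slices counts
once, and sub-volume noise does not count at all. The lipid-peroxidation
ratio is green/red slice intensity on the same mask and slice, defaulting
to the middle slice (the analyzed slice is a recorded parameter); zero red
intensity is an error.

## The synthetic-data generator

The generator exists so every stage has inputs with known ground truth.

*Counts.* Four populations (CON/HFDM × F2/F3, 200 cells each by default)
over a gene universe containing the marker panels, the three gene sets, 20
ribosomal genes and filler genes (2000 total by default). Counts are
negative binomial via a gamma–Poisson mixture (var = µ + µ²/θ, θ = 2 by
default) with independent Bernoulli dropout (rate 0.2) — a deliberately
minimal structure matching what the downstream tests assume. Baseline
means are log-normal (median 2 counts); ribosomal genes are 3× higher so
the ribosomal-fraction covariate has realistic spread. TE/ICM markers are
8-fold elevated in their own type and 4-fold suppressed in the other
(~70% TE cells); male markers have mean 3 in male cells (~30% of cells)
and are strictly zero elsewhere, and every male cell is guaranteed at
least one marker transcript after dropout — sex ground truth is defined by
marker presence, so sampling noise must not erase a cell's sex. Planted
effects multiply the NB mean of chosen genes in one (group, generation)
population by 2^effect. All randomness flows from one integer seed;
identical seeds give bit-identical output.

What the generator does **not** emulate: doublets, ambient RNA,
batch-specific library-size distributions, gene–gene correlation, UMI
saturation, or any real optics (nuclei are solid spheres, other channels
are Poisson noise fields, there is no PSF). Passing tests therefore
demonstrate correctness of the computations under the stated model, not
robustness to every artifact of real data.

*Other fixtures.* Grade cohorts draw litter sizes from a Poisson and
grades from per-group distributions over valid grade strings (these
distributions are free parameters — no published per-group distribution
exists to copy). Rater pairs repeat rater 1's uniform 3–9 score with the
given agreement probability, else draw independently, so agreement 1 gives
κ = 1 and agreement 0 gives κ ≈ 0. Barnyard profiles place the two species
at mapping rates 0.5 ± separation/2 with Gaussian noise, clipped to [0, 1].
Z-stacks contain disjoint solid nuclei placed by rejection sampling with
whole-configuration restarts (centers ≥ 2r + 2 apart so components stay
separate under 26-connectivity; on axes thinner than one diameter the
nucleus is centered and clipped, as real stacks clip nuclei at the first
and last slice); ground truth records rendered channel sums, nucleus count
and centers.

## Problem sizes and determinism

The test-suite and acceptance-script simulations use 100–250 cells per
population, 120–2000 genes, 150-barcode mixtures and 8×24×24-voxel stacks —
sizes chosen so the full suite completes in about a minute on one CPU while
leaving every statistical check well-powered (e.g. the 2000-gene null gives
a type-I estimate with Monte-Carlo s.e. ≈ 0.005). All stochastic tests fix
their seeds; the pipeline manifest records file hashes so a rerun with the
same config is verifiably identical.

## Known limitations

- The hurdle test is a fully specified stand-in for hurdle *regression*:
  it cannot adjust for covariates or random effects, and its combined
  p-value is mildly conservative.
- Tabulated fold changes from other toolchains are not bit-reproducible
  here (pseudocount and shrinkage conventions differ); only sign and
  approximate magnitude are comparable.
- The normalization is linear in the ribosomal covariate; nonlinear
  confounding would leave residual structure.
- Enrichment treats pathways independently (no GO-graph propagation or
  redundancy reduction) and ignores gene–gene correlation.
- Nucleus counting is plain connected components: touching nuclei merge,
  which the generator avoids but real images may not.
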