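# Methods

This note documents the models, numerical conventions and design choices
behind `phyllo`, and what the synthetic-data tests do and do not establish
about real data.

## Black-carbon quantification

Black carbon on leaf surfaces emits white light under femtosecond pulsed
illumination, so particles appear as compact bright blobs over a dim
autofluorescence background in a confocal z-stack (default geometry:
1.8 µm in-plane pixels, 6.6 µm z step, ~25 slices over a 900 × 900 µm
field). Quantification proceeds as:

1. maximum-intensity projection along z — a particle visible in a single
   slice survives;
2. thresholding at `threshold_frac` of full-scale detector intensity
   (default 0.0128, i.e. 1.28% of `2^bit_depth − 1`). The threshold is an
   **absolute** background-removal cutoff, not a per-image quantile: it is
   a one-time instrument calibration. Pixels strictly *above* the cutoff
   are foreground; a pixel exactly at the cutoff is background (the image
   bit depth, default 8, and the strictness are both configurable);
3. connected-component labelling of the foreground (8-connectivity by
   default, 4 available) via `skimage.measure.label`;
4. metrics: particles per mm² (component count over imaged area,
   rows × cols × pixel² / 10⁶) and % leaf area covered (labelled-pixel
   fraction × 100). Particle area is measured in the 2-D projection, since
   the reference quantity — leaf area — is two-dimensional.

Location comparisons use the Kruskal–Wallis rank-sum omnibus test followed
by pairwise Wilcoxon rank-sum tests with BH adjustment, the appropriate
choice for the small, skewed replicate sets this design produces
(18 technical replicates per location: 3 stacks × 3 biopsies × 2 leaves).

## Community analysis

The analysis order is: rarefy → Good's coverage check → alpha diversity
(+ between-site rank tests) → singleton removal → genus collapse → core
extraction → Bray-Curtis → PCoA → PERMANOVA → enrichment screen.
Singleton removal (ASVs with a *total* count of exactly 1) precedes all
beta-diversity and enrichment steps; alpha diversity is computed on the
rarefied, unfiltered table. Whether alpha should instead follow filtering
is ambiguous in this design's tradition; both orders are supported and the
default is the one above.

* **Rarefaction** is a single without-replacement draw per sample
  (`multivariate_hypergeometric`), not an average over draws; the seed is
  recorded in the run manifest. `depth="min"` keeps every sample.
* **Shannon diversity uses log base 2** (bits). Rationale: diversity
  values of ~5.6 alongside ~79 observed ASVs are impossible in nats
  (ln 79 ≈ 4.4) but natural in bits — the convention of the major amplicon
  platforms this pipeline mirrors. Simpson is the Gini–Simpson index
  1 − Σ pᵢ².
* **Faith's PD** sums branch lengths of the minimal subtree spanning the
  observed tips *and the root* (default); a crown-group variant
  (`include_root=False`) stops at the observed tips' LCA.
* **PCoA** is classical scaling: Gower-centre −½D², eigendecompose, scale
  eigenvectors by √λ. Negative eigenvalues (Bray-Curtis is non-Euclidean)
  are reported but excluded from coordinates and proportions explained;
  a Lingoes correction is available but off by default.
* **PERMANOVA** uses the one-way distance-based pseudo-F
  (SS_between/(a−1)) / (SS_within/(N−a)) with SS terms from within-group
  squared distances. Sampled permutation p-values use (b+1)/(m+1), so p is
  never 0; fully separated groups report F = +∞ and tie against permuted
  +∞ values. With `strata`, labels shuffle only within blocks
  (e.g. within years). "Blocking by year" in the site test is additionally
  provided as independent per-year analyses, which is what the pairwise
  tables report.
* **Exact pairwise tests.** For a 4-vs-4 pair there are only 70 distinct
  label assignments, so the attainable p floor is 2/70 ≈ 0.0286 — and
  after BH over three pairs, ≈ 0.0429, just below 0.05. A Monte-Carlo
  estimate of that floor straddles the threshold run-to-run, which makes
  sampled pairwise tests unstable exactly where replicate-level field
  designs live. `pairwise_permanova` therefore enumerates **all** distinct
  assignments whenever their number is at most `n_permutations`
  (`method="auto"`); p is then the exact fraction of assignments with
  F ≥ F_obs, observed assignment included. `permanova` itself defaults to
  the sampled estimator; `method="exact"` is opt-in.
* **Wilcoxon rank-sum** p-values are exact (full enumeration of the U
  distribution via a prefix DP) for tie-free samples of ≤10 per group, and
  use the tie-corrected normal approximation with continuity correction
  otherwise. **Kruskal–Wallis** applies the average-rank tie correction
  with a χ² reference (an optional permutation p is provided). **BH** is
  the standard step-up procedure, clipped at 1.

## Persistent core

A genus is persistent at a site iff in *every* year it is present
(count ≥ 1 on the analysis-ready table, i.e. rarefied and
singleton-filtered) in at least 75% of that year's replicates. "At least
75%" is inclusive: with 4 replicates, 3/4 qualifies — an exclusive reading
would make the threshold unreachable except at 4/4. Whether persistence
should be assessed pre- or post-rarefaction is not dictated by the
procedure; the default is the analysis-ready table and both are supported.
The shared core is the intersection over sites; read fractions are taken
over the same table used for the persistence calls, and the ASV fraction
counts member ASVs of shared genera over all ASVs. Pairwise-exclusive
persistent genera (shared by exactly one site pair beyond the full core)
are reported alongside.

## Enrichment screen (LDA effect size)

Features are clade paths over the stacked ranks phylum→genus; per rank and
sample, relative abundances are rescaled to 10⁶, so a clade's value equals
the sum of its children. A feature is kept iff

1. the between-class (urban vs rural) Kruskal–Wallis p < α (0.05);
2. within every subclass (year) where both classes occur, the unpaired
   Wilcoxon rank-sum shift is significant at α *and* has the same sign.
   The subclass test is the unpaired rank-sum test — samples are not
   paired across classes, so a signed-rank pairing would be ill-defined;
3. the LDA effect size is ≥ `lda_min` (2.0 on the log₁₀ scale, the
   conventional inclusion threshold; the boundary is included, which is
   measure-zero for a continuous score).

The effect size follows the published LEfSe recipe: over `n_boot` (30)
class-balanced bootstrap resamples, fit the two-class discriminant
direction w from the pooled within-class covariance (ridge-regularised by
1e-6 × trace/dim to stay well-defined on sparse features), and score
feature i as the mean of |wᵢ| × (class separation along w) and the raw
class-mean difference, reported as log₁₀(1 + mean score). Features present
in fewer than 3 samples are dropped up front (sparsity guard,
configurable). Enrichment direction is the class with the higher feature
mean. Because clade abundances are compositional, strongly boosting one
clade deflates the rest — complementary enrichment in the other class is
expected, not an artefact.

## Synthetic data

The generator reproduces the study design: 3 sites (Rural, Inner-city,
Intersection) × 2 years (2014, 2016) × 4 replicates = 24 samples, with
library depths drawn log-uniformly over 2,907–34,895 reads (the ~12-fold
right-skewed spread typical of real runs).

Counts are Dirichlet-multinomial: per-sample composition
~ Dirichlet(α · 2^effects), counts ~ Multinomial(depth, composition).
`base_concentration` is the Dirichlet prior — a vector is used as the
per-ASV prior directly; a scalar (default **50**) broadcasts as the mean
per-taxon prior count, i.e. a total concentration of 50 × S. This yields
moderate replicate overdispersion (within-group Bray-Curtis ≈ 0.2–0.4),
consistent with field replicates taken from the same tree; reading the
scalar as the *total* concentration instead would make replicates nearly
unrelated (within-group BC ≈ 0.65) and no 4-replicate design could detect
anything — inconsistent with the kind of study this emulates. Replicate
overdispersion in such designs is not well constrained; the concentration
is deliberately exposed.

Genus base abundances are lognormal with shape `abundance_sigma = 2.0` —
a few dominant genera plus a long tail of rare ones, the canonical
amplicon abundance shape — so occupancy-based persistence genuinely
filters (roughly half the genera fail 75% occupancy at ~3k-read depth).
ASV shares within a genus are lognormal (σ = 0.7). Site/year effects
multiply genus proportions by 2^lfc before renormalisation, so planted
effects are exact on the composition scale; `urban_site_effects` plants
the standard condition of ±1.5 log₂ on 10 random genera at both urban
sites. Trees are star (unit branches; closed-form PD) or Kingman
coalescent (dendropy) over the ASVs.

Z-stacks plant spheres in physical coordinates: with the default
anisotropy (z step ≈ 3.7 × the xy pixel) a radius-2 px particle
intersects exactly one slice, deliberately exercising the projection
step. Centres keep ≥2 background pixels between discs and particles are
strictly supra-threshold, background strictly sub-threshold, so planted
count = component count by construction; impossible packings raise rather
than truncate.

**What passing tests do not show:** the generator has no read-level error,
chimeras, taxonomy misclassification, spatial autocorrelation between
replicates, or compositional zero-inflation beyond what the DM model
produces; BC stacks have no autofluorescence bleed-through or out-of-focus
halos. Recovery rates measured here are upper bounds for real data.

## Problem sizes and determinism

Default inferential settings are 999 permutations, α = 0.05,
LDA ≥ 2.0, 30 bootstrap iterations. The verification suite runs the
particle-recovery check on 100 stacks of 192 × 192 × 8 px, the PERMANOVA
null calibration on 500 simulated 12-sample datasets at 199 permutations,
and the planted-effect power study on 100 independent 24-sample datasets —
sizes chosen to make Monte-Carlo bounds tight while the whole suite stays
in the minutes range on one CPU. Every random stage takes an explicit
seed; the pipeline derives all stage seeds from one global seed and
records them in the run manifest, making reruns byte-identical.
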