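# Methods

This note records the models, the parameters that matter, the numerical
choices, and the limits of what a green test establishes.

## Leaf morphometrics

**Straightening.** The mid-vein polyline is resampled at 1-px arc-length
steps; every outline vertex maps to (arc length of its nearest vein
point plus its tangential residual, signed perpendicular offset), and the
transformed polygon is re-rasterised. This removes smooth bends
introduced by pressing/drying while preserving area to within a few
percent. Self-intersecting outlines and zero-length veins are rejected.

**Dissection index.** LDI = P²/(4πA), the isoperimetric quotient: 1 for
a circle, scale-invariant, unbounded above with increasing incision.
Contours extracted from binary masks are Gaussian-smoothed (σ = 2 px,
`mask_to_contour`) before measurement: the raw marching-squares contour
is a staircase whose length overestimates the true perimeter by ~11%
*independent of resolution*, which would bias every LDI upward (a
rasterised circle scores ~1.11 unsmoothed, 1.001 smoothed).

**Elliptic Fourier descriptors.** The Kuhl–Giardina closed-contour
formulation with chord-length parameterisation, 20 harmonics
(A_n, B_n, C_n, D_n). Normalisation removes start-point, rotation, and
scale, pinning (A₁, B₁, C₁) = (1, 0, 0); the feature vector is the
remaining 77 coefficients in fixed order (D₁, A₂..D₂, …, A₂₀..D₂₀). Two
numerical points:

* the normalisation equations admit a residual half-turn symmetry
  (start-point + orientation shifted by π together), which negates every
  even harmonic; we canonicalise by making the first even-harmonic
  coefficient exceeding 1e-7 positive, giving invariance to rotation,
  scale, and start-point to ≤ 1e-6;
* under chord-length parameterisation an ellipse is *not* a pure
  first-harmonic object (the coordinate functions are not sinusoidal in
  arc length): a 2:1 ellipse retains a third harmonic of ~0.07 relative
  to A₁. The implementation is verified harmonic-by-harmonic against an
  independent FFT of the chord-parameterised coordinate functions; D₁
  approximates the minor/major ratio with an O(eccentricity²) bias.

**Tests.** Shape PCA is centred but not re-standardised (normalised EFA
coefficients are already commensurate). The permutation statistic is the
mean cross-taxon Euclidean distance in PC space (a cross-minus-within
variant is selectable); rows are canonically ordered internally so the
p-value is invariant to input row order. NPMANOVA uses Anderson's
pseudo-F computed from the distance matrix and reduces exactly to the
classical one-way ANOVA F on 1-D Euclidean data. Welch's t uses the
Welch–Satterthwaite df. Permutation p-values are (1 + #{T* ≥ T})/(B + 1);
all pairwise tables are Bonferroni-corrected with m = number of taxon
pairs and truncated at 1. Defaults: 20 harmonics, 15 PCs, B = 5000
(shape permutation), B = 100 (NPMANOVA), α = 0.01.

## Nei distances and ordination

Per-accession allele frequencies are dosage/ploidy, so diploids and
tetraploids are directly comparable. For a pair, J terms are averaged
over pairwise-complete sites (missing calls are never imputed); pairs
sharing fewer than `min_shared_sites` (default 50) are flagged, pairs
sharing none get NaN. Since −ln I diverges for allele-disjoint samples, D
is capped at `d_cap` = 10 (recorded in the result object). Frequencies
may optionally be pooled per taxon before the distance.

PCoA double-centres −½D² and eigendecomposes. When λ_min < −1e-8 the
Lingoes correction is applied as d′² = d² + 2c with c = |λ_min| — the
additive constant that shifts all non-trivial eigenvalues by exactly +c
and makes the configuration Euclidean (adding c instead of 2c, a reading
the wording of some descriptions invites, shifts them by only c/2 and
leaves negative eigenvalues behind). Scores for λ > 0 reproduce the
corrected distances to 1e-6; `n_axes_50` is the smallest axis count
reaching half the (corrected) variance and defines the clustering input
space.

## Consensus clustering (WKM)

Each of `n_runs` (default 5000) k-means runs draws ⌈0.60·d⌉ features and
⌈0.80·n⌉ samples without replacement and k ~ U{2..14} (capped at subset
size − 1 so the silhouette stays defined), k-means++ init, ≤ 300
iterations. The run weight is

    w = ((s̄ + 1)/2) · Q · geomean(q_c)

with s̄ the mean silhouette, Q = 1 − (violated / applicable constraint
weight) the clustering-level consistency, and q_c its per-cluster
restriction (Q = 1 with no applicable constraints). The product form is
one reasonable reading of "non-linearly combined" and is isolated behind
`combine_weight` so alternatives can be swapped; it is recorded in the
model object. Weighted co-assignment evidence accumulates only over
co-sampled pairs; C_ij = M_ij/N_ij with unit diagonal. A consequence
worth knowing: with k drawn above the true cluster number, runs
legitimately split true clusters, so within-cluster consensus values sit
well below 1 (≈ 0.5 for two blobs with k ≤ 6) while across-cluster
values stay near 0 — the signal is the margin, not C ≈ 1.

Consensus partitions are average-linkage cuts of 1 − C at each k, scored
on the input scores by the Calinski–Harabasz index (higher better) and by
a spherical-Gaussian BIC (lower better): shared MLE variance
σ² = SS_w/(d(n−k)), log-likelihood with the assignment term
Σ n_c ln(n_c/n), and k(d+1) parameters. The naive
n·d·ln(SS_w/(nd)) + k·d·ln n variant was tried first and is monotone
decreasing in k on well-separated low-dimensional score configurations
(its argmin always hits k_max on planted-structure data), so it cannot
recover a planted cluster number; the X-means-style form recovers a
planted k = 4 in 10/10 seeds. Ties in both optima resolve toward smaller
k (parsimony).

## SNP-category parentage scan

Per site and per (p1, p2, child) individual triplet, with both parents
required homozygous (fixed for single alleles a, b — any allele, not
necessarily the reference): child fixed for a → CAT1, fixed for b →
CAT2, carrying any allele outside {a, b} → CAT34 (derived; categories 3
and 4 are not separable without phasing, and the novel-allele case is
classified CAT34 even when a ≠ b for exhaustiveness), carrying exactly
{a, b} with a ≠ b → CAT5 (homeo-SNP). Anything missing or a
heterozygous parent is unclassified; a = b with a fixed-a child is
monomorphic, not a SNP. Proportions are per child individual over its
classified sites, then averaged arithmetically across child individuals;
the scan evaluates all unordered candidate pairs and sorts by mean CAT5.
Swapping parent order swaps CAT1↔CAT2 and leaves CAT34/CAT5 unchanged.

## Niche modelling and geography

Environmental layers are standardised over valid cells (constant layers
dropped), soil-depth triplets averaged per variable beforehand, and the
first three PC rasters retained. The default suitability model is a
deliberately simple deterministic Gaussian envelope — χ²_df=3 survival of
the Mahalanobis distance to the occurrence centroid in PC space (a small
ridge, 1e-6·I, stabilises the covariance) — so the comparison framework
is testable without a MaxEnt binary; a presence–background regularised
logistic model (1000 background points within 20 km of occurrences,
latitude-corrected) and an adapter for externally computed grids are
alternatives. A taxon occupying a single raster cell raises
`NicheUndefinedError` and propagates as "n/a" through every pairwise
table (the point-endemic case).

Overlap uses surfaces normalised to sum 1 over shared valid cells:
Schoener's D = 1 − ½Σ|p−q| and Warren's I = 1 − ½Σ(√p−√q)², with
0 ≤ D ≤ I ≤ 1 and invariance to positive rescaling. The equivalency test
pools occurrences, re-splits preserving group sizes (200 replicates),
refits both models, and is one-tailed: equivalency is rejected when the
observed overlap is *lower* than the pooled null, p = (1 + #{stat* ≤
obs})/(B + 1).

Occupied ranges binarise suitability at 0.25, take 8-connected
components, and keep only components containing an occurrence cell;
occurrence cells below threshold are retained as singletons (an occupied
cell is by definition part of the realised range). Overlap is
|A∩B|/min(|A|,|B|) so a narrow endemic nested in a widespread taxon
scores 1 (Jaccard selectable). The sympatry null permutes taxon labels
over the pooled points (400 replicates), rebuilding both pruned ranges
each time; a small p means deviation from sympatry, i.e. allopatry.

## Rank integration

Axis flags derive only from Bonferroni-corrected p-values at α (default
0.01); GEN is significant iff the taxa occupy different consensus
clusters at the BIC-optimal k; "n/a" maps to not-testable. The ordered
rules: a declared hybrid-swarm override on a genetically distinct pair
forces subspecies *before* the species rule fires (taxa that blur into
introgressive swarms on contact are kept at subspecific rank for
conservative reasons — without this precedence the documented case could
never apply, since such pairs can be significantly allopatric overall);
genetic distinctness plus any ecological or morphological signal →
distinct species; genetic homogeneity plus allopatry (or untestable
endemicity) plus eco/morph signal or a declared edaphic difference →
subspecies; all axes silent → conspecific; genetic distinctness alone →
species; the remainder → conspecific. Overrides are explicit named
inputs, never inferred. Merging non-species pairs (union–find) yields the
species arrangement. Decisions are a pure function of the evidence
matrix and overrides.

## Synthetic data: what it does and does not establish

Genotypes follow a Balding–Nichols-style model: site-wise ancestral
frequency p₀ ~ U(0.05, 0.95), taxon frequency ~ Beta with concentration
(1−F)/F (one interpretable differentiation parameter F; default 0.2 in
the planted-recovery scenarios), diploid dosage ~ Bin(2, p),
allotetraploid = Bin(2, p_parent1) + Bin(2, p_parent2), autotetraploid ~
Bin(4, p_taxon), uniform missingness. Sites are unlinked — no LD, no
coalescent gene trees, no RADseq locus dropout structure. A green
recovery test therefore establishes that the pipeline detects
frequency-pattern structure of the stated strength, not that it would
resolve a particular empirical system. Individual-level Nei distances
retain a positive baseline from binomial genotype sampling even at F → 0
(undifferentiated taxa show between ≈ within, not D ≈ 0); and an
autotetraploid is genetically inseparable from its source taxon by
construction — the realistic hard case for the genetic axis.

Leaves are radial outlines r(θ) = R·e(θ)·(1 + a·sin(mθ + φ)) with
elongation e, dissection amplitude a < 1, lobe count m, per-leaf jitter
(5%), and optional circular-arc bending applied to outline and vein (the
unbent mask is kept as ground truth for straightening tests). They lack
petioles, teeth hierarchies, and venation beyond the mid-vein.
Landscapes are gradient-plus-smoothed-noise layers with Gaussian niches
in environment space and suitability-proportional occurrence sampling
under sympatric / allopatric / parapatric / point-endemic scenarios;
spatial autocorrelation of occurrences beyond the niche itself is not
modelled. All generators are deterministic under a fixed seed and
serialise their parameters (SimTruth JSON).

## Known limitations

* MaxEnt itself is not implemented; results with the envelope model are
  for the comparison framework, not SDM benchmarking.
* GeoTIFF raster I/O is not supported (no geospatial raster library in
  the dependency set); ESRI ASCII grids are the interchange format.
* Categories 3 and 4 are never separated (unphased data).
* The consensus-matrix heatmap and stacked-bar figures are plain
  matplotlib renderings of the exported CSVs; the CSVs are the interface.
* Range approximation inherits every bias of the underlying suitability
  model; with few occurrences the pruned range is conservative.
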