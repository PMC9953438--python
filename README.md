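# polyrank

Integrative species delimitation for mixed-ploidy plant complexes.

Polyploid lineages are hard to rank taxonomically: a newly formed
tetraploid is reproductively isolated from its diploid parents
immediately, but morphological, ecological, and genetic differentiation
may lag far behind — and coalescent-based delimitation tools are not
available for polyploid genotype data. `polyrank` implements the
pattern-based alternative: it scores a set of predefined morphotaxa on
four independent axes of evidence — genetic, geographic, ecological, and
morphological — and feeds the per-pair significance pattern to an
explicit, ordered rule engine (a four-axis "tesseract" of rank
decisions) that recommends *distinct species*, *subspecies of one
species*, or *conspecific* for every taxon pair.

## What it computes

**Morphology.** Leaves annotated with an outline polygon and a main-vein
polyline are straightened into a vein-aligned frame, then summarised by
the leaf dissection index

    LDI = P² / (4 π A)

(perimeter P, area A; 1 for a circle, growing with lobing) and by 20
normalised elliptic Fourier harmonics (Kuhl–Giardina; normalisation pins
A₁ = 1, B₁ = C₁ = 0, leaving 77 shape descriptors that are decorrelated
with a centred PCA). Taxon pairs are compared with Welch's *t* on LDI, a
permutation test on mean cross-taxon Euclidean distance in PC space, and
a distance-based non-parametric MANOVA (Anderson's pseudo-F), all
Bonferroni-corrected.

**Genetics.** From a mixed-ploidy VCF (diploid `0/1` and tetraploid
`0/0/0/1` calls), per-accession allele frequencies x = dosage/ploidy give
Nei's (1972) standard distance over pairwise-complete sites,

    I = J_xy / √(J_x J_y),   D = −ln I,

which is directly comparable between ploidy levels. Distances are
embedded by principal coordinate analysis with the Lingoes
negative-eigenvalue correction, and the PCo scores covering ≥ 50% of the
variance enter a weighted ensemble of random-(k) k-means (WKM): 5000
k-means runs on random feature/sample subsets with k ~ U{2..14}, each
weighted by silhouette and by consistency with fuzzy must-link /
must-not-link constraints, accumulated into a consensus co-association
matrix. Average-linkage cuts of the consensus matrix are scored by BIC
and the Calinski–Harabasz index to choose the number of genetic clusters.
Distance matrices export to NEXUS/PHYLIP for external network viewers.

**Parentage.** For a (diploid, diploid, tetraploid) triplet, every SNP
where both parents are homozygous falls into category 1/2 (child fixed
for one parent's allele), 3+4 (allele unique to the child), or 5
("homeo-SNPs": the child combines both parents' alleles — the signature
of recent allopolyploidy). Scanning all candidate diploid pairs and
ranking by mean category-5 share proposes the parents of each tetraploid.

**Ecology and geography.** Environmental rasters are reduced to three
standardised principal-component layers; a pluggable suitability model
(default: a Gaussian envelope via the χ² survival function of Mahalanobis
distance, with a presence–background logistic model and an external-grid
adapter as alternatives) yields niche overlap as Schoener's D and
Warren's I, tested by the niche-equivalency permutation test (pooled
occurrences re-split, 200 replicates). Occupied ranges are suitability ≥
0.25, pruned to the 8-connected components that contain collection
points; range overlap |A∩B|/min(|A|,|B|) is tested against a
label-permutation null (400 simulated datasets) for sympatry vs
allopatry.

**Integration.** Per-pair significance flags on all axes (α = 0.01)
plus explicitly declared overrides (`hybrid_swarms`, `edaphic_distinct`)
drive the ordered rule engine; merges implied by subspecies/conspecific
recommendations yield the final species arrangement.

## Worked example

Everything runs end-to-end on synthetic data (the `polyrank.synthetic`
module generates mixed-ploidy genotypes with planted taxon structure,
parameterised leaf silhouettes, and gradient landscapes with Gaussian
niches):

```python
from polyrank.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=7, out_dir="run", n_diploid_taxa=3,
                samples_per_taxon=6, n_sites=600, leaves_per_taxon=15,
                grid_shape=(24, 36), n_occ_per_taxon=25,
                n_perm_shape=999, wkm_runs=1000,
                niche_reps=100, sympatry_sims=100)
summary = run_pipeline(cfg)
```

This prints (seed 7; a world with three diploid taxa, one allotetraploid
child of taxon00 × taxon01, and one autotetraploid derived from taxon02):

```
parent1 parent2          child  cat1  cat2  cat34  cat5  n_sites
taxon00 taxon01 allotetraploid 0.043 0.043  0.579 0.336      600
taxon00 taxon02 allotetraploid 0.072 0.030  0.611 0.287      600
taxon01 taxon02 allotetraploid 0.071 0.031  0.619 0.279      600

arrangement: [['allotetraploid', 'taxon00'], ['autotetraploid', 'taxon02'], ['taxon01']]
```

The true parent pair (taxon00, taxon01) ranks first by mean homeo-SNP
(category 5) proportion. The autotetraploid merges with its source taxon
in the arrangement — it draws from the same allele-frequency pool, so the
genetic axis cannot separate them, which is precisely the autopolyploid
ranking problem the four-axis protocol exists to arbitrate. `run/`
contains the pairwise morphology table, the NEXUS distance export, the
consensus matrix and per-k BIC/CH curves, the parentage scan, the
evidence matrix, the per-pair rank decisions, and a Markdown report.

The same pipeline is available from the shell:

```sh
polyrank all --config run.yaml --seed 7 --out run
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on a seed-derived synthetic
dataset — synthesis, morphometrics, Nei distances + PCoA, WKM consensus
clustering, the parentage scan, niche-equivalency and sympatry tests,
and rank integration — at the protocol's default analysis parameters,
and writes the result JSON to `--out`.
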