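# Methods

`forestscan` implements a genome scan that finds regions distinguishing two
(or more) groups of resequenced accessions by training many randomized
tree-ensemble classifiers on a genotype dosage matrix, plus two companion
analyses: admixture-profile relatedness and least-cost coastline distances
for isolation-by-distance studies. This note records the models, the
defaults and the design choices in enough detail to reproduce or audit any
number the package prints.

## Genotype encoding and missing data

All scans consume an `n_samples x n_variants` integer matrix of
alternate-allele dosages at biallelic sites: hom-ref 0, het 1, hom-alt 2.
VCF genotypes map as `0/0 -> 0`, `0/1`/`1/0` (phased or not) `-> 1`,
`1/1 -> 2`; any genotype containing a missing allele becomes the sentinel
`-1`. Multiallelic records are dropped by default; optionally the dosage of
the first ALT allele is counted. On disk the matrix uses the 012 triplet
dialect (`.012` with `-1` for missing, `.012.indv`, `.012.pos`).

Models never see the sentinel: imputation is an explicit, logged step.
The default `most_frequent_per_variant` replaces missing entries with the
variant's modal observed dosage (ties resolve to the smaller dosage;
all-missing columns fall back to 0 with a warning). `zero_fill` is
available for callers who prefer treating missing as hom-ref. Imputation
choice matters little at the few-percent missingness the scan targets,
because trees split on dosage thresholds and a small minority of imputed
entries rarely moves a split.

Coordinates are 1-based (VCF convention) everywhere except inside window
arithmetic and interval reports, which are 0-based half-open.

## The forest ensemble

The scan trains `n_models` independent classifiers (default 42). Each
model:

1. draws its own stratified train/test split (default 75% train); each
   class's train share is within one sample of the target fraction
   (round-half-up, both sides non-empty);
2. grows `n_trees` CART trees (default 5000, Gini impurity). Every tree
   receives a bootstrap resample of the training samples and — the key
   departure from a stock random forest — its own uniform random subset of
   `ceil(feature_fraction x n_variants)` variant columns, drawn once per
   tree (default 5%). Within that subset split search is exhaustive.
   Subsetting per tree rather than per split caps how often any one tight
   LD block can dominate, so importance mass spreads across linked
   variants instead of collapsing onto one tag SNP;
3. predicts by majority vote over trees; exact vote ties resolve to the
   lowest class label (deterministic);
4. scores per-variant importance as the mean over trees of the tree's
   normalized impurity decrease, with variants outside a tree's subset
   contributing zero for that tree. The mean is taken over trees that made
   at least one split, so each model's importance vector is nonnegative
   and sums to 1; trees that never split (possible on degenerate
   bootstraps) contribute nothing.

Across models the per-variant maximum is kept ("deduplicated importance"):
when several models detect the same variant, the strongest detection
counts. The ensemble also tallies, per sample, in how many models it was
misclassified while in the test set — samples misclassified by many
independent splits are candidate label errors, hybrids or outliers — and
logs the minimum test-set membership per sample as a diagnostic.

Model seed `i` is `base_seed + i` and drives both the split and all tree
randomness, so any single model can be re-run in isolation. Class
imbalance is not reweighted by default; a `balanced` class-weight option
applies inverse-frequency sample weights per bootstrap.

Test and acceptance runs use a scaled ensemble — 12 models of 300 trees on
20,000 variants for 200 samples — chosen as the smallest configuration at
which the planted-signal recovery and null-calibration properties are
stable across seeds; the 42 x 5000 defaults remain the recommended
analysis configuration.

## Window aggregation and thresholds

Deduplicated importances are summed in sliding windows of 5000 bp with a
2500 bp offset per scaffold, windows starting at 0, 2500, 5000, ... Every
position from 2500 bp onward is covered by exactly two windows; the stripe
before the first offset is covered once (the identity
`sum(window sums) = 2 x total importance - first-stripe mass` is verified
by a brute-force audit in the tests). The last window may overhang the
scaffold end.

Two threshold modes:

* **Fixed factor** (default for two-group domestication-style scans): a
  window is eligible if it holds at least `min_variants` variants
  (default 10); the threshold is `factor` (default 2.5) times the mean
  importance sum over eligible windows; eligible windows strictly above
  the threshold are called. The `min_variants` rule gates both the
  averaging set and callability, so long variant-free stretches cannot
  deflate the mean.
* **Permutation** (default for small-group scans where the fixed mean is
  noisy): the nonzero ("detected") importance values are shuffled across
  their variant positions `n_permutations` times (default 10,000),
  positions held fixed, zero-importance variants held at zero; each
  window's null distribution of sums is accumulated and the window is
  called when its observed sum strictly exceeds its own empirical
  `percentile`-th order statistic (default 99th, type-1 quantile). The
  null is per-window because windows differ in variant count. With all
  importances equal, every permutation reproduces the observed sums and
  nothing is called. Under an exchangeable null, the expected called
  fraction is `(floor(n(1-p/100)) + 1)/(n + 1)` — about 1.1% at p = 99,
  n = 1000 — which the calibration tests track.

Ties at either threshold are not called (strict `>`). Called windows that
overlap or abut on a scaffold merge into regions by interval union;
region length is at least the window size. Regions intersect gene models
(GFF3, converted to 0-based half-open) by >= 1 bp overlap. A top-variant
table unions each model's single best variant with the global top-k by
deduplicated importance.

## Admixture profiles

A profile is a K-vector of ancestry proportions (K = 16 by default)
summing to 1. Relatedness is the profile overlap
`r(A, B) = sum_k min(q_Ak, q_Bk)`, the intersection of two probability
vectors; `1 - r` equals half the L1 distance and is therefore a proper
metric (triangle inequality asserted on random triples in the tests).
PCA runs on the raw mean-centred proportions — no per-column scaling,
since proportions share a unit — with each component's sign fixed so its
largest-magnitude loading is positive, making coordinates deterministic.
Rule-based selection returns all samples whose proportion of one ancestry
is at least a threshold (inclusive), with the per-sample fractions
reported for audit.

## Geographic distances

Linear distances are great-circle (haversine) on a sphere of radius
6371.0088 km; the ellipsoidal correction (<= 0.5%) is out of scope.

Coastline distances use a cost raster: a coastline polyline is rasterized
at 0.05 degrees/cell (default); cells whose center lies within half the
coast width of the line are *coast*, remaining cells are *land* on one
declared side and *sea* on the other. Costs per class default to land
99999, coast 1, sea 500 — land effectively impassable, open-sea crossings
500x dearer per km than hugging the shore. Classification by cell center
makes the coast cell set monotone in width. The traversal graph is
8-connected; a step costs the mean of the two endpoint cell costs times
the step length (`resolution x 111.1949 km/degree`, `x sqrt(2)`
diagonally). The reported distance between two samples is the minimum
accumulated cost of a path between their snapped coast cells (Dijkstra;
samples snap to the nearest coast cell within 2 cells, else an error
names them). "Minimum score" rather than "geometric length of the
minimum-score path" is the reported quantity: the score is what the
optimization defines, and it is a metric by construction, whereas the
length of an argmin path is unstable under ties. Exactness is checked
against an independently enumerated Dijkstra oracle on small random
grids.

Correlation of relatedness against either distance is Pearson over the
upper triangle of sample pairs (optionally restricted to pairs involving
a reference sample); non-finite distances (disconnected pairs) are
dropped.

## Association comparator

The univariate baseline is a per-variant Wald test of the dosage
coefficient in a linear probability model of the 0/1 group label, with an
intercept and optionally the top principal components of the centred
genotype matrix as fixed covariates, and a Bonferroni threshold of
`alpha / n_variants`. This is a deliberate simplification of a mixed-model
GWAS: PCs stand in for the kinship random effect, keeping the comparator
vectorized and desk-scale. Monomorphic variants, and variants fully
absorbed by the covariates, are flagged with p = 1.

Two calibration caveats are inherent and documented rather than patched:

* With integer dosages the Wald statistic has an atom at zero — the two
  groups' dosage sums tie exactly with probability of a few percent per
  variant — so the null p-value distribution carries an atom at 1.0. Tail
  calibration (`P(p < alpha) = alpha`) holds at all practical alpha, but
  a Kolmogorov–Smirnov test against the uniform will reject at large
  variant counts on this discreteness alone.
* When the phenotype *is* the group membership (as in these scans),
  genotype PCs partially absorb the signal under test; PC correction is
  for confounding substructure, not for the contrast itself.

## The synthetic-data generators

Generators are pure functions of (spec, seed); identical inputs give
bit-identical output. They emulate only the statistical features the
pipeline consumes:

* **Genotypes** — background variants are i.i.d. `Binomial(2, maf)` with
  maf drawn uniformly from a configurable range, shared across groups
  (no group signal); each planted causal block places consecutive
  variants with alternate-allele frequency `f_A` in one group and `f_B`
  in the other; within a block each variant copies its left neighbour's
  entire genotype column with probability `ld_copy_prob` (at 1 the block
  is one repeated column, at 0 independent draws) — a cheap, controllable
  stand-in for LD block structure; missing calls are planted uniformly at
  random. Not modelled: realistic site-frequency spectra, selfing,
  within-group substructure, recombination maps, or sequencing error.
  The standard test panel (2 x 100 samples, 20,000 variants on four
  1.25 Mbp scaffolds, five 10-variant blocks at frequencies 0.05/0.9,
  `ld_copy_prob` 0.5, 2% missing) puts ~20 variants in a 5 kbp window, so
  a block spans less than one window.
* **Admixture** — per group, the dominant component receives a fixed
  mass and the remaining mass is spread over the other K-1 components by
  a symmetric Dirichlet draw.
* **Coast** — a polyline coastline rasterized as above, with samples
  placed evenly by arclength and planted relatedness
  `exp(-d_alongcoast / decay)`. The canonical fixture is a U-shaped bay
  whose arm tips are ~2 degrees apart in a straight line but ~7.5 degrees
  along the coast with a 5-degree decay length, so the coastline distance
  explains the planted relatedness visibly better than the linear one.
  Because the planted decay follows the exact polyline arclength, the
  correlation magnitude declines slowly and monotonically as the coast
  band widens (the narrowest corridor tracks the polyline best); an
  interior optimum over widths, as seen in real dispersal data, requires
  dispersal noise this fixture does not model.

Consequently, passing tests demonstrate that the machinery — encoding,
splitting, training, aggregation, thresholding, merging, distances —
behaves exactly as specified on data whose generative process is known;
they do not certify performance on real panels, where LD, substructure
and label noise are richer.

## Reproducibility and numerics

* Every pipeline stage derives its sub-seed as
  `sha256(global_seed:stage_name) mod 2^31`, so changing one stage's
  parameters never perturbs another stage's random stream; manifests
  record sub-seeds and input/output checksums and contain no timestamps,
  making reruns byte-identical.
* Permutation null sums are accumulated in float32 (memory-bounded) and
  the observed sums are compared in float32 as well, so exact null ties
  are never called.
* Degenerate inputs have defined behaviour: empty matrices round-trip
  through the 012 format; constant profile matrices give all-zero PCA
  coordinates; unreachable sample pairs get infinite distance with a
  warning and are dropped from correlations; classes with one sample are
  rejected by name.

## Limitations

Multiclass scans are pairwise by design; one-vs-rest is out of scope.
VCF filtering/QC is the caller's responsibility — the scan consumes an
already-filtered call set and applies no MAF or missingness filters. The
association comparator is not a mixed-model implementation. Raster I/O is
ESRI ASCII grid; the geometry utilities use planar degree arithmetic
within the narrow extents typical of a coastal study region.
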