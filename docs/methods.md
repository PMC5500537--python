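# Methods

## Scope and model

`comodule` implements weighted gene co-expression network analysis
(WGCNA-style) for two-group transcriptome studies — the motivating use
case is liver biopsies from mild (fibrosis stage 0–1) versus advanced
(stage 3–4) fatty liver disease. Given a gene × sample log2 expression
matrix X and a binary severity code y, the analysis proceeds:

1. **Network.** Pearson correlation r_ij between genes; unsigned
   adjacency a_ij = |r_ij|^β with β the smallest integer power whose
   network satisfies the scale-free topology criterion (signed R² of the
   log–log degree regression ≥ 0.9, grid 1–20). The topological overlap

       TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
       ℓ_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{j≠i} a_ij

   combines direct adjacency with shared-neighbour weight; 1 − TOM is
   the clustering dissimilarity.
2. **Modules.** Average-linkage hierarchical clustering on 1 − TOM,
   dynamic tree cut (below), size-ordered colour labels (largest =
   turquoise; grey = unassigned). Each module is summarised by its
   eigengene (first principal component of the standardised module
   expression, unit variance, oriented so mean gene–eigengene
   correlation is positive). Module membership kME_i,m = cor(x_i, ME_m);
   genes whose own-module |kME| < 0.7 are returned to grey in a single
   pass (eigengenes are not recomputed — the rule is a membership
   filter, not an iteration).
3. **Trait association.** Gene significance GS_i = cor(x_i, y)
   (point-biserial, signed); module–trait correlation cor(ME_m, y) with
   two-sided Student-t p; module significance = mean |GS| per module;
   meta-modules = maximal eigengene-dendrogram subtrees with all
   pairwise eigengene correlations > 0.5 (the standardised trait joins
   as a pseudo-eigengene); intramodular connectivity
   K.in(i) = Σ_{j∈module(i), j≠i} a_ij; hub genes = top of the K.in and
   GS rankings, with the intersection flagged as consensus hubs.
4. **Preservation.** See below.
5. **Enrichment.** One-sided Fisher/hypergeometric over-representation
   against user GMT libraries, EASE variant (overlap − 1) by default,
   BH across the library, and an Enrichr-style combined score
   C = ln(p)·z where z is the deviation of a set's observed rank from
   its expected rank under size-matched random queries (z < 0 when the
   set ranks better than chance, so enriched sets get large positive C;
   natural log, and p = 1 forces C = 0).

Differential expression uses a moderated t by default: per-gene pooled
variances are shrunk toward a scaled inverse-chi-square prior whose
degrees of freedom and scale are estimated by method of moments on the
log variances (digamma/trigamma matching), with the posterior variance
(d₀s₀² + d·s²)/(d₀ + d) and d + d₀ degrees of freedom. This reproduces
limma's eBayes t and p to machine precision on the same data (checked
in the test suite by running limma through Rscript). Pooled and Welch t
are available for hand-checkable examples. BH adjustment is the
standard step-up (delegated to statsmodels).

## Dynamic tree cut

No maintained Python implementation of the reference hybrid tree-cut
algorithm exists, so the package implements a simplified hybrid
variant:

* static cut at h = q₅ + 0.99·(h_max − q₅), where q₅ is the 5th
  percentile of merge heights — adaptive to the height range of the
  tree;
* flat clusters smaller than `min_cluster_size` (default 30) become
  grey;
* a branch-quality test: a cluster is accepted only when its mean
  internal dissimilarity (core scatter) stays below
  q₅ + c·(h − q₅) with c ∈ {0.64, 0.73, 0.82, 0.91, 0.95} indexed by
  `deep_split` (default 2). Diffuse clusters as loose as the cut itself
  — the signature of background noise that happens to agglomerate —
  are rejected;
* an optional PAM-like stage (off by default) assigns each grey gene to
  the nearest module by average dissimilarity when that distance is
  within the module's own radius (the maximum member-to-module average
  dissimilarity).

Defaults `min_cluster_size=30` and `deep_split=2` suit desk-scale
matrices of a few hundred to a few thousand genes.

## Module preservation

Whether reference-defined modules replicate in a test dataset is
quantified by seven statistics per module on the gene overlap — four
density statistics evaluated in the test data (mean within-module
correlation, mean within-module adjacency, eigengene variance
explained, mean signed kME) and three connectivity statistics measuring
agreement of gene roles between the datasets (correlation of
intramodular connectivity profiles, of kME profiles, and of the
vectorised within-module correlation matrices). Each observed statistic
is standardised against a permutation null of random same-size gene
sets drawn from all genes in the assignment (200 permutations by
default). Composites follow the standard construction: Zdensity and
Zconnectivity are the medians within each family, Zsummary their mean;
medianRank is the analogous rank-based composite (computed from the
observed statistics, so it is largely independent of module size).
Zsummary < 2 means no evidence of preservation, 2–10 weak-to-moderate
(boundaries inclusive), > 10 strong. This seven-statistic set is a
deliberate reduction of the much larger published battery: it covers
both families the composites require while staying cheap enough to
permute at desk scale. The test-network power defaults to the
reference's selected β.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
so every stage can be verified against planted truth:

* **Design.** 40 + 32 samples in two groups (the mild/advanced design
  of the motivating study); defaults plant seven modules of 600, 400,
  250, 150, 100, 60, 40 genes among ~3000 genes total, with
  eigengene–trait correlations ρ spanning −0.3 to 0.7 and 1400
  unstructured background genes.
* **Model.** Standardised trait t_s; module eigengene
  e_m = ρ_m t + √(1−ρ_m²) η with η ~ N(0,1); gene i of module m is
  baseline + noise_sd·(a_i e_m + √(1−a_i²) ε) with loading a_i uniform
  on (0.4, 0.95) by default — a hub-to-periphery gradient. Expected
  within-module correlation is a_i a_j and expected gene–trait
  correlation a_i ρ_m, which the tests exploit as closed forms.
* **Baseline 8.0 log2 units** so matrices resemble microarray
  intensities; **noise_sd 1.0**.
* **DEG genes** (default 150, +1 log2 unit in group 1) are drawn from
  the background so DEG-module overlap is controllable; a flag places
  them inside modules instead.
* **Determinism.** One RNG stream per module (spawned from the seed),
  so a module's data do not depend on how many other blocks exist.
  `generate_preserved_pair` shares the per-gene loadings between the
  two draws (hub structure replicates) while the noise is independent;
  scrambled modules are regenerated as pure noise — ground-truth
  "not preserved".

What the generator does **not** emulate: probe-level artifacts, batch
effects, intensity-dependent variance, correlated background structure,
or non-normal noise. Passing tests therefore demonstrate correctness of
the algorithms under the model's assumptions, not robustness to the
messiness of real microarray data.

## Numerical and design choices

* **Unsigned network** by default (|r|^β): consistent with negative kME
  values co-existing with module membership; signed available.
* **Scale-free fit**: 10 equal-width connectivity bins, regression of
  log10 bin frequency on log10 bin-mean connectivity over non-empty
  bins, fit index −sign(slope)·R². Degenerate (single-bin) degree
  distributions are an error.
* **β selection** takes the smallest qualifying power; when no power
  reaches the cut the maximiser is returned with a flag. On small
  matrices the criterion can select a high power, which thins the
  network and can shrink detected modules — visible in the stability
  diagnostics rather than hidden.
* **Gene filter**: mean ≥ median of gene means, then variance strictly
  above the survivors' mean variance; if the strict filter empties the
  set (all variances equal) the mean-filter survivors are kept with a
  warning. Probe collapse keeps the probe with the highest mean
  (lexicographic tie-break).
* **Outlier samples**: average-linkage on Euclidean distance of
  per-gene standardised expression; a sample is flagged when its leaf
  joins the tree above mean + 2.5·sd of all merge heights (`cut_z`
  overridable).
* **Grey reassignment boundary**: strict (<0.7 goes grey; exactly 0.7
  is retained).
* **GS/MM correlations** are computed on signed values by default with
  an `absolute=True` option — module significance always uses |GS|.
* **Eigengene sign ties** (mean kME exactly 0, e.g. a two-gene module
  with r = −1) break toward the first gene positive.
* **Hub ranking ties** in K.in break by GS, then gene ID.
* **Zero null sd** in preservation permutations yields Z = +inf with a
  warning; infinite Z values are excluded from the family medians.
* **Recovery measurement.** Planted-module recovery (adjusted Rand
  index against the planted non-grey labels) is evaluated on the
  tree-cut assignment before the |kME| < 0.7 sweep: with loadings drawn
  down to 0.6, the membership rule intentionally greys out peripheral
  true members, which is a stringency choice, not a detection error.

## Problem sizes

The test suite and the verification script run at desk scale by design:
networks of 300–700 genes, 72 samples, 100–200 permutations, 20-replicate
null studies. These sizes give stable statistics (e.g. Zsummary
separations of >10 units between intact and scrambled modules) while
keeping a full run in minutes on one CPU. The implementation targets
matrices up to roughly 8000 genes; block-wise approximations for larger
matrices are out of scope.

## Known limitations

* The simplified hybrid tree cut is not a line-for-line port of the
  reference algorithm; on borderline branches the two can disagree.
* Preservation uses random-gene-set nulls only (no sample-label
  permutation) and a seven-statistic battery, not the full published
  set.
* Enrichment expects user-supplied GMT libraries; no gene-set
  databases are bundled, and no web services are queried.
* The pipeline assumes normalised log2 input; raw-array preprocessing
  (e.g. RMA) is upstream of this package.
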