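# comodule

Weighted gene co-expression network analysis for two-group transcriptome
studies: network construction, module detection, module–trait
association, hub-gene ranking, cross-dataset module preservation and
gene-set enrichment — with a synthetic-data generator that plants known
module structure so every stage is verifiable without downloading any
accession.

The motivating setting is expression profiling of liver biopsies in
fatty liver disease, mild (fibrosis stage 0–1) versus advanced (stage
3–4): which groups of co-expressed genes track fibrosis severity, which
genes sit at the hubs of those groups, and do the groups replicate in
independent cohorts?

## The method

From a gene × sample log2 matrix, pairwise Pearson correlations r_ij
are soft-thresholded into an adjacency a_ij = |r_ij|^β, with β chosen
as the smallest power whose degree distribution meets the scale-free
criterion (signed R² ≥ 0.9). The topological overlap matrix

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_u a_iu a_uj,  k_i = Σ_j a_ij

measures shared-neighbour similarity; genes are clustered by average
linkage on 1 − TOM and modules cut from the dendrogram (dynamic hybrid
cut, minimum size 30). Each module is summarised by its eigengene
(first principal component); genes with own-module |kME| < 0.7 return
to the unassigned "grey" pool. Modules relate to the trait through
eigengene–trait correlation, genes through gene significance
GS = cor(x_i, y), module membership kME and intramodular connectivity
K.in; hub genes rank high on all three. Module preservation in a second
dataset is scored by permutation composites Zsummary and medianRank
(Zsummary < 2: not preserved; 2–10: weak-to-moderate; > 10: strong).
Enrichment of module gene lists against GMT libraries uses the
Fisher/EASE test with BH correction and the combined score C = ln(p)·z.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

```python
from comodule import (WGCNA, ModulePreservation, SyntheticConfig,
                      generate_dataset, generate_preserved_pair)

cfg = SyntheticConfig(module_sizes=(100, 80, 60),
                      module_trait_cor=(0.6, 0.3, 0.0),
                      loading_range=(0.6, 0.95),
                      n_background=400, n_deg=0, seed=11)
ds = generate_dataset(cfg)            # 640 genes x 72 samples (40 + 32)
res = WGCNA(ds.expr, ds.trait).fit()
print(res.summary())
```

```
Weighted co-expression network fit
==================================
genes: 640   samples: 72
network type: unsigned   soft threshold beta: 8
modules (excl. grey): 3   grey genes: 467

module sizes:
  grey              467
  turquoise          70
  blue               57
  brown              46

module-trait correlations:
  turquoise      r = +0.454   p = 6.29e-05 *
  blue           r = +0.348   p = 2.71e-03 *
  brown          r = -0.002   p = 9.84e-01
  (* p < 0.05)
```

The three planted modules are recovered exactly (the |kME| < 0.7 rule
then trims peripheral members into grey); the two modules planted with
nonzero trait correlation (0.6 and 0.3) are the two significant ones,
and the recovered eigengene–trait correlations (0.45, 0.35) track the
planted values attenuated by estimation noise. Hub genes, ranked by
intramodular connectivity and by gene significance:

```python
print(res.hub_genes("turquoise", top_n=3))
```

Preservation against an independent draw in which the "blue" module was
deliberately scrambled into noise:

```python
ref, test = generate_preserved_pair(cfg, scramble_modules=["blue"])
pres = ModulePreservation(ref.expr, test.expr, ref.truth, beta=6).fit(
    n_perm=200, seed=1)
print(pres.summary())
```

```
Module preservation
===================
permutations: 200
module          size  Zsummary  medianRank  class
turquoise        100     20.76         1.0  strong
brown             60      9.68         2.0  weak_to_moderate
blue              80     -3.15         3.0  none
```

The scrambled module falls below the no-evidence band and takes the
worst median rank; the intact modules score far above it.

Real data enter the same way — `WGCNA.from_files("expr.tsv",
"trait.tsv")` reads plain TSV or GEO series-matrix text, and
`comodule.preprocess` provides probe collapse, the mean/variance gene
filter and outlier-sample detection. The `comodule` command line wraps
the full pipeline (`comodule run --config run.yaml`) and each stage
(`simulate`, `preprocess`, `deg`, `network`, `modules`, `preserve`,
`enrich`).

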