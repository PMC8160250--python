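# coexatlas

Multilayer analysis of multi-tissue gene co-expression networks: an atlas of
signed co-expression communities per tissue, multiplex tissue-sharing
statistics, bootstrap inference on the global structure of low-dimensional
embeddings, community-based tissue prediction, gene-set over-representation,
and community-conditional statistics for gene-level association p-values.

The package is aimed at computational biologists studying how co-expression
structure is organized within and across tissues (e.g., in GTEx-style
multi-tissue RNA-seq resources), and at methodologists who want a tested,
seedable implementation of these statistics that can be exercised end-to-end
on synthetic data with planted ground truth.

## The model

For each tissue, Pearson correlations `r_ij` between all gene pairs are
Fisher-transformed, `z_ij = 0.5 ln((1 + r_ij)/(1 - r_ij))`, and only the
strongest (anti-)correlations are kept: the signed adjacency stores `z_ij`
when `z_ij < -0.8` or `z_ij > 0.8` (strict) and zero otherwise.

Communities are found by maximizing a signed modularity

```
Q* = (1/v+) Σ_ij (w+_ij − e+_ij) δ(M_i, M_j)
     − (1/(v+ + v−)) Σ_ij (w−_ij − e−_ij) δ(M_i, M_j),
```

where `w±_ij` are the positive/negative edge weights mapped into [0, 1],
`e±_ij = s±_i s±_j / v±` the chance-expected weights, and `δ` indicates
co-membership. The asymmetric normalization penalizes negative weight inside
a community more mildly than it rewards positive weight, driving
anti-correlated genes into different communities. The optimizer is a Louvain
procedure (greedy local moves + graph aggregation) extended with a
Kernighan–Lin-style escape pass; communities with fewer than four genes are
dropped from the atlas.

Tissue sharing is quantified on a multiplex network whose layers are the
per-tissue community structures: the global multiplexity index
`gmi(i, j) = Σ_g δ(c_i^g, c_j^g)` counts the layers in which genes i and j
co-cluster, with pair distribution `π_k = P(gmi = k | gmi > 0)` and maximal
groups (pairwise `gmi = L`) extracted per architecture.

Embedding persistence: samples × genes master matrices (per-gene min-max
scaled to [0, 1], zero-filled where a gene is absent from a tissue) are
embedded in 2-D (UMAP by default), and the matrix `d(i, j)` of tissue-cluster
centroid distances is bootstrapped over B = 500 re-embeddings of 80%
subsamples. The clustering conservation coefficient
`C_(i0,i1) = corr(d̄(i0,·), d̄(i1,·))` is tested with
`sqrt((L−3)/1.06)·arctanh(C) ~ N(0,1)` (Spearman correlation by default).

Downstream, a community "can predict" a tissue when a one-vs-rest linear SVM
(class-balanced, stratified 3-fold CV) reaches mean F1 > 0.80 on the
community's genes; communities are tested for gene-set over-representation
with the hypergeometric test and Benjamini–Hochberg adjustment; and
gene-level association p-values are compared between community members and
the complement via conditional Q-Q data and a Storey-type estimate of the
non-null proportion π1, with Bayes FDR(p) = π0·p/F(p).

## Worked example

The repository ships a demo configuration that simulates three tissues with
three planted blocks (one shared by all tissues, one with mixed loading
signs shared by two, one tissue-specific):

```
coexatlas run --config examples/demo.yaml --out demo_out
```

which completes in well under a minute and prints

```
completed stages: ['communities', 'multiplex', 'persistence', 'predict', 'simulate', 'twas']
```

The provenance manifest (`demo_out/manifest.json`) records, among other
things:

```
"n_communities": {"tissue_0": 4, "tissue_1": 3, "tissue_2": 1}
"multiplex": {"all": {"L": 3, "max_gmi": 3, "n_groups": 1},
              "pair": {"L": 2, "max_gmi": 2, "n_groups": 3}}
```

Reading these numbers: tissue_0 carries four retained communities — the
fully shared block, the two halves of the mixed-sign block (anti-correlated
genes are split apart, as the signed modularity intends), and its private
marker block — while tissue_2 carries only the shared block. In the
three-layer multiplex the shared block attains the maximal global
multiplexity index 3, equal to the layer count, and is reported as the one
fully shared gene group; the two-layer architecture additionally recovers
the two mixed-sign sub-blocks. Every stage's outputs (edge lists, atlas
JSON, gmi tables, distance matrices, prediction table, Q-Q series) are
written under `demo_out/` and hashed into the manifest, so a rerun with the
same configuration is verifiably identical.

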