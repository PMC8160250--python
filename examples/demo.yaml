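# Demo pipeline: three simulated tissues with planted co-expression blocks.
# Block 1 is shared by all tissues, block 2 (mixed loading signs) by two,
# and block 3 is specific to tissue_0.
seed: 1
simulate:
  n_tissues: 3
  samples_per_tissue: [30, 30, 30]
  n_genes: 40
  blocks:
    - genes: [0, 1, 2, 3, 4, 5, 6, 7]
      loadings: 0.95
      tissues: [0, 1, 2]
    - genes: [8, 9, 10, 11, 12, 13, 14, 15]
      loadings: [0.95, 0.95, 0.95, 0.95, -0.95, -0.95, -0.95, -0.95]
      tissues: [0, 1]
    - genes: [16, 17, 18, 19, 20, 21]
      loadings: 0.95
      tissues: [0]
  noise_sd: 0.31
  tissue_effect_sd: 1.0
coexpress:
  cutoff: 0.8
communities:
  gamma: 1.0
  min_size: 4
multiplex:
  architectures:
    all: all
    pair: [tissue_0, tissue_1]
persistence:
  B: 6
  frac: 0.8
  backend: umap
predict:
  enabled: true
twas:
  n_genes: 2000
  pi1: 0.3
  effect: 3.0
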