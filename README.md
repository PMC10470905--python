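# streak-abundance

Supervised estimation of cell-surface receptor abundance for single-cell
RNA-seq data, trained on joint scRNA-seq/CITE-seq data.

## The problem

scRNA-seq measures transcripts, but many analyses — cell typing, gating,
cell–cell interaction inference — need the abundance of surface *proteins*.
The naive proxy, the receptor's own transcript, is often nearly useless:
dropout leaves the transcript undetected in most positive cells, and for
some receptors protein abundance is simply not well correlated with the
cognate mRNA. When a joint scRNA-seq/CITE-seq dataset of the same tissue is
available, the association between the whole transcriptome and each
antibody-derived-tag (ADT) readout can be *learned* and then transferred to
cells profiled by RNA alone.

## The method

**Training** (paired cells, RNA counts `X_tR` and ADT counts `X_tP`):

1. Log-normalize `X_tR` (per-cell library scaling to 10⁴, then `ln(1+x)`)
   and compute a reduced-rank reconstruction `X_tR*` via randomized SVD,
   with the rank chosen at the elbow of the non-centered component-SD curve;
   negative reconstructed entries are clamped to 0.
2. CLR-normalize `X_tP` across antibodies within each cell.
3. For each receptor, rank every gene by the Spearman correlation ρ between
   its reconstructed expression and the receptor's normalized ADT level;
   keep the top 10 genes with ρ > 0. The ρ values are the gene weights —
   together they form the weighted membership matrix `A`.

**Estimation** (target cells, RNA counts `X_R` only):

1. Log-normalize + reduced-rank-reconstruct `X_R` into `X_R*`.
2. For each receptor with gene set `k` of size `g` and weights `w`, compute
   per cell the squared modified Mahalanobis distance
   `M[c,k] = Σ_j X_R*[c,j]² / (σ²_tech,j / w_j)` — no centering, per-gene
   technical variances (sample variances) shrunk by large weights.
3. Fit a gamma distribution (MLE) to the nonzero distances of a
   column-permuted copy of the set matrix; the cell's score
   `S[c,k] ∈ [0,1]` is the gamma CDF at `M[c,k]`.
4. Cluster each receptor's distances with exact 1-D k-means (dynamic
   programming, k ≤ 4 chosen by BIC) and set the scores of the lowest
   cluster to zero: those cells are called receptor-negative. `S` is the
   returned abundance estimate.

Two unsupervised baselines ship with the package: the log-normalized cognate
transcript, and a reconstruct-then-threshold estimator that applies the same
clustering directly to each reconstructed gene column.

## Worked example

`examples/03_estimate_abundance.py` simulates 2,500 cells with 6 receptors
(70% RNA dropout), trains gene sets on 40% of the cells and estimates
abundance for the held-out 60%:

```
estimates: 1500 cells x 6 receptors, values in [0.00, 1.00]
  ADT00: thresholded score rho = 0.585   naive transcript rho = 0.197
  ADT01: thresholded score rho = 0.511   naive transcript rho = 0.184
  ADT02: thresholded score rho = 0.604   naive transcript rho = 0.179
  ...
```

Each `rho` is the Spearman correlation between the per-cell estimate and the
simulator's true protein level: the trained 10-gene score roughly triples
the concordance of the single-transcript proxy under heavy dropout. The
other examples cover simulation (`01`), gene set construction and module
recovery (`02`), the cross-validated benchmark with win shares (`04`), and
the shell CLI (`05`, commands `streak simulate/train/estimate/baseline/
evaluate/preprocess`).

## Library surface

```python
from streak import (SyntheticSpec, generate_joint,          # paired simulator
                    RunConfig, streak_train, streak_estimate,  # the estimator
                    rna_baseline, speck_baseline,           # baselines
                    make_splits, concordance, best_method_proportions)
```

All randomness flows from `RunConfig.seed` through documented per-stage
derived seeds; identical inputs and seed give byte-identical output files.

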