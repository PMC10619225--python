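# hascad

Cell-composition deconvolution (CCD) of bulk RNA-seq with batch-harmonized
single-cell references and an ensemble neural network.

Bulk RNA-seq measures the average expression of all cells in a tissue;
estimating the underlying cell-type fractions matters wherever immune
composition drives biology (e.g. tumor-infiltrating lymphocytes and
immunotherapy response). `hascad` predicts the fractions of **15 immune
cell types** — aDC, pDC, memory/naive B, memory/naive CD4 T, Treg,
effector/memory/naive CD8 T, HSC, MK, CD14/CD16 monocytes, and NK — from a
bulk expression profile.

## Method

1. **Harmonized reference.** Multi-batch scRNA-seq references are
   log2(CP10K+1) normalized, reduced to the most variable genes by a
   VST-style standardized-variance ranking, standardized per gene, and
   embedded by PCA: `M = UΣVᵀ`, `Z = ΣVᵀ`. A Harmony-style iteration
   alternates a diversity-penalized soft k-means with a per-cluster ridge
   regression that removes batch-specific linear offsets, giving the
   corrected embedding `Z′`; `U·Z′` mapped back to the expression scale is
   the batch-corrected reference expression. New bulk samples are projected
   Symphony-style into the same corrected space (`Z_q`, `Z_q′`, `U·Z_q′`).
2. **Pseudo-bulk simulation.** Training samples are per-gene means of cells
   drawn at random fractions `S_n`; ground truth is `S_n / ΣS_n`.
3. **Ensemble network.** Three parallel MLPs (first layers 1024/512/256,
   three hidden layers each, softmax over 15 types) are trained with Adam
   (lr 1e-4, batch 64) on the composite loss

   `loss = MSE(truth, pred) + (1 − r(truth, pred))`

   with the Pearson `r` taken across the 15 types of each sample; early
   stopping monitors validation loss with patience 20. The prediction is
   the average of the three softmax outputs, which stays on the simplex.

A seeded synthetic-data module emulates multi-batch scRNA-seq (cell-type
expression programs, gene-wise multiplicative batch effects, library-size
variation, dropout) so the entire pipeline is testable offline.

## Worked example

```python
import numpy as np
from hascad import (SyntheticDesign, generate_cells, build_reference,
                    build_set, DeconvolutionEnsemble, EnsembleSpec)
from hascad.evaluate import per_sample_pcc

cells = generate_cells(SyntheticDesign(n_batches=3, cells_per_type_per_batch=40,
                                       n_genes=600, batch_effect_sd=1.0, seed=7))
ref = build_reference(cells, n_top=256, d=20, seed=0)
bulk = build_set(ref.corrected_expression, ref.type_labels,
                 ref.scaling.selected_genes, n_samples=2200,
                 cells_per_sample=300, seed=1)
ens = DeconvolutionEnsemble.build(EnsembleSpec(seed=0), bulk.gene_ids)
ens.train(bulk.subset(np.arange(1800)), bulk.subset(np.arange(1800, 2000)),
          max_epochs=30)
test = bulk.subset(np.arange(2000, 2200))
pcc = per_sample_pcc(test.truth, ens.predict(test.expression))
print(round(float(np.median(pcc)), 3))
```

This prints `0.93`: the median per-sample Pearson correlation between
predicted and true fractions on 200 unseen pseudo-bulk samples. Training
the same model on the *uncorrected* pool (`ref.normalized_expression`)
prints `0.867` — the batch correction is what buys the gap.

The same workflow is available from the shell:

```bash
hascad simulate-sc --out sc/ --seed 1
hascad build-ref --sc sc/ --genes 512 --dim 20 --out ref.h5
hascad make-bulk --ref ref.h5 --n 8000 --cells 500 --seed 2 --out train/
hascad make-bulk --ref ref.h5 --n 1000 --cells 500 --seed 3 --out val/
hascad train --train train/ --val val/ --out model.h5
hascad predict --model model.h5 --ref ref.h5 --input bulk.tsv --out fractions.tsv
```

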