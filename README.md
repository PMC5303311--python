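# dwglasso

Gene networks from expression data, with prior biological knowledge, and
network-based differential gene expression analysis.

Conventional differential expression ranks genes one at a time and
ignores how their interactions rewire between conditions — yet a gene
that is a hub in tumors and isolated in normal tissue is biologically
interesting even when its mean shift is modest. This package provides:

- **wgLASSO** — sparse Gaussian graphical model estimation with an
  element-wise penalty that encodes prior interaction confidence
  (e.g. STRING protein–protein association scores),

      Θ̂ = argmin_{Θ≻0} −log det Θ + tr(SΘ) + λ‖(1 − W) ∗ Θ‖₁ ,

  where W ∈ [0,1]^{p×p} holds the prior scores: a trusted pair
  (w_ij → 1) is penalized lightly, an unsupported pair gets the full
  penalty. W = 0 is the plain graphical LASSO.
- **dwgLASSO** — the differential pipeline: per-gene significance
  filtering (Welch t-test or survival concordance index, BH-FDR),
  one wgLASSO network per group with its own cross-validated λ
  (one-standard-error rule), and a per-gene **differential network
  score** dns_i = |sd_i^h − sd_i^l|, the absolute change in scaled node
  degree (degree / max degree) between the two group networks. Genes are
  ranked by dns; the top of the list is the biomarker candidate set.
- A **simulation benchmark** comparing wgLASSO against neighbor
  selection ("or"/"and" rules) and the graphical LASSO on scale-free
  ground truths, with sparsity-matched tuning and FP/FN scoring, plus
  precision–recall curves along the regularization path.

Intended users: computational biologists doing network-based biomarker
discovery on expression matrices (microarray or normalized RNA-seq),
and methodologists who need a weighted graphical LASSO with a verified
solver (KKT-certified, oracle-tested) as a baseline.

## Worked example

Simulate a two-condition study in which 3 genes rewire their
interactions (100 genes, 60 samples per condition), then run the full
pipeline:

```python
import numpy as np
import dwglasso as dw

Xa, Xb, truth = dw.generate_two_group_data(
    p=100, n_per_group=60, n_differential_hubs=3, seed=0
)
X = np.vstack([Xa, Xb])
groups = np.array([1] * 60 + [0] * 60)

table = dw.run_dwglasso(X, groups, alpha=1.0, cv_folds=10, seed=0)
print("planted hubs:", sorted(f"g{h + 1}" for h in truth.differential_nodes))
print(table.head(5)[["d_h", "d_l", "sd_h", "sd_l", "dns"]].round(3))
```

```
planted hubs: ['g54', 'g56', 'g88']
      d_h  d_l   sd_h   sd_l    dns
gene
g88    14    3  0.933  0.231  0.703
g56    15    4  1.000  0.308  0.692
g54     6   13  0.400  1.000  0.600
g55    11    2  0.733  0.154  0.579
g21     8    1  0.533  0.077  0.456
```

The three planted hubs head the ranking: each has ~14 estimated partners
in the condition where it was rewired and ~3 in the other, so its scaled
degree swings by 0.6–0.7 while most unrewired genes score lower. The
`d_*` columns are raw degrees in the two group networks, `sd_*` the
degrees scaled by each network's maximum, and `dns` their absolute
difference — the ranking criterion.

The same pipeline runs from the shell on TSV files (expression matrix,
labels, optional STRING-style prior):

```bash
dwglasso simulate --p 100 --n 50 --acc 0.6 --seed 1 --out-dir sim/
dwglasso fit --data sim/X.tsv --weights sim/W.tsv --cv 10 --seed 7 --out net.tsv
dwglasso benchmark --p 100 --n 50 --replicates 100 --seed 1 --out report.tsv
```

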