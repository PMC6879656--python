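# mrmrsig

A tested pipeline for two-class gene-expression biomarker discovery:
mutual-information-based **mRMR** gene ranking, **incremental feature
selection (IFS)** with a leave-one-out cross-validated RBF-SVM,
plateau-based signature-size selection, confusion-matrix metrics
(accuracy / sensitivity / specificity), and reporting (IFS curve, clustered
signature heatmap, JSON run report).  A synthetic-data module generates
two-class expression matrices with planted informative genes, correlated
redundant copies, and noise genes, so the whole pipeline is testable without
any external download.

## Layout

| module | contents |
|---|---|
| `mrmrsig.datamodel_io` | `ExpressionMatrix` / `DatasetPair`, TSV readers/writers, gene-set intersection, quantile normalization |
| `mrmrsig.mrmr` | 3-state z-score discretization, plug-in mutual information, greedy mRMR ranking (MID / MIQ) |
| `mrmrsig.ifs_classify` | LOOCV SVM evaluation, IFS curve, signature-size selection, final train/test, ACC/Sn/Sp |
| `mrmrsig.synthetic_data` | seeded two-class generator with informative / redundant / noise gene roles |
| `mrmrsig.reporting` | hierarchically clustered signature heatmap with 2-cut purity, JSON + text run report |
| `mrmrsig.cli` | `mrmrsig` command with `simulate`, `rank`, `ifs`, `evaluate`, `report` subcommands |

## CLI

```sh
# generate a synthetic train/test pair with planted signal
mrmrsig simulate --spec spec.yaml --out-dir data/

# rank genes by mRMR (quantile-normalize + discretize + greedy MID)
mrmrsig rank --matrix data/train_matrix.tsv --labels data/train_labels.tsv \
             --top-n 500 --criterion MID --k-sd 1.0 --out ranked.tsv

# incremental feature selection over the ranked list
mrmrsig ifs --matrix data/train_matrix.tsv --labels data/train_labels.tsv \
            --ranked ranked.tsv --k-max 500 --delta 0.01 --floor 0.90 \
            --out curve.tsv --summary summary.json

# evaluate a fixed signature: training LOOCV + independent test
mrmrsig evaluate --train data/train_matrix.tsv --train-labels data/train_labels.tsv \
                 --test data/test_matrix.tsv --test-labels data/test_labels.tsv \
                 --genes signature.txt --out eval.json

# full pipeline with heatmap + JSON report
mrmrsig report --train ... --train-labels ... --test ... --test-labels ... \
               --out-dir run/
```

Expression matrices are tab-separated (genes in rows, first column gene id,
header row sample ids); labels are two-column `sample_id<TAB>class` files
with classes `COPD` / `ILD` mapped to the internal positive/negative labels.

## Notes on defaults

* SVM: RBF kernel, cost 1, gamma = 1/n_features, per-fold feature scaling —
  the defaults of the classical e1071 `svm` function. Scaling is fitted on
  the held-in samples of each LOOCV fold only (no leakage).
* Discretization: per-gene z-score, states −1/0/+1 at ±1 SD (configurable).
* Quantile normalization: ties receive the mean of the rank-means they span;
  train and test sets are normalized separately by default.
* Signature size: smallest k on the IFS-curve plateau (strictly within
  `delta` of the maximum) whose accuracy clears `floor`; the argmax k is
  reported alongside.
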