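# plantloc

Subcellular localization prediction for plant proteins over 11 compartments
(plastid, cytoplasm, extracellular, nucleus, mitochondrion, cell membrane,
Golgi, ER, vacuole, peroxisome, cell wall), including dual-location calls
for the pair classes observed in plants (mitochondrion+plastid,
cytoplasm+nucleus, cytoplasm+Golgi).

The package is for bioinformaticians who need a reproducible, testable
localization pipeline: a fixed 479-feature protein encoder, three feature
selection procedures, a heterogeneous soft-voting ensemble, evaluation
utilities, and a synthetic-data generator so everything runs end-to-end
with no external tools or downloads.

## Model

Each protein sequence is encoded as an ordered 479-feature vector:
amino-acid composition; four pseudo-composition variants
(type-I with λ=2 and λ=10, type-II with λ=2 over 3 properties,
amphiphilic with λ=5); grouped composition/transition/distribution
descriptors over 7 physicochemical properties; Geary autocorrelation
(4 properties × lags 1..10); quasi-sequence-order descriptors and
sequence-order coupling numbers under two residue distance matrices
(nlag=10); projections onto multi-dimensional property scales; scalar
physicochemical indices (net charge, aliphatic and instability indices,
isoelectric point, hydrophobic moments, covariance indices); 18 scores
from external sorting-signal predictors (supplied by file or by a
deterministic mock); and one GO-homology compartment code.

Three base classifiers are trained on the same rows and features — KNN
(k = 12, inverse-distance weights, standardized features), a 100-tree
random forest, and gradient boosting (50 rounds, depth 5, η = 0.1,
multiclass log-loss). The consensus probability for class *c* is the
unweighted average

&nbsp;&nbsp;&nbsp;&nbsp;P(c) = ⅓ · (P_KNN(c) + P_RF(c) + P_XGB(c)),

the top class is always called, and the runner-up is added when its
consensus probability reaches θ (default 0.30). Per-class performance is
reported as Sn, Sp, MCC and AUC from one-vs-rest confusion counts, with a
record counted correct only when its predicted label *set* matches the
truth exactly. Full formulas, parameter pinning and design rationale are
in [docs/methods.md](docs/methods.md).

## Worked example

Generate a small labeled dataset (with mock external scores), encode it,
train the ensemble, predict, and score:

```bash
plantloc simulate --fixture tiny --out-dir data
plantloc extract data/sequences.fasta --scores data/scores.tsv --out features.tsv
plantloc train features.tsv data/labels.tsv --model-dir model --seed 1
plantloc predict features.tsv --model-dir model --out predictions.tsv
plantloc evaluate predictions.tsv data/labels.tsv --out report.tsv
```

which prints

```
wrote 22 records to data
wrote 22x479 feature table to features.tsv
model saved to model
wrote 22 predictions to predictions.tsv
overall accuracy 100.00%
```

`predictions.tsv` holds, per protein, the called label(s) and the 11
consensus probabilities (first columns shown):

```
id              label1     label2  p_plastid  p_cytoplasm
cytoplasm_0000  cytoplasm  NA      0          0.977527
cytoplasm_0001  cytoplasm  NA      0          0.977527
cytoplasm_0002  cytoplasm  NA      0          0.974194
```

— `label2` is `NA` when the runner-up consensus probability stays below
θ, and the report (`report.tsv`) lays out per-location counts, percent
correct and MCC with single-label/dual-label/overall subtotals:

```
type      location        n   correct  percent  MCC
single    cytoplasm       11  11       100      1
single    nucleus         11  11       100      1
subtotal  Total (single)  22  22       100
subtotal  Total all       22  22       100
```

This is a tiny 2-class fixture that the model fits perfectly; the
`strong` fixture (11 classes + pairs, 569 records) and `plantloc cv` give
a more informative picture. Feature selection is available as
`plantloc select features.tsv data/labels.tsv --method relieff|oner|cfs_ga ...`,
and the same functionality is exposed as scikit-learn estimators
(`FeatureExtractor`, `ReliefFSelector`, `OneRSelector`,
`CFSGeneticSelector`, `LocalizationEnsemble`) for use in Python.

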