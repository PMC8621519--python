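# binsim — occurrence-based pre-treatment for MS metabolomics

High-resolution, direct-infusion mass spectrometry (e.g. FT-ICR-MS) yields
peak tables with thousands of *m/z* features, few samples, and 20–85 %
missing entries, most of them missing-not-at-random: a gap usually means the
metabolite was absent or below the detection limit. Conventional
pre-treatment pipelines impute those gaps, normalize, transform and scale
the intensities — a stack of method choices whose outcome they strongly
affect.

**Binary Simplification (BinSim)** replaces that stack with a single step:

```
x_ij  ->  1 if feature j was detected in sample i, else 0
```

The occurrence pattern itself carries the discriminative information. This
package implements BinSim together with a full benchmark harness to compare
it against intensity-based pipelines:

- **`binsim.peak_table`** — peak-table data model, TSV/CSV I/O, alignment of
  per-sample peak lists at a ppm *m/z* tolerance, occurrence
  (reproducibility) filters, dataset summaries.
- **`binsim.pretreatment`** — scikit-learn style transformers for the seven
  benchmark pipelines: half-minimum and random-forest imputation,
  reference-feature and probabilistic-quotient (PQN) normalization,
  generalized-log transform, Pareto scaling, and `BinSim` itself. They
  compose with `sklearn.pipeline.Pipeline`.
- **`binsim.binary_distances`** — Jaccard, Yule and Hamming dissimilarities
  over occurrence vectors, and distance-matrix construction.
- **`binsim.cluster_eval`** — UPGMA hierarchical clustering, K-means with
  restarts, and replicate-ground-truth quality metrics: correct-clustering
  %, correct-first-cluster %, Discrimination Distance, adjusted Rand index,
  plus cophenetic and Baker's gamma dendrogram correlations.
- **`binsim.classifier_eval`** — random-forest and PLS-DA classifiers under
  repeated stratified cross-validation, permutation tests, ROC curves, Gini
  and VIP feature importances with top-fraction selection and
  occurrence profiling.
- **`binsim.synthetic_data`** — a generator of peak tables with known ground
  truth (planted class-exclusive biomarkers, intensity-threshold MNAR
  censoring, per-sample dilution), including presets mimicking typical
  benchmark regimes.
- **`binsim.cli`** — a `binsim` command with `align`, `filter`, `pretreat`,
  `distances`, `cluster-bench`, `classify-bench`, `simulate` and `run`
  subcommands.

## Worked example

```python
import numpy as np
import binsim as bs
from binsim.classifier_eval import ClassifierSpec, cv_accuracy

# synthetic 15-sample / 5-class dataset, ~65 % missing entries
pt, groups, truth = bs.table1_like("YD-like", seed=1)
print(pt)                     # PeakTable(15 samples x 1968 features, 65.1% missing)

bm = bs.binsim(pt)            # 0/1 occurrence matrix
dend = bs.hca(bs.distance_matrix(bm, "jaccard"))
print(bs.correct_clustering_hca(dend, groups))   # 100.0

y = np.array([groups[s] for s in bm.sample_ids])
spec = ClassifierSpec(kind="random_forest", n_folds=3, n_repeats=20, seed=1)
print(cv_accuracy(bm, y, spec).mean_accuracy)    # 1.0
```

The three printed values say: the generated table matches the intended
regime (15 samples, ~2000 features, ~65 % missing); UPGMA on the Jaccard
dissimilarity of the binary matrix re-groups every replicate triplet before
mixing groups (100 % correct clustering); and a 100-tree random forest
reaches perfect mean accuracy over 20 repeats of stratified 3-fold
cross-validation — the occurrence encoding alone suffices to discriminate
the five classes.

The same comparison over several pre-treatments runs from the shell:

```bash
binsim simulate --preset YD-like --seed 1 --out table.tsv --meta meta.tsv
binsim cluster-bench --pretreat binsim --pretreat half_min-P \
    --seed 1 table.tsv meta.tsv report.json
```

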