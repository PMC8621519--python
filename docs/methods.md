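# Methods

## The occurrence encoding and why it can work

A high-resolution direct-infusion MS peak table records, for each sample
and each aligned *m/z* feature, either a positive intensity or a gap. In
this regime most gaps are missing-not-at-random: the metabolite was absent
from the sample or sat below the detection limit. Binary Simplification
(BinSim) encodes detection as 1 and a gap as 0 and discards the
intensities. The encoding acts simultaneously as imputation (gaps become
an informative 0), normalization (all features are bounded by 0 and 1
regardless of magnitude; global intensity biases largely cancel) and
scaling. Its information content degrades when missingness is dominated by
random (MCAR/MAR) mechanisms or when almost nothing — or almost
everything — is missing.

## Pre-treatment pipelines

All seven benchmark pipelines operate on a samples × features matrix with
NaN gaps, in the fixed order *imputation → normalization → transform →
scaling*; BinSim short-circuits all four stages.

- **Half-minimum imputation** replaces every gap by half the global minimum
  observed intensity — a limit-of-detection assumption.
- **Random-forest imputation** (missForest-style): features are visited in
  order of increasing missingness; each incomplete feature is regressed,
  over the samples where it is observed, on its 100 most
  |correlation|-similar features of the provisionally (half-minimum) filled
  matrix, with a 50-tree regression forest; the fitted forest predicts the
  gaps. Sweeps repeat until the sum of squared changes in the imputed cells
  increases (the previous sweep is then kept) or 10 sweeps elapse. Features
  observed in fewer than two samples fall back to half-minimum. The loop
  structure (initial fill, similarity on the provisionally filled matrix,
  divergence stopping rule) is this package's specification of an otherwise
  under-determined procedure; the contract is parameter recovery on
  low-rank data, not bit-equality with any particular implementation.
- **Reference-feature normalization** divides each sample by its intensity
  of a designated feature (e.g. the leucine-enkephalin lock mass,
  *m/z* 556.276575 in ESI+ / 554.262022 in ESI−), resolved within a ppm
  tolerance.
- **PQN** divides each sample by the median of its feature-wise quotients
  against a reference spectrum. The reference is the feature-wise median
  over the fitted samples — a choice this package fixes because the method
  itself leaves it open. With the reference held fixed, the transform is
  exactly idempotent.
- **glog** maps x → ln((x + √(x² + λ))/2). λ = 0 reduces to ln. The default
  λ is the square of the matrix minimum at fit time; after half-minimum
  imputation that minimum *is* the imputation value, so the flattening
  region of the transform coincides with the detection limit. λ is
  user-overridable.
- **Pareto scaling** centers each feature and divides by the square root of
  its standard deviation (n−1 denominator — another convention the method
  description leaves open); zero-variance features map to zero.

All steps are scikit-learn transformers (`fit`/`transform`,
`get_params`/`set_params`) and compose in `sklearn` Pipelines. In the
benchmark harness, as in common metabolomics practice, pre-treatment is fit
on the full table before cross-validation; BinSim is immune to the leakage
this can cause because each encoded cell depends only on its own entry.

## Binary dissimilarities

For two occurrence vectors with contingency counts n11 (present in both),
n10/n01 (present in one) and n00 (absent in both):

- Jaccard: 1 − n11/(n11+n10+n01), in [0,1]; ignores joint absences.
- Yule: 2·n10·n01/(n11·n00 + n10·n01), in [0,2]. A zero denominator
  (no concordance/discordance evidence) returns 0 with a warning. Note
  this is *not* the variant in `scipy.spatial.distance.yule`, which uses
  2R/(n11·n00 + R) with R = 2·n10·n01.
- Hamming: (n10+n01)/total, the disagreement fraction.

## Clustering evaluation

Replicate groups define the ground truth. UPGMA (average linkage) runs on
any of the three binary dissimilarities (or Euclidean distance for
intensity pipelines); K-means always runs in Euclidean geometry — also on
binary matrices — with 15 random initializations, Lloyd iterations, and the
minimum-inertia solution retained.

- **Correct clustering % (HCA)**: a group counts as correct iff some tree
  node contains exactly its samples. **(K-means)**: iff some cluster equals
  exactly its sample set. The K-means condition is stricter in expectation.
- **Correct first cluster %**: the percentage of samples whose first merge
  joins only own-group samples.
- **Discrimination Distance (HCA)**: for each correctly clustered group,
  the height of the merge that absorbs the pure-group node minus the height
  of that node, normalized by the maximum merge height; 0 for incorrect
  groups (and for a pure node that is already the root); averaged over
  groups. This is the margin a stray sample would have to bridge to break
  the group. **(K-means)**: distance from the correct group's centroid to
  the nearest other centroid, over the maximum centroid-pair distance.
  Both normalizations are this package's reading of an informally defined
  quantity; they are validated against hand-computed cases, and values are
  comparable only within a method.
- **Adjusted Rand index** via the standard pair-counting formula
  (`sklearn`); two single-cluster partitions score 1 by convention.
- **Cophenetic correlation**: Pearson correlation of the two trees'
  pairwise cophenetic distances. **Baker's gamma**: Spearman correlation of
  the per-pair cluster-count levels at which each pair first co-clusters;
  merges with tied heights — which no height cut can separate — all take
  their tie block's last index, making the statistic invariant to tie
  ordering and to monotone height transforms.

## Classifier evaluation

- Random forest: 100 trees, Gini splits, √p candidate features per split,
  bootstrap resampling (scikit-learn defaults). PLS-DA: multi-response PLS
  (NIPALS, `PLSRegression(scale=False)`) on one-hot class targets, argmax
  decision (two classes: one 0/1 column, 0.5 threshold); no internal
  rescaling, since data arrive pre-treated. The component count can be
  fixed or chosen by maximizing cross-validated Q² = 1 − PRESS/TSS, falling
  back to one component with a warning when no count achieves Q² > 0.
- Accuracy: stratified k-fold cross-validation (3-fold for
  replicate-design data, 5-fold for the larger two-class designs) repeated
  20 times with fresh shuffles; each repeat pools its held-out predictions;
  the mean over repeats is reported. All seeds fan out deterministically
  from one master seed.
- Permutation test: the observed statistic uses the full 20-repeat
  protocol; each of the 500 label permutations is scored with a single
  stratified-CV pass (the protocol fixes only the iteration count, and the
  null needs the location of the distribution, not a 20-fold-smoothed
  version of each draw). p = (1 + #{null ≥ observed})/(n_perm + 1).
- Importance: Gini importance (normalized to sum 1) or VIP,
  VIP_j = √(p·Σ_a ssy_a (w_aj/‖w_a‖)² / Σ_a ssy_a) with
  ssy_a = Σ_k q²_ak·t_aᵀt_a, satisfying mean(VIP²) = 1. Scores are averaged
  over the training-fold refits of all 20 CV repeats (repeat-level
  averaging), then the ⌈0.02·p⌉ top features are retained, ties broken by
  ascending *m/z*. Selected features are profiled by the number of samples
  and distinct classes in which they occur — class-exclusive
  ("biomarker-type") features show a class occurrence of 1.
- ROC (two-class): out-of-fold decision scores (RF vote fraction, PLS-DA
  predicted y) pooled over all folds and repeats into one curve; AUC by the
  trapezoid rule.

## Synthetic data generator

The generator emulates the structure of replicate-design direct-infusion
datasets. A shared feature's natural-log intensity in sample *s* of class
*c* is

    base_f + shift_cf + module_cf + eps + dilution_s

with base_f ~ N(μ, σ_base) across features, class shifts
shift_cf ~ N(0, effect_sd), replicate noise eps ~ N(0, noise_sd) and a
per-sample log dilution ~ N(0, dilution_sd). Planted biomarkers are drawn
only in their class, boosted by `biomarker_log_boost` log units — a
detectable class marker sits above the detection limit by construction. A
reference (lock-mass) feature is present in every sample at high intensity.
An optional "module" mechanism (off in the presets) lets a feature be
boosted in a random subset of ≥ 2 classes with extra per-sample
variability, modelling metabolic modules shared by related classes.

Missingness: MNAR censoring removes entries below a global intensity
quantile of the post-dilution matrix — so missingness depends on dilution,
exactly the bias BinSim claims to absorb; the reference feature is never
censored. MCAR deletion (optional) removes surviving entries uniformly.
Features left with zero occurrences are dropped, so the requested quantile
and the realized missing fraction of the delivered table differ; the
preset constructor calibrates the quantile by bisection on actual draws
(deterministic under the seed).

Two identifiability properties hold by construction: biomarkers are
structurally absent outside their class, and any *shared* feature whose
realized occurrence pattern is perfectly class-aligned (every class fully
present or fully absent) is rejected, so the planted map is the complete
inventory of class-determined features. Without the rejection rule,
"planted-biomarker recovery" would be measured against an unknown number
of pattern-identical unlabelled confounders.

Preset regimes (sizes follow typical benchmark datasets):

| preset  | samples | classes | features | missing |
|---------|---------|---------|----------|---------|
| GD-like | 33      | 11      | ~3000    | ~80 %   |
| YD-like | 15      | 5       | ~2000    | ~65 %   |
| HD-like | 249     | 2       | ~12000   | ~38 %   |

Noise scales (σ_base 0.6, effect_sd 0.6, noise_sd 0.2, dilution_sd 0.1,
boost 3.0 for the replicate designs) were chosen so that generated data
reproduce the qualitative character of the corresponding real regimes —
high within-replicate reproducibility, well-separated groups in the
YD-like case — rather than to be maximally adversarial. What the generator
does **not** model: isotope patterns and adducts, correlated features from
shared pathways (beyond the optional modules), chromatographic dimensions,
batch effects, and heavy-tailed intensity error. Passing benchmarks on
these data therefore demonstrate correctness of the machinery and the
expected qualitative behaviour of BinSim under MNAR-dominated missingness,
not performance guarantees on any particular instrument's output.

## Known limitations and numerical notes

- The group-level clustering metrics are sensitive to single stray samples
  and are meaningful mainly for small replicate groups (the designs here
  have ~3 replicates per group); correct-first-cluster % is the
  outlier-robust companion.
- A single label permutation of a small, strongly structured dataset
  often scores *below* chance (training replicates carry coherently wrong
  labels), so the shuffled-label degradation level is estimated as the
  mean over 10 independent shuffles.
- Planted-biomarker recovery through the top-2 % of random-forest Gini
  importance has a structural ceiling: the selection holds ⌈0.02·p⌉
  features, pattern-identical planted markers split their Gini credit
  within a class, and any clean class-informative background feature earns
  at least a single marker's per-feature credit. In the YD-like regime
  (~2000 features, 50 planted markers, 40 slots) recovery measures
  40–60 %, with the selected features still showing the biomarker-type
  profile (median class occurrence 1). Recovery ≥ 80 % is achievable — and
  asserted as a property test — when the planted markers are the only
  class-structured features and slots exceed the planted count.
- UPGMA ties break by scipy's deterministic merge order; K-means
  empty-cluster handling follows scikit-learn (relocation to the farthest
  points); Yule's zero-denominator convention returns 0 with a warning;
  Jaccard on two all-absent vectors is an error (such samples cannot occur
  in a valid peak table).
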