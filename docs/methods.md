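# Methods

## Scope

`cpipred` implements a complete compound–protein interaction (CPI)
prediction workflow: curation of multi-source bioactivity records into a
labeled benchmark, canonical-correlation screening of candidate negatives,
pair featurization (fingerprint PCA + protein 3-mer CBOW embeddings), a
fully connected binary classifier with an exhaustive hyperparameter grid,
threshold-free evaluation metrics, and an applicability-domain analysis
based on protein embedding distance. A seeded synthetic-data generator
provides download-free benchmarks with the statistical structure each
stage assumes, so the whole pipeline is testable at desk scale.

## Curation model and assumptions

A bioactivity record is one measurement of one compound–protein pair from
one source: a potency (IC50, Ki or EC50, normalized to µM on ingest; nM,
µM and mM accepted, unknown units rejected with a warning) or a binary
active/inactive call. Curation applies, in order:

1. **Label resolution.** A pair is positive if any record is active —
   potency ≤ 10 µM (the conventional high-throughput-screening hit
   cutoff; the boundary is inclusive), an explicit active flag, or a
   known-interaction catalogue entry — and negative only if every record
   is inactive. The representative potency is the minimum over sources
   (the most potent, hence most biologically relevant, measurement).
   Conflicting duplicate binary calls from one source are resolved by the
   same any-active rule and logged.
2. **Molecular-weight window.** Compounds outside [100, 1000] Da are
   removed (small-molecule focus). Both boundaries are inclusive: the
   exclusion criterion is strictly-below/strictly-above.
3. **Ligand-bias removal.** Per protein and per label class, compounds are
   visited in decreasing interaction-count order (count = number of
   resolved pairs the compound participates in anywhere in the working
   dataset; ties broken lexicographically by compound id) and greedily
   leader-clustered: a compound joins the first already-accepted leader
   with Morgan-Tanimoto similarity > 0.8, otherwise becomes a leader.
   Only leaders survive. Positives and negatives are deduplicated
   separately so a positive can never suppress a negative. The procedure
   is deterministic, order-stable and idempotent.
4. **Negative capping.** At most 1,000 negatives per protein, accepted in
   decreasing interaction-count order, each required to have Tanimoto
   < 0.8 to every previously accepted survivor. The similarity constraint
   is checked against other negatives only, not positives.
5. **Split.** A seeded random 80/20 split; the train side takes
   round-half-up(0.8·n) pairs.

Cross-source overlap is reported as a matrix: totals on the diagonal,
pairwise overlap counts above, and below the diagonal the overlap as a
percentage of the smaller source, rounded to two decimals (undefined and
reported absent for an empty source).

## Negative screening (compound–target correlation space)

Descriptor tables for compounds and proteins are plain DataFrames, so any
externally computed descriptor set plugs in. The built-in sets — folded
fingerprint block counts plus physchem proxies (molecular weight, ring
count, heteroatom fraction) for compounds; amino-acid composition, a
homodipeptide-composition subset and log length for proteins — exist so
the screen runs without licensed descriptor software, and `reduce_descriptors`
offers PCA selection by component count or variance fraction.

The correlation space is a CCA fit on known positive pairs: descriptor
columns are z-scored, covariance blocks get a ridge of 1e-6 for stability
(a warning is raised when the covariance is near-degenerate), and the
canonical weights come from the SVD of the whitened cross-covariance, so
the reported per-component correlations are non-increasing by
construction. The default component cap is min(5, rank).

For each compound with at least two known targets, the targets' protein-
side canonical coordinates form its target space. The distance threshold
is the upper limit of the 95% t-confidence interval of the mean pairwise
Euclidean distance among the targets, `mean + t(0.975, m-1)·sd/√m` over
the m pairwise distances; with a single pair the dispersion is undefined
and the threshold degenerates to that distance. A candidate negative is
confirmed only when the protein's coordinates are farther than the
threshold from the *nearest* target (minimum distance — the conservative
reading that is least likely to discard a true binder; centroid distance
is available by configuration). Compounds with fewer than two known
targets cannot be screened; their candidates pass through flagged
"unscreened" and are kept as negatives. Screening follows capping, per
the workflow order.

## Featurization

* **Compounds.** 2048-bit radius-2 Morgan fingerprints (RDKit), reduced
  by PCA to 200 principal-component scores. The PCA is fitted on
  training-set fingerprints only; test and external compounds are
  transformed with the frozen projection (no leakage). If the data rank
  is below 200 the projection truncates with a warning and scores are
  zero-padded so downstream dimensionality stays fixed.
* **Proteins.** A sequence is a document of non-overlapping 3-mer words,
  single reading frame, trailing 1–2 residues dropped. A CBOW word2vec
  model (embedding dim 100, context window 5, 5 negative samples drawn
  from the unigram^0.75 distribution, linearly decaying SGD rate) is
  trained on the training proteins; the protein embedding is the mean of
  its word vectors. Out-of-vocabulary words at inference are skipped; a
  protein with no in-vocabulary word is outside the feature space and is
  an error. Training defaults to a single worker and a fixed seed so runs
  are bit-reproducible; a worker-count parameter exists for configuration
  compatibility.
* **Pairs.** 300-d concatenation, compound block first.

The CBOW trainer is implemented in numpy inside the package (input/output
vector tables, negative-sampling logistic updates, per-center reduced
window) and is exercised by distributional property tests.

## Classifier

Two hidden blocks, each affine → batch normalization → ReLU → dropout
(the conventional arrangement of those components), then affine →
sigmoid. Optimization is Adam (β1 0.9, β2 0.999) on binary cross-entropy
with probabilities clipped at 1e-7; batch size 256 by default; non-finite
loss aborts with a diagnostic. Batch-norm inference uses running
statistics (momentum 0.9). The implementation is pure numpy with
hand-written backpropagation, so a fixed seed reproduces final weights
exactly. Inputs are centered; the scaling mode is selectable:
`per_feature` z-scoring, or `global` (one scalar scale), which preserves
the relative variance of the PCA components and is the pipeline default.
Prediction labels a pair positive when its probability is ≥ 0.5
(inclusive).

The grid search enumerates the full Cartesian product of the candidate
values — first hidden layer {256, 512, 1024, 2048}, second {128, 256,
512, 1024}, dropout {0, 0.2, 0.5}, learning rate {0.01, 0.001, 0.0001},
epochs {100, 200, 500}; 432 specifications — and scores each by
stratified k-fold (default 5) cross-validated accuracy, ties broken by
enumeration order. Cross-validation selects the specification; the
held-out split reports final performance. The classifier's constructor
defaults are the optimum found at full scale (2048/1024, dropout 0.5,
learning rate 1e-4, 500 epochs); desk-scale runs use smaller explicit
settings (below).

## Metrics

ACC, SEN (=TPR=recall), SPE, FPR and precision from the 2×2 table, with
zero-denominator cases reported as explicit `None`, never silent zeros.
AUROC is the Mann–Whitney pairwise-ranking probability (average ranks, so
ties earn half credit). AUPR is the step-wise area of the precision-recall
curve over descending score thresholds with no linear interpolation
(equivalent to average precision). Both are checked against brute-force
pair-counting / threshold-enumeration oracles and against scikit-learn.

## Applicability domain

Similarity between a tested protein and the training proteins can be
measured three ways: Euclidean distance or cosine similarity between CBOW
embeddings (embeddings always come from the frozen word model fitted on
training proteins), or global sequence identity (alignment with match +1,
mismatch 0, gap −1; identity = identical aligned pairs / alignment
columns × 100). The metrics are validated against the shared-active-
compound principle: all unordered protein pairs are binned by similarity
and the per-bin distribution (median/quartiles) of shared active
compounds is reported — on data with planted structure the closest bin
concentrates the shared compounds.

The per-pair reliability statistic is the Euclidean distance to the
nearest training protein. Predictions are binned by this distance
(half-open bins, last bin closed; bin edges are configuration with
default {0, 0.4, 0.67, 1, 2, 3, 4, 10}) and per-bin n, accuracy,
true/false prediction proportions and AUROC (where both classes occur)
are reported. A distance of at most 0.4 (inclusive) marks a prediction as
within-domain. On synthetic data, whose embedding spread is not
calibrated to the full-scale model, domain checks are expressed relative
to the training cloud's own scale `s`, the mean pairwise distance between
training embeddings, i.e. the within-domain bin is [0, 0.4·s].

## Synthetic benchmark design

The generator plants one latent interaction signal expressed on both
sides so that every stage has something real to recover:

* Each compound draws a latent u ~ N(0, I_4); fingerprint bit j activates
  with probability sigmoid(−3 + 6·(Wu)_j/√d) for a fixed random
  projection W, giving ~5–25% bit density and a latent recoverable by
  PCA (first-component correlation with the planted coordinate well
  above 0.5). A 5% fraction of compounds gets a twin with ~8 random bit
  flips (Tanimoto ≈ 0.9) sharing its latent, to exercise deduplication.
* Each protein draws v ~ N(0, I_4); its sequence samples non-overlapping
  3-mer words from a softmax distribution over a 64-motif vocabulary
  whose logits are linear in v, length uniform in [240, 600] residues,
  so mean CBOW embeddings encode v.
* A sampled 20% of the compound×protein grid becomes records. The true
  interaction is Bernoulli(sigmoid(u·v/0.15)) — the low temperature
  keeps Bayes error at a few percent — and the observed activity flips
  with probability 0.02. Potencies are log-normal (σ = 1 in log units)
  around 1 µM for active and 100 µM for inactive pairs, so the 10-µM
  rule recovers the observed label ~99% of the time with realistic
  overlap tails. 20% of pairs receive a second jittered record from
  another synthetic source (exercising the min-value rule and occasional
  cross-threshold conflicts), and 5% of active pairs an extra binary
  catalogue record (exercising any-active).
* External proteins for domain analysis come in two kinds. "Near"
  proteins resample a fresh sequence from a training protein's own motif
  distribution: in-domain, signal preserved. "Far" proteins keep a fresh
  interaction latent but draw their composition from an unrelated,
  sharpened latent chosen (among 30 candidates) to be least similar in
  composition to every training protein: their embeddings sit away from
  the training cloud and their sequences carry no information about
  their interaction latent — exactly the failure mode the applicability
  domain is meant to flag, so performance degradation beyond 0.4·s is a
  property of the construction, not an artifact of one seed.

Temperature, noise rate, density, signal scale and protein length were
fixed once while designing the generator so that the planted signal is
strong enough to be recoverable end-to-end yet leaves a visible Bayes
gap; they are not tuned per run. The generator does not attempt to mimic
real chemical space or protein families: fingerprints are synthetic bit
patterns by default (an optional fragment-grammar SMILES mode exists for
integration tests of the RDKit path), and sequences are motif soups. A
passing end-to-end suite therefore demonstrates that the pipeline's
machinery is correct and information-preserving — not that the model will
reach any particular accuracy on real bioactivity data.

## Desk-scale problem sizes and settings

The default benchmark is 2,000 compounds × 50 proteins (~25k records,
~20k curated pairs). At this scale the end-to-end runs use hidden layers
256/128, dropout 0, learning rate 1e-3, 150 epochs, batch 256, global
input scaling, and 20 CBOW epochs — small enough to train in about a
minute on one CPU while staying comfortably above the 0.85 AUROC
acceptance bar (typical held-out AUROC ≈ 0.90–0.92 across seeds; the
label-permuted control sits at 0.49–0.51). The full 432-model grid is
enumerated and counted exactly but only trained on toy grids in tests.

## Numerical choices and degenerate inputs

* Loss clipping ε = 1e-7; predicted probabilities additionally clipped at
  1e-12 so reported values stay strictly inside (0, 1) despite float
  saturation of the sigmoid.
* Batch-norm ε = 1e-5; batches of size 1 are skipped (batch statistics
  undefined).
* Tanimoto of two empty bit-sets is defined as 0; length mismatch is an
  error.
* CCA eigenvalues are floored at 1e-12 before the inverse square root;
  canonical correlations are clipped to [0, 1].
* Undefined metrics (zero denominators, one-class AUROC bins) propagate
  as `None`/NaN markers.
* Dedup/cap tie-breaks are lexicographic; grid-search ties resolve to the
  first specification in enumeration order.

## Known limitations

* The built-in descriptor sets are deliberately small proxies, not a
  reimplementation of commercial/academic descriptor catalogues.
* The CBOW trainer is single-threaded; the parallelism setting is
  accepted but not exploited.
* Distances for the screen are computed in protein-side canonical
  coordinates; whether the original procedure used per-target, nearest or
  centroid distance is ambiguous — nearest-target is the default here and
  centroid is available.
* Baseline learners (KNN/RF/XGBoost) and full-scale database ingestion
  are out of scope; ingestion is file-based with identifiers taken as
  given.
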