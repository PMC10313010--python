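# Methods

This note records the models behind `seqsimrank`, the defaults and why
they were chosen, what the synthetic benchmarks do and do not emulate,
and the numerical decisions that affect results.

## Problem setting

All tasks are cast as ranking over labeled (query, candidate) pairs.
Homogeneous tasks (e.g. remote homology) score pairs of the same entity
type drawn from one embedding table; heterogeneous tasks (e.g.
RNA–disease association) score pairs across two tables. Embeddings are
produced upstream and are frozen here: nothing in this package updates
them, which has consequences noted below for the interaction matchers.

Inputs are tab-separated embedding tables (column 1 an identifier, the
rest decimal floats; an optional `#shape L D` header declares per-token
matrix layout, reshaped row-major) and two-column pair-label files.
Homogeneous pairs are canonicalized to (min-id, max-id) before any
duplicate checking, so orientation never matters.

## Partitioning

Queries are shuffled with the run seed and dealt into
train/valid/test (default 0.6/0.2/0.2); a query's candidates never
straddle partitions. Two refinements matter:

* **Homogeneous tasks split at the item level.** Every item can appear
  on either side of a pair, so splitting only by group key would let an
  item occur as a training candidate and again as a test query. An
  encoder that memorizes item identity then scores above chance with
  no pair-level signal at all — we observed held-out AUC ≈ 0.72 for the
  Siamese matcher on pure-noise embeddings under key-level splitting.
  Both members of a pair must now share a partition; straddling pairs
  are dropped with a warning (≈ 56 % of pairs at the default fractions
  — the price of an honest test set). Heterogeneous tasks keep
  query-side splitting: candidate entities (diseases, GO terms) are a
  closed vocabulary shared across partitions, as is standard in
  association prediction.
* **Candidates within a group are ordered by identifier.** Scores are
  ranked with a stable sort, so any correlation between input order and
  labels would silently inflate NDCG for scorers that produce ties
  (tree ensembles especially). Sorting by id makes tie-breaking
  label-agnostic.

Groups without a positive are excluded from NDCG (zero ideal gain) with
a warning, but retained for threshold metrics.

## Base scorers

**Distribution family.** Nine classifiers (SVC with Platt scaling,
random forest, extra trees, k-NN, multinomial naive Bayes, and
gradient boosting in gbdt/goss/dart flavors, plus an MLP) fit on fused
pair features. Fusion is `[u, v]` for heterogeneous pairs and
`[|u−v|, u⊙v]` for homogeneous ones; the symmetric form makes
`s(a,b) = s(b,a)` hold bitwise, which we treat as a correctness
property, not an approximation. Naive Bayes requires nonnegative
features; the per-column training minimum is subtracted (and recorded
in the scorer, with clipping at scoring time). Grid search is
controlled by `gs_mode`: 0 = library defaults, 1 = each grid axis
truncated to two points, 2 = the full grid (≤ 4 points per axis, ≤ 4³
combinations); selection maximizes the run metric on the validation
partition, ties preferring the earliest grid point for reproducibility.
Token-matrix inputs are mean-pooled over tokens before fusion.

**Representation (Siamese) family.** One encoder — an MLP
(hidden 64/32, latent 16, tanh) for vectors, or window-3 convolution
with 32 channels, max-pooling and the same dense stack for token
matrices — is applied to both sides; sharing is structural (a single
parameter block), so the serialized side encoders are identical by
construction. Cosine matching is the default (parameter-free and
exactly symmetric); bilinear matching (`xᵀWy`, `W` initialized to the
identity) is available where asymmetry is wanted. The match value feeds
a logistic output `σ(a·m + b)` with learnable scale and bias, so scores
live strictly in (0, 1).

**Interaction family.** Pairs are expanded to an interaction matrix
(cosine by default; a zero token row has cosine 0 by definition). On
top of it: drmm (per-query-token log-count matching histograms, 30
bins over [−1, 1] with a closed top edge, scored by a shared MLP and
combined through a softmax term gate over query tokens), drmm_tks
(top-k = 5 sorted similarities per query token, zero-padded, same
gated head), knrm (11 Gaussian kernels — exact match μ=1, σ=10⁻³ plus
μ ∈ {0.9, 0.7, …, −0.9}, σ=0.1 — pooled row-wise, logged, summed, then
a linear layer and tanh), match_lstm (an LSTM over candidate tokens,
each concatenated with an attention context over query tokens), and
duet (sum of a local MLP on the flattened interaction matrix and a
distributed branch on mean-pooled sides). Because the input embeddings
are frozen, the attention weights in match_lstm contain no learnable
upstream parameters and the contexts are precomputed once; likewise the
histograms, top-k lists and kernel features are fixed per pair, so
training reduces to the compact heads. For homogeneous tasks the
lexicographically smaller id takes the query role — scoring is
order-deterministic rather than order-invariant, by design.

Histogram/kernel/flattened features are standardized with training
mean and sd (recorded in the scorer). The exact-match kernel's log can
reach −690 for rows with no near-1 entry; unstandardized, such features
saturate the tanh head for some initializations and training collapses
to constant scores.

All neural matchers train with seeded minibatch Adam (lr 10⁻²,
batch 32, ≤ 50 epochs) on binary cross-entropy over a numpy
reverse-mode autodiff core (`_autograd.py`), with early stopping on the
validation run metric (patience 10, best snapshot restored). A
non-finite loss raises an error suggesting a smaller learning rate.
Everything is deterministic given the seed.

## Learning-to-rank integration

The top 5 base models by validation metric (ties lexicographic) are
integrated by LambdaMART (lightgbm lambdarank: pairwise lambda
gradients weighted by the |ΔNDCG| of swapping two candidates in a
group; binary relevance; NDCG truncation from the run metric, else 10).
Defaults: ≤ 100 trees, learning rate 0.1, 15 leaves, min 5 samples per
leaf. Two adaptations make this work at desk scale (tens of groups,
hundreds of pairs):

* **Out-of-fold features.** Base scorers are near-perfect on their own
  training pairs, so a ranker fitted on in-sample scores just learns
  "trust the most overfit model". Each base model is refit five times
  with one fold of training queries held out (same hyperparameters),
  and the ranker trains on these out-of-fold scores.
* **Warm start + round selection.** The boosting starts from
  `init_score` margins given by the validation-best base model —
  specifically its per-group ranks mapped to (−2, 2), which makes the
  warm start invariant to monotone rescaling of that model's scores —
  and the number of boosting rounds actually kept is the one (possibly
  zero) that maximizes validation NDCG, scanned with the patience
  window. Piecewise-constant tree corrections preserve the backbone's
  within-leaf ordering, so the ensemble degrades gracefully to its best
  single model when corrections do not generalize. With ~10 validation
  groups the max-over-models test NDCG is a high-variance target; the
  warm start is what keeps the ensemble within noise of it.

Contribution weights are the per-column split gains of the kept rounds,
normalized to 1; with zero kept rounds the backbone carries weight 1.
Integrated scores are ranking margins: comparable within a query group
(use grouped metrics such as NDCG@k), not across groups.

## Metrics

AUC uses the rank-sum estimator (ties ½). AUPR is the step-wise
precision–recall integral over distinct thresholds, without precision
envelope interpolation. ROC-n sums, over the first n false positives in
descending score order, the true positives ranked above each, divided
by `n·P` — the homology-search convention where perfect separation
scores 1; ties fall back on stable input order with a warning, and
ROC-n with n = all negatives equals AUC. NDCG uses gain `2^rel − 1`
and `log2(rank+1)` discounts (identical to linear gain for binary
relevance). Fmax sweeps distinct prediction scores; precision averages
over proteins with ≥ 1 prediction at the threshold, recall over all
proteins, and the smallest maximizing threshold is reported on ties.
Smin is `min_t sqrt(ru(t)² + mi(t)²)` with information-content-weighted
remaining uncertainty and misinformation, including the empty
prediction set as a threshold. Truth sets are assumed
ontology-propagated by the caller. Every metric is tested against an
independent brute-force oracle (exhaustive pair counting, explicit
threshold re-scans) to 10⁻¹² on hundreds of random instances.

## Synthetic benchmarks

The homogeneous generator plants family structure: unit-norm Gaussian
centers, members = center + isotropic noise. `noise_sd` is the
*expected norm* of the noise vector (per-coordinate variance
`noise_sd²/dim`), i.e. a direct noise-to-signal ratio against the
unit-norm centers — at the default 0.5 an oracle cosine ranker achieves
AUC ≈ 0.9996, leaving the planted signal recoverable but not trivial
after the item-level split. Positives are all within-family pairs;
negatives an equal-size seeded sample of cross-family pairs, so
AUC ≈ 0.5 is the unambiguous null. The heterogeneous generator draws
rank-4 latent factors; a pair is positive when `u_i·v_j` exceeds the
empirical quantile matching the target density (0.1), and observed
embeddings are the factors zero-padded to dim 16, randomly rotated,
plus noise under the same convention. An optional `label_flip_rate`
relabels a seeded fraction of sampled negatives as positives to mimic
the contaminated negative sets of real association benchmarks. Token
layouts repeat the item signal per token with independent noise.

What these fixtures do **not** emulate: real sequence composition,
alignment-based similarity structure, hierarchical family/superfamily
nesting, ontology structure among candidates, or class imbalance at
genomic scale. Passing here shows the machinery recovers a known
planted signal without leaking labels; it does not certify accuracy on
any real benchmark.

Default problem sizes (20×10 items homogeneous, 50×50 heterogeneous,
L=8 tokens) were chosen so a full pipeline run completes in seconds on
one CPU while leaving hundreds of labeled pairs per run.

## Determinism and degenerate inputs

All randomness flows from explicit seeds (numpy `default_rng`,
`random_state` for sklearn, `seed`+`deterministic`+single-thread for
lightgbm); two runs with the same config produce byte-identical metric
tables and weights. Degenerate cases are defined, not crashed on:
cosine of a zero vector is 0 (warned), histogram inputs are clamped to
[−1, 1] within 10⁻⁹ (beyond is an error), single-class training
partitions and groups are rejected with the offending group named, and
NDCG on an all-negative ranking is an error rather than 0.

## Known limitations

* Only 2 of the Siamese and 5 of the interaction architectures are
  implemented; others plug in behind the same `PairScorer` contract.
* Integrated scores are not calibrated probabilities (base-scorer
  probabilities are also used uncalibrated; only orderings are
  asserted anywhere).
* The LambdaMART round selection uses the same validation partition as
  base-model selection; with very few queries both selections are
  noisy, and the max-base-model comparison can go either way outside
  the warm start's reach.
* match_lstm's attention is fixed given the embeddings (see above); a
  learnable-embedding variant would require gradients through the
  interaction matrix.
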