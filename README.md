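# seqsimrank

Semantic similarity ranking for biological sequences from precomputed
embeddings.

Many sequence-analysis problems reduce to ranking: given a query protein,
rank candidate proteins by evolutionary relatedness (remote homology, where
true relatives share < 30 % sequence identity and alignment scores fail);
given a circRNA, rank diseases by association; given a protein, rank GO
terms by annotation confidence. `seqsimrank` treats all of these as one
problem — learning a similarity score `s(q, c) ∈ [0, 1]` over pairs of
embedded items — and borrows its scoring machinery from neural text
matching. It is aimed at bioinformaticians who already have embeddings
(from k-mer profiles, PSSMs, or protein language models) and want a tested,
deterministic pipeline from embeddings to ranked predictions and evaluation
reports.

## What it does

Three families of **base scorers**, one shared contract (pairs → scores):

* **distribution** (classical): `svm rf ert knn mnb gbdt goss dart mlp`
  fit on fused pair features — `[u, v]` for heterogeneous pairs,
  the order-invariant `[|u − v|, u ⊙ v]` for homogeneous pairs — with the
  positive-class probability as the score.
* **representation** (Siamese): a shared encoder `f` maps each side to a
  latent vector; the score is `σ(a·cos(f(u), f(v)) + b)`. MLP encoder for
  vector embeddings (`dssm`), 1-D convolution + max-pooling for per-token
  matrices (`cdssm`).
* **interaction**: the pair is first expanded into a token-by-token
  cosine matrix `M`, `M_ij = cos(u_i, v_j)`, and the score is learned from
  `M` — matching histograms with term gating (`drmm`), top-k similarities
  (`drmmtks`), Gaussian kernel pooling
  `φ_k = Σ_i ln Σ_j exp(−(M_ij − μ_k)²/2σ_k²)` (`knrm`), an
  attention-conditioned recurrent pass (`match_lstm`), or a local +
  distributed sum (`duet`).

Base scorers are evaluated per query group on a validation partition, the
top 5 are **integrated with LambdaMART** (gradient-boosted trees driven by
pairwise lambda gradients weighted by |ΔNDCG|), and per-model contribution
weights are reported. Evaluation covers AUC, AUPR, truncated ROC-n
(ROC50/ROC1 convention: area up to the first n false positives, normalized
by `n·P`), NDCG@k, and the CAFA protein-centric Fmax / Smin. Eight plot
kinds (ROC/PR curves, radar, metric and score histograms, correlation
heatmap, contribution pie, similarity network, 3-D t-SNE) each emit their
underlying data table.

A `synth` module generates benchmarks with planted structure — clustered
"families" for homogeneous tasks, low-rank bipartite associations for
heterogeneous ones — so the entire pipeline is testable offline.

## Worked example

Generate a homogeneous benchmark (20 families × 10 members, embedding
dimension 16, noise 0.5) and run three classical scorers:

```python
from seqsimrank.synth import HomoBenchSpec, generate_homo_benchmark
from seqsimrank.data import write_embedding_table, write_pair_labels

corpus, labels, _ = generate_homo_benchmark(HomoBenchSpec(seed=1))
write_embedding_table(corpus, "bmk_vec.txt")
write_pair_labels(labels, "pos_label.txt", "neg_label.txt")
```

```bash
seqsimrank clf -data_type homo -bmk_vec bmk_vec.txt \
    -bmk_label pos_label.txt neg_label.txt \
    -clf rf knn svm -metric auc -seed 1 -out_dir run_out
```

prints

```
              auc   aupr  ndcg@10
model
rf         1.0000 1.0000   1.0000
knn        0.9978 0.9954   1.0000
svm        1.0000 1.0000   1.0000
integrated 0.8136 0.7578   1.0000

contribution weights: {"knn": 1.0, "rf": 0.0, "svm": 0.0}
```

Reading this: each base scorer separates held-out within-family pairs from
cross-family pairs nearly perfectly (pooled AUC ≈ 1); every test query's
candidates are ranked ideally (NDCG@10 = 1). The integrated row's NDCG@10
is the meaningful column for it — integrated scores are per-group ranking
margins, comparable within a query group but not pooled across groups,
which is why its pooled AUC is lower. The contribution weights say the
ensemble kept the validation-best model (knn here) as its backbone and
found no correction worth adding. `run_out/` contains per-model score
tables, `metrics.tsv`/`metrics.json`, the contribution weights, and a
manifest from which every number can be reproduced; add `-plot` for the
figures.

Heterogeneous runs take two tables
(`-bmk_vec_a circRNA.txt -bmk_vec_b disease.txt`), neural matchers run via
the `arc` subcommand (`-arc dssm cdssm drmm drmmtks match_lstm duet knrm`;
interaction matchers need matrix-layout tables, declared with a
`#shape L D` header or `-layout L D`), and `-gs_mode 0|1|2` widens the
hyperparameter grids.

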