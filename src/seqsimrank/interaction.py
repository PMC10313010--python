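"""Interaction-matrix matchers.

Each pair of token matrices (L_A x D, L_B x D) is turned into a
token-by-token similarity ("interaction") matrix, and the score is
learned from that matrix. Five architectures are provided:

* ``drmm`` — per-query-token matching histograms -> shared feed-forward
  scoring -> softmax term gate over query tokens.
* ``drmm_tks`` — like drmm, but each query token is summarized by its
  top-k candidate similarities (sorted descending, zero-padded).
* ``knrm`` — Gaussian kernel pooling of the interaction matrix into one
  soft-match feature per kernel, followed by a linear layer and tanh.
* ``match_lstm`` — a recurrent pass over the candidate tokens, each
  augmented with an attention context over the query tokens (attention
  weights come from the interaction matrix; with precomputed input
  embeddings these weights carry no learnable upstream parameters, so
  the contexts are computed once up front).
* ``duet`` — the sum of a local subnetwork on the flattened interaction
  matrix and a distributed subnetwork on pooled per-side embeddings.

For homogeneous tasks the lexicographically smaller identifier takes
the query role, making scoring order-deterministic. Other interaction
architectures can be added behind the same PairScorer contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._autograd import Tensor
from ._nn import apply_mlp, glorot, make_mlp, train_loop
from .base import PairScorer
from .data import RankingDataset, TaskSpec
from .metrics import ScoredLabeledList, grouped_metric, parse_metric_flag

__all__ = [
    "INTERACTION_MODELS",
    "KernelBank",
    "HistogramSpec",
    "InteractionHyper",
    "InteractionScorer",
    "interaction_matrix",
    "matching_histogram",
    "kernel_features",
    "train_interaction_model",
]

INTERACTION_MODELS = ("drmm", "drmm_tks", "knrm", "match_lstm", "duet")


@dataclass(frozen=True)
class KernelBank:
    """Gaussian kernels for soft-match pooling.

    Default: one exact-match kernel (mu=1, sigma=1e-3) plus ten soft
    kernels at mu in {0.9, 0.7, ..., -0.9} with sigma=0.1.
    """

    centers: tuple = (1.0, 0.9, 0.7, 0.5, 0.3, 0.1, -0.1, -0.3, -0.5, -0.7, -0.9)
    widths: tuple = (1e-3,) + (0.1,) * 10

    def __post_init__(self):
        centers = tuple(float(c) for c in self.centers)
        widths = tuple(float(w) for w in self.widths)
        if len(centers) != len(widths):
            raise ValueError("centers and widths must have equal length")
        if any(w <= 0 for w in widths):
            raise ValueError("kernel widths must be positive")
        if any(not -1.0 <= c <= 1.0 for c in centers):
            raise ValueError("kernel centers must lie within [-1, 1]")
        exact = sum(1 for c, w in zip(centers, widths) if c == 1.0 and w < 0.01)
        if exact != 1:
            raise ValueError("exactly one exact-match kernel (mu=1, small sigma) required")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "widths", widths)

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class HistogramSpec:
    """Matching-histogram layout: B equal-width bins over [-1, 1], the
    top edge closed, counts transformed as ln(1 + count)."""

    bins: int = 30

    def __post_init__(self):
        if self.bins < 2:
            raise ValueError("histogram needs at least 2 bins")


@dataclass(frozen=True)
class InteractionHyper:
    """Per-architecture settings shared by the five matchers."""

    measure: str = "cosine"  # cosine | dot
    histogram: HistogramSpec = HistogramSpec()
    kernels: KernelBank = KernelBank()
    top_k: int = 5
    hidden: int = 16
    lstm_hidden: int = 16
    epochs: int = 50
    learning_rate: float = 1e-2
    batch_size: int = 32
    patience: int = 10


# ---------------------------------------------------------------------------
# operators


def interaction_matrix(A: np.ndarray, B: np.ndarray, measure: str = "cosine") -> np.ndarray:
    """Token-by-token similarity matrix, entry (i, j) = measure(A_i, B_j).

    Under cosine, an all-zero token row is matched as 0.
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"channel counts differ: {A.shape[1]} vs {B.shape[1]}"
        )
    if measure == "dot":
        return A @ B.T
    if measure == "cosine":
        na = np.linalg.norm(A, axis=1)
        nb = np.linalg.norm(B, axis=1)
        denom = np.outer(na, nb)
        out = np.zeros((A.shape[0], B.shape[0]))
        np.divide(A @ B.T, denom, out=out, where=denom > 0)
        return out
    raise ValueError(f"unknown measure {measure!r}")


def matching_histogram(row: np.ndarray, spec: HistogramSpec) -> np.ndarray:
    """Log-count histogram of one query token's similarities.

    Counts conserve exactly: sum_b (e^h_b - 1) equals the row length.
    """
    row = np.asarray(row, float)
    if row.size == 0:
        raise ValueError("matching_histogram requires a non-empty row")
    if np.any(row < -1 - 1e-9) or np.any(row > 1 + 1e-9):
        raise ValueError("similarities must lie within [-1, 1] (tolerance 1e-9)")
    row = np.clip(row, -1.0, 1.0)
    width = 2.0 / spec.bins
    idx = np.minimum(((row + 1.0) / width).astype(int), spec.bins - 1)
    counts = np.bincount(idx, minlength=spec.bins)
    return np.log1p(counts.astype(float))


def kernel_features(M: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Kernel-pooled soft-match features.

    phi_k = sum_i ln( sum_j exp(-(M_ij - mu_k)^2 / (2 sigma_k^2)) ):
    row-wise Gaussian pooling, logged, summed over query tokens.
    """
    M = np.atleast_2d(np.asarray(M, float))
    if M.size == 0:
        raise ValueError("kernel_features requires a non-empty matrix")
    mu = np.asarray(bank.centers)[:, None, None]
    sigma = np.asarray(bank.widths)[:, None, None]
    pooled = np.exp(-((M[None] - mu) ** 2) / (2.0 * sigma**2)).sum(axis=2)
    return np.log(np.maximum(pooled, 1e-300)).sum(axis=1)


# ---------------------------------------------------------------------------
# scorer


def _orient(pair: tuple, task: TaskSpec) -> tuple:
    if task.kind == "homogeneous":
        a, b = pair
        return (a, b) if a <= b else (b, a)
    return pair


class InteractionScorer(PairScorer):
    """A trained interaction matcher."""

    #: per-arch feature key that is standardized with training statistics
    #: (raw kernel/log-count magnitudes would saturate the tanh/sigmoid heads)
    _NORMALIZED_KEY = {"drmm": "H", "drmm_tks": "T", "knrm": "phi", "duet": "flat"}

    def __init__(self, arch: str, hyper: InteractionHyper, params: dict, seed: int):
        super().__init__(seed=seed, metadata={"arch": arch})
        self.name = arch
        self.arch = arch
        self.hyper = hyper
        self.params = params
        self.feature_stats: tuple | None = None  # (mean, sd) for the normalized key

    # input assembly --------------------------------------------------------

    def _inputs(self, pairs: Sequence[tuple], task: TaskSpec) -> dict:
        """Precompute the fixed per-pair feature arrays for this arch."""
        hyper = self.hyper
        As, Bs, Ms = [], [], []
        for pair in pairs:
            q, c = _orient(pair, task)
            A = task.query_corpus.get(q) if task.kind == "heterogeneous" else task.corpus_a.get(q)
            B = task.candidate_corpus.get(c)
            As.append(A)
            Bs.append(B)
            Ms.append(interaction_matrix(A, B, hyper.measure))
        A = np.stack(As)
        B = np.stack(Bs)
        M = np.stack(Ms)
        out = {"A": A, "B": B, "M": M}
        if self.arch == "drmm":
            out["H"] = np.stack(
                [
                    [matching_histogram(m[i], hyper.histogram) for i in range(m.shape[0])]
                    for m in M
                ]
            )
        elif self.arch == "drmm_tks":
            k = hyper.top_k
            srt = -np.sort(-M, axis=2)  # descending along candidate tokens
            if srt.shape[2] >= k:
                out["T"] = srt[:, :, :k]
            else:
                pad = np.zeros((*srt.shape[:2], k - srt.shape[2]))
                out["T"] = np.concatenate([srt, pad], axis=2)
        elif self.arch == "knrm":
            out["phi"] = np.stack([kernel_features(m, hyper.kernels) for m in M])
        elif self.arch == "match_lstm":
            # attention over query tokens from the (fixed) interaction matrix
            att = np.exp(M - M.max(axis=1, keepdims=True))
            att = att / att.sum(axis=1, keepdims=True)  # (n, Lq, Lc)
            context = np.einsum("nqc,nqd->ncd", att, A)
            out["X"] = np.concatenate([B, context], axis=2)  # (n, Lc, 2D)
        elif self.arch == "duet":
            out["flat"] = M.reshape(M.shape[0], -1)
            out["pa"] = A.mean(axis=1)
            out["pb"] = B.mean(axis=1)
        key = self._NORMALIZED_KEY.get(self.arch)
        if key is not None and self.feature_stats is not None:
            mean, sd = self.feature_stats
            out[key] = (out[key] - mean) / sd
        return out

    def fit_feature_stats(self, inputs: dict) -> dict:
        """Record feature mean/sd from the (raw) training inputs and return
        the standardized inputs."""
        key = self._NORMALIZED_KEY.get(self.arch)
        if key is None:
            return inputs
        arr = inputs[key]
        axes = tuple(range(arr.ndim - 1))
        mean = arr.mean(axis=axes)
        sd = arr.std(axis=axes)
        sd = np.where(sd > 1e-12, sd, 1.0)
        self.feature_stats = (mean, sd)
        inputs = dict(inputs)
        inputs[key] = (arr - mean) / sd
        return inputs

    # forwards ---------------------------------------------------------------

    def _gated_forward(self, F: np.ndarray, Q: np.ndarray) -> Tensor:
        """Shared drmm / drmm_tks head: per-token MLP + softmax term gate."""
        z = apply_mlp(Tensor(F), self.params["score_mlp"], last_linear=True)  # (n, Lq, 1)
        z = z.reshape(z.shape[0], z.shape[1])
        gate_logits = (Tensor(Q) @ self.params["gate_W"]).reshape(Q.shape[0], Q.shape[1])
        gate = gate_logits.softmax(axis=1)
        s = (gate * z).sum(axis=1)
        return (s * self.params["out_scale"] + self.params["out_bias"]).sigmoid()

    def _forward(self, inputs: dict, idx=None) -> Tensor:
        take = (lambda x: x) if idx is None else (lambda x: x[idx])
        if self.arch == "drmm":
            return self._gated_forward(take(inputs["H"]), take(inputs["A"]))
        if self.arch == "drmm_tks":
            return self._gated_forward(take(inputs["T"]), take(inputs["A"]))
        if self.arch == "knrm":
            phi = Tensor(take(inputs["phi"]))
            out = (phi @ self.params["w"] + self.params["b"]).tanh()
            out = out.reshape(phi.shape[0])
            return (out * self.params["out_scale"] + self.params["out_bias"]).sigmoid()
        if self.arch == "match_lstm":
            return self._lstm_forward(take(inputs["X"]))
        if self.arch == "duet":
            local = apply_mlp(Tensor(take(inputs["flat"])), self.params["local"], last_linear=True)
            za = apply_mlp(Tensor(take(inputs["pa"])), self.params["dist"])
            zb = apply_mlp(Tensor(take(inputs["pb"])), self.params["dist"])
            dist = (za * zb) @ self.params["dist_out"]
            s = (local + dist).reshape(local.shape[0])
            return (s + self.params["out_bias"]).sigmoid()
        raise ValueError(f"unknown arch {self.arch!r}")

    def _lstm_forward(self, X: np.ndarray) -> Tensor:
        n, L, _ = X.shape
        H = self.hyper.lstm_hidden
        Wx, Wh, b = self.params["lstm_Wx"], self.params["lstm_Wh"], self.params["lstm_b"]
        h = Tensor(np.zeros((n, H)))
        c = Tensor(np.zeros((n, H)))
        Xt = Tensor(X)
        for t in range(L):
            gates = Xt[:, t, :] @ Wx + h @ Wh + b  # (n, 4H)
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            o = gates[:, 2 * H : 3 * H].sigmoid()
            g = gates[:, 3 * H : 4 * H].tanh()
            c = f * c + i * g
            h = o * c.tanh()
        out = (h @ self.params["out_W"] + self.params["out_b"]).reshape(n)
        return out.sigmoid()

    def score_pairs(self, pairs: Sequence[tuple], task: TaskSpec) -> np.ndarray:
        if len(pairs) == 0:
            return np.zeros(0)
        return self._forward(self._inputs(pairs, task)).data

    def retrain(self, dataset: RankingDataset) -> "InteractionScorer":
        """Retrain the same architecture/hyperparameters on the dataset's
        current training partition (used for out-of-fold stacking scores)."""
        return train_interaction_model(self.arch, dataset, self.hyper, self.seed)

    # persistence ------------------------------------------------------------

    def _trainable(self) -> list:
        flat = []
        for value in self.params.values():
            if isinstance(value, list):
                for W, b in value:
                    flat.extend([W, b])
            else:
                flat.append(value)
        return flat

    def __getstate__(self):
        blocks = {}
        for key, value in self.params.items():
            if isinstance(value, list):
                for k, (W, b) in enumerate(value):
                    blocks[f"{key}.{k}.W"] = W.data
                    blocks[f"{key}.{k}.b"] = b.data
            else:
                blocks[key] = value.data
        return {
            "arch": self.arch,
            "hyper": self.hyper,
            "blocks": blocks,
            "seed": self.seed,
            "metadata": self.metadata,
            "feature_stats": self.feature_stats,
        }

    def __setstate__(self, state):
        params: dict = {}
        layers: dict = {}
        for name, arr in state["blocks"].items():
            if "." in name:
                key, k, wb = name.split(".")
                layers.setdefault(key, {}).setdefault(int(k), {})[wb] = arr
            else:
                params[name] = Tensor(arr, requires_grad=True)
        for key, by_idx in layers.items():
            params[key] = [
                (
                    Tensor(by_idx[k]["W"], requires_grad=True),
                    Tensor(by_idx[k]["b"], requires_grad=True),
                )
                for k in sorted(by_idx)
            ]
        self.__init__(state["arch"], state["hyper"], params, state["seed"])
        self.metadata = state["metadata"]
        self.feature_stats = state["feature_stats"]


def _init_params(arch: str, hyper: InteractionHyper, shapes: dict, rng) -> dict:
    params: dict = {
        "out_scale": Tensor(np.array(3.0), requires_grad=True),
        "out_bias": Tensor(np.array(0.0), requires_grad=True),
    }
    D = shapes["D"]
    if arch == "drmm":
        params["score_mlp"] = make_mlp(rng, [hyper.histogram.bins, hyper.hidden, 1])
        params["gate_W"] = Tensor(glorot(rng, D, 1), requires_grad=True)
    elif arch == "drmm_tks":
        params["score_mlp"] = make_mlp(rng, [hyper.top_k, hyper.hidden, 1])
        params["gate_W"] = Tensor(glorot(rng, D, 1), requires_grad=True)
    elif arch == "knrm":
        params["w"] = Tensor(glorot(rng, len(hyper.kernels), 1), requires_grad=True)
        params["b"] = Tensor(np.zeros(1), requires_grad=True)
    elif arch == "match_lstm":
        H = hyper.lstm_hidden
        params["lstm_Wx"] = Tensor(glorot(rng, 2 * D, 4 * H), requires_grad=True)
        params["lstm_Wh"] = Tensor(glorot(rng, H, 4 * H), requires_grad=True)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        params["lstm_b"] = Tensor(b, requires_grad=True)
        params["out_W"] = Tensor(glorot(rng, H, 1), requires_grad=True)
        params["out_b"] = Tensor(np.zeros(1), requires_grad=True)
    elif arch == "duet":
        params["local"] = make_mlp(rng, [shapes["flat"], 32, 1])
        params["dist"] = make_mlp(rng, [D, 32, hyper.hidden])
        params["dist_out"] = Tensor(glorot(rng, hyper.hidden, 1), requires_grad=True)
    else:
        raise ValueError(
            f"unknown interaction architecture {arch!r}; valid: "
            + ", ".join(INTERACTION_MODELS)
        )
    return params


def train_interaction_model(
    arch: str,
    dataset: RankingDataset,
    hyper: InteractionHyper | None = None,
    seed: int = 0,
    metric: str = "auc",
) -> InteractionScorer:
    """Train one interaction matcher with binary cross-entropy.

    Requires matrix-layout (token) corpora; per-pair interaction inputs
    are precomputed once, and early stopping monitors the run metric on
    the validation partition.
    """
    if arch not in INTERACTION_MODELS:
        raise ValueError(
            f"unknown interaction architecture {arch!r}; valid: "
            + ", ".join(INTERACTION_MODELS)
        )
    task = dataset.task
    for corpus in (task.query_corpus, task.candidate_corpus):
        if corpus.layout != "matrix":
            raise ValueError(
                "interaction matchers require matrix-layout corpora; "
                "generate or declare token-matrix embeddings"
            )
    hyper = hyper or InteractionHyper()

    train_pairs, y, _ = dataset.pairs_in("train")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("training partition must contain both classes")

    rng = np.random.default_rng(seed)
    Lq, D = task.query_corpus.shape
    Lc, _ = task.candidate_corpus.shape
    shapes = {"D": D, "flat": Lq * Lc}
    scorer = InteractionScorer(arch, hyper, _init_params(arch, hyper, shapes, rng), seed)

    inputs = scorer.fit_feature_stats(scorer._inputs(train_pairs, task))
    flag = parse_metric_flag(metric)
    valid_pairs, vy, vg = dataset.pairs_in("valid")

    def validate():
        scores = scorer.score_pairs(valid_pairs, task)
        return grouped_metric(ScoredLabeledList(scores, vy, groups=vg), flag)

    history = train_loop(
        lambda idx: scorer._forward(inputs, idx),
        scorer._trainable(),
        len(train_pairs),
        y.astype(float),
        validate=validate if len(valid_pairs) else None,
        epochs=hyper.epochs,
        batch_size=hyper.batch_size,
        lr=hyper.learning_rate,
        patience=hyper.patience,
        seed=seed,
    )
    scorer.metadata["loss_history"] = history
    return scorer
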