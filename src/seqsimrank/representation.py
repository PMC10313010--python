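"""Siamese ("representation") matchers.

One encoder, shared between the two sides of a pair, maps each item to a
latent vector; a matching layer on the two latents yields the similarity
score through a logistic output. Two encoder architectures are provided:

* ``dssm_like`` — a multilayer perceptron on vector embeddings.
* ``cdssm_like`` — a 1-D convolution over the token matrix followed by
  max-pooling and a dense stack.

Matching is ``cosine`` (parameter-free; exactly symmetric in its
arguments) or ``bilinear`` (x' W y with W learned, initialized to the
identity). Further Siamese variants plug in behind the same
:class:`~seqsimrank.base.PairScorer` contract by adding an architecture
tag here.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._autograd import Tensor, concat
from ._nn import apply_mlp, glorot, make_mlp, train_loop
from .base import PairScorer
from .data import RankingDataset, TaskSpec
from .metrics import ScoredLabeledList, grouped_metric, parse_metric_flag

__all__ = [
    "REPRESENTATION_MODELS",
    "EncoderConfig",
    "SiameseScorer",
    "match_latent",
    "train_representation_model",
]

REPRESENTATION_MODELS = ("dssm", "cdssm")


@dataclass(frozen=True)
class EncoderConfig:
    architecture: str = "dssm_like"  # dssm_like | cdssm_like
    hidden: tuple = (64, 32)
    latent_dim: int = 16
    activation: str = "tanh"
    match: str = "cosine"  # cosine | bilinear
    conv_window: int = 3
    conv_channels: int = 32
    epochs: int = 50
    learning_rate: float = 1e-2
    batch_size: int = 32
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("dssm_like", "cdssm_like"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.latent_dim < 2:
            raise ValueError("latent dimension must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.match not in ("cosine", "bilinear"):
            raise ValueError(f"unknown matching scheme {self.match!r}")


def match_latent(x: np.ndarray, y: np.ndarray, scheme: str = "cosine", W: np.ndarray | None = None) -> float:
    """Raw match value of two latent vectors.

    cosine is in [-1, 1]; a zero vector is matched as 0 with a warning.
    bilinear returns x' W y (unsquashed).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("latent dimensions must agree")
    if scheme == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0.0 or ny == 0.0:
            warnings.warn("cosine of a zero vector defined as 0")
            return 0.0
        return float(x @ y / (nx * ny))
    if scheme == "bilinear":
        if W is None:
            W = np.eye(x.size)
        return float(x @ W @ y)
    raise ValueError(f"unknown matching scheme {scheme!r}")


def _batched_cosine(zx: Tensor, zy: Tensor, eps: float = 1e-12) -> Tensor:
    dot = (zx * zy).sum(axis=1)
    nx = ((zx * zx).sum(axis=1) + eps).pow(0.5)
    ny = ((zy * zy).sum(axis=1) + eps).pow(0.5)
    return dot / (nx * ny)


class SiameseScorer(PairScorer):
    """A trained Siamese matcher: shared encoder + matching + logistic."""

    def __init__(self, config: EncoderConfig, params: dict, seed: int):
        super().__init__(seed=seed, metadata={"architecture": config.architecture})
        self.name = "dssm" if config.architecture == "dssm_like" else "cdssm"
        self.config = config
        self.params = params  # name -> Tensor

    # encoding -------------------------------------------------------------

    def _encode(self, X: np.ndarray) -> Tensor:
        cfg = self.config
        if cfg.architecture == "dssm_like":
            return apply_mlp(Tensor(X), self.params["encoder"], cfg.activation)
        # cdssm_like: (n, L, D) -> windows -> conv -> max-pool -> dense
        n, L, D = X.shape
        w = min(cfg.conv_window, L)
        windows = np.stack(
            [X[:, i : i + w, :].reshape(n, w * D) for i in range(L - w + 1)], axis=1
        )  # (n, L-w+1, w*D)
        conv = (Tensor(windows) @ self.params["conv_W"] + self.params["conv_b"]).tanh()
        pooled = conv.max(axis=1)  # (n, channels)
        return apply_mlp(pooled, self.params["encoder"], cfg.activation)

    def _forward(self, Xq: np.ndarray, Xc: np.ndarray) -> Tensor:
        zq = self._encode(Xq)
        zc = self._encode(Xc)
        if self.config.match == "cosine":
            m = _batched_cosine(zq, zc)
        else:
            m = (zq @ self.params["bilinear_W"] * zc).sum(axis=1)
        logit = m * self.params["out_scale"] + self.params["out_bias"]
        return logit.sigmoid()

    def score_pairs(self, pairs: Sequence[tuple], task: TaskSpec) -> np.ndarray:
        if len(pairs) == 0:
            return np.zeros(0)
        Xq = np.stack([task.query_corpus.get(q) for q, _ in pairs])
        Xc = np.stack([task.candidate_corpus.get(c) for _, c in pairs])
        return self._forward(Xq, Xc).data

    def retrain(self, dataset: RankingDataset) -> "SiameseScorer":
        """Retrain the same configuration on the dataset's current training
        partition (used for out-of-fold stacking scores)."""
        return train_representation_model(self.config, dataset, seed=self.seed)

    def parameter_blocks(self) -> dict:
        """Raw parameter arrays; the encoder block is shared across sides."""
        out = {}
        for key, value in self.params.items():
            if isinstance(value, list):
                for k, (W, b) in enumerate(value):
                    out[f"{key}.{k}.W"] = W.data
                    out[f"{key}.{k}.b"] = b.data
            else:
                out[key] = value.data
        return out

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
        return {
            "config": self.config,
            "blocks": self.parameter_blocks(),
            "seed": self.seed,
            "metadata": self.metadata,
        }

    def __setstate__(self, state):
        cfg = state["config"]
        fresh = _init_params(cfg, input_dim=None, blocks=state["blocks"])
        self.__init__(cfg, fresh, state["seed"])
        self.metadata = state["metadata"]


def _init_params(cfg: EncoderConfig, input_dim, blocks: dict | None = None) -> dict:
    """Fresh (or restored, when blocks given) parameter tensors."""
    if blocks is not None:
        params: dict = {}
        layers: dict = {}
        for name, arr in blocks.items():
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
        return params
    rng = np.random.default_rng(cfg.seed)
    params = {}
    if cfg.architecture == "dssm_like":
        sizes = [input_dim, *cfg.hidden, cfg.latent_dim]
    else:
        L, D = input_dim
        w = min(cfg.conv_window, L)
        params["conv_W"] = Tensor(glorot(rng, w * D, cfg.conv_channels), requires_grad=True)
        params["conv_b"] = Tensor(np.zeros(cfg.conv_channels), requires_grad=True)
        sizes = [cfg.conv_channels, *cfg.hidden, cfg.latent_dim]
    params["encoder"] = make_mlp(rng, sizes)
    if cfg.match == "bilinear":
        params["bilinear_W"] = Tensor(np.eye(cfg.latent_dim), requires_grad=True)
    params["out_scale"] = Tensor(np.array(3.0), requires_grad=True)
    params["out_bias"] = Tensor(np.array(0.0), requires_grad=True)
    return params


def train_representation_model(
    config: EncoderConfig,
    dataset: RankingDataset,
    seed: int | None = None,
    metric: str = "auc",
) -> SiameseScorer:
    """Train a Siamese matcher with binary cross-entropy.

    The encoder is one parameter block applied to both sides, so weight
    sharing is exact by construction. Early stopping monitors the run
    metric on the validation partition.
    """
    task = dataset.task
    if seed is None:
        seed = config.seed
    elif seed != config.seed:
        config = dataclasses.replace(config, seed=seed)
    corpus = task.query_corpus
    if config.architecture == "cdssm_like" and corpus.layout != "matrix":
        raise ValueError("cdssm_like requires matrix-layout (token) corpora")
    if config.architecture == "dssm_like" and corpus.layout != "vector":
        raise ValueError("dssm_like requires vector-layout corpora")

    train_pairs, y, _ = dataset.pairs_in("train")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("training partition must contain both classes")
    Xq = np.stack([task.query_corpus.get(q) for q, _ in train_pairs])
    Xc = np.stack([task.candidate_corpus.get(c) for _, c in train_pairs])

    if config.architecture == "dssm_like":
        input_dim = Xq.shape[1]
    else:
        input_dim = Xq.shape[1:]
    params = _init_params(config, input_dim)
    scorer = SiameseScorer(config, params, seed)

    flag = parse_metric_flag(metric)
    valid_pairs, vy, vg = dataset.pairs_in("valid")

    def validate():
        scores = scorer.score_pairs(valid_pairs, task)
        return grouped_metric(ScoredLabeledList(scores, vy, groups=vg), flag)

    history = train_loop(
        lambda idx: scorer._forward(Xq[idx], Xc[idx]),
        scorer._trainable(),
        len(train_pairs),
        y.astype(float),
        validate=validate if len(valid_pairs) else None,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        patience=config.patience,
        seed=seed,
    )
    scorer.metadata["loss_history"] = history
    return scorer
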