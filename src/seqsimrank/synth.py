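"""Synthetic benchmarks with planted similarity structure.

Two generators emulate the two task layouts the pipeline supports:

* homogeneous — items fall into "families" (clusters around unit-norm
  Gaussian centers); within-family pairs are the positives. This mirrors
  remote-homology style benchmarks where relatives share a superfamily.
* heterogeneous — a bipartite association structure driven by low-rank
  latent factors; pair (i, j) is positive when the latent inner product
  u_i . v_j exceeds the empirical quantile matching the target density.
  This mirrors RNA-disease association benchmarks.

``noise_sd`` is the expected *norm* of the additive noise vector (the
noise is isotropic Gaussian with per-coordinate variance
``noise_sd**2 / dim``), so it reads directly as a noise-to-signal ratio
against the unit-norm family centers.

Negatives are an equal-size seeded sample of the non-positive pairs, so
AUC ~ 0.5 is the unambiguous null. An optional ``label_flip_rate``
relabels a seeded fraction of sampled negatives as positives to simulate
the contaminated negative sets common in association benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EmbeddedCorpus, PairLabelSet

__all__ = [
    "HomoBenchSpec",
    "HeteroBenchSpec",
    "generate_homo_benchmark",
    "generate_hetero_benchmark",
]


@dataclass(frozen=True)
class HomoBenchSpec:
    """Clustered-family benchmark parameters."""

    n_families: int = 20
    members_per_family: int = 10
    dim: int = 16
    noise_sd: float = 0.5
    seed: int = 0
    layout: str = "vector"
    tokens: int = 8  # token count when layout == "matrix"
    label_flip_rate: float = 0.0

    def __post_init__(self):
        if self.n_families < 2 or self.members_per_family < 2 or self.dim < 2:
            raise ValueError("counts and dimension must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.label_flip_rate < 1.0:
            raise ValueError("label_flip_rate must be in [0, 1)")
        if self.layout not in ("vector", "matrix"):
            raise ValueError("layout must be 'vector' or 'matrix'")


@dataclass(frozen=True)
class HeteroBenchSpec:
    """Low-rank bipartite association benchmark parameters."""

    n_a: int = 50
    n_b: int = 50
    latent_dim: int = 4
    embed_dim: int = 16
    target_density: float = 0.1
    noise_sd: float = 0.3
    seed: int = 0
    layout: str = "vector"
    tokens: int = 8
    label_flip_rate: float = 0.0

    def __post_init__(self):
        if self.n_a < 4 or self.n_b < 4:
            raise ValueError("entity counts must be >= 4")
        if not 0.0 < self.target_density < 0.5:
            raise ValueError("target_density must be in (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.embed_dim < self.latent_dim:
            raise ValueError("embed_dim must be >= latent_dim")
        if not 0.0 <= self.label_flip_rate < 1.0:
            raise ValueError("label_flip_rate must be in [0, 1)")
        if self.layout not in ("vector", "matrix"):
            raise ValueError("layout must be 'vector' or 'matrix'")


def _tokenize(signal: np.ndarray, tokens: int, noise_sd: float, rng) -> np.ndarray:
    """Expand item signals (n, D) into token matrices (n, L, D).

    Each token repeats the item's signal plus independent noise, so the
    family/latent structure is present in every token row.
    """
    n, d = signal.shape
    sd = noise_sd / np.sqrt(d)
    return signal[:, None, :] + rng.normal(0.0, sd, size=(n, tokens, d))


def generate_homo_benchmark(spec: HomoBenchSpec):
    """Return (corpus, labels, truth) for the clustered-family benchmark.

    truth maps each item id to its family index. Positives are all
    within-family pairs (canonical id order); negatives an equal-size
    seeded sample of cross-family pairs.
    """
    rng = np.random.default_rng(spec.seed)
    centers = rng.normal(size=(spec.n_families, spec.dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)

    ids, families = [], []
    for f in range(spec.n_families):
        for m in range(spec.members_per_family):
            ids.append(f"f{f:03d}m{m:03d}")
            families.append(f)
    families = np.asarray(families)
    signal = centers[families]
    if spec.layout == "matrix":
        values = _tokenize(signal, spec.tokens, spec.noise_sd, rng)
    else:
        sd = spec.noise_sd / np.sqrt(spec.dim)
        values = signal + rng.normal(0.0, sd, size=signal.shape)
    corpus = EmbeddedCorpus(tuple(ids), values, layout=spec.layout)

    positives = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if families[i] == families[j]:
                positives.append((ids[i], ids[j]))

    cross = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if families[i] != families[j]
    ]
    pick = rng.choice(len(cross), size=len(positives), replace=False)
    negatives = [cross[k] for k in sorted(pick)]
    positives, negatives = _apply_label_flips(
        positives, negatives, spec.label_flip_rate, rng
    )
    labels = PairLabelSet(tuple(positives), tuple(negatives))
    truth = dict(zip(ids, (int(f) for f in families)))
    return corpus, labels, truth


def generate_hetero_benchmark(spec: HeteroBenchSpec):
    """Return (corpus_a, corpus_b, labels, truth) for the bipartite benchmark.

    truth holds the latent factors and the boolean association matrix.
    Observed embeddings are the latent factors zero-padded to embed_dim,
    passed through a seeded random rotation, plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(size=(spec.n_a, spec.latent_dim))
    v = rng.normal(size=(spec.n_b, spec.latent_dim))
    affinity = u @ v.T
    # threshold at the empirical quantile so the positive count is forced
    n_pos = int(round(spec.target_density * spec.n_a * spec.n_b))
    n_pos = max(n_pos, 1)
    flat = np.sort(affinity.ravel())[::-1]
    threshold = flat[n_pos - 1]
    assoc = affinity >= threshold

    ids_a = tuple(f"a{i:04d}" for i in range(spec.n_a))
    ids_b = tuple(f"b{j:04d}" for j in range(spec.n_b))

    def embed(factors: np.ndarray) -> np.ndarray:
        padded = np.zeros((factors.shape[0], spec.embed_dim))
        padded[:, : spec.latent_dim] = factors
        q, _ = np.linalg.qr(rng.normal(size=(spec.embed_dim, spec.embed_dim)))
        rotated = padded @ q
        if spec.layout == "matrix":
            return _tokenize(rotated, spec.tokens, spec.noise_sd, rng)
        sd = spec.noise_sd / np.sqrt(spec.embed_dim)
        return rotated + rng.normal(0.0, sd, size=rotated.shape)

    corpus_a = EmbeddedCorpus(ids_a, embed(u), layout=spec.layout)
    corpus_b = EmbeddedCorpus(ids_b, embed(v), layout=spec.layout)

    pos_idx = np.argwhere(assoc)
    positives = [(ids_a[i], ids_b[j]) for i, j in pos_idx]
    neg_pool = np.argwhere(~assoc)
    pick = rng.choice(len(neg_pool), size=len(positives), replace=False)
    negatives = [(ids_a[i], ids_b[j]) for i, j in neg_pool[sorted(pick)]]
    positives, negatives = _apply_label_flips(
        positives, negatives, spec.label_flip_rate, rng
    )
    labels = PairLabelSet(tuple(positives), tuple(negatives))
    truth = {"u": u, "v": v, "association": assoc, "threshold": float(threshold)}
    return corpus_a, corpus_b, labels, truth


def _apply_label_flips(positives, negatives, rate, rng):
    """Relabel a seeded fraction of negatives as positives (contamination)."""
    if rate <= 0.0:
        return positives, negatives
    n_flip = int(round(rate * len(negatives)))
    if n_flip == 0:
        return positives, negatives
    flip = set(rng.choice(len(negatives), size=n_flip, replace=False).tolist())
    flipped = [p for k, p in enumerate(negatives) if k in flip]
    kept = [p for k, p in enumerate(negatives) if k not in flip]
    return list(positives) + flipped, kept
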