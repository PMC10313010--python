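"""Pair feature fusion for the classical (distribution) scorers.

Two schemes map an embedding pair (u, v) to one feature vector:

* ``concat`` — [u, v]; the convention for heterogeneous tasks, where
  the two sides live in different feature spaces.
* ``symmetric`` — [|u - v|, u * v] (elementwise); order-invariant, the
  default for homogeneous tasks where a similarity score should not
  depend on argument order. Requires dim(u) == dim(v).

Token-matrix embeddings are mean-pooled over tokens before fusion, so
the same schemes apply to both layouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import TaskSpec

__all__ = ["PairFeatureScheme", "make_pair_features", "pair_feature_matrix", "default_scheme"]


@dataclass(frozen=True)
class PairFeatureScheme:
    name: str  # "concat" | "symmetric"

    def __post_init__(self):
        if self.name not in ("concat", "symmetric"):
            raise ValueError(f"unknown feature scheme {self.name!r}")

    def output_dim(self, dim_u: int, dim_v: int) -> int:
        if self.name == "concat":
            return dim_u + dim_v
        if dim_u != dim_v:
            raise ValueError("symmetric scheme requires equal dimensions")
        return 2 * dim_u


def _pool(x: np.ndarray) -> np.ndarray:
    """Mean-pool a token matrix to a vector; vectors pass through."""
    return x.mean(axis=0) if x.ndim == 2 else x


def make_pair_features(u: np.ndarray, v: np.ndarray, scheme: PairFeatureScheme) -> np.ndarray:
    u = _pool(np.asarray(u, dtype=float))
    v = _pool(np.asarray(v, dtype=float))
    if scheme.name == "concat":
        return np.concatenate([u, v])
    if u.shape != v.shape:
        raise ValueError(
            f"symmetric scheme requires equal dims, got {u.shape} and {v.shape}"
        )
    return np.concatenate([np.abs(u - v), u * v])


def pair_feature_matrix(
    pairs: Sequence[tuple], task: TaskSpec, scheme: PairFeatureScheme
) -> np.ndarray:
    """Stack fused features for a list of identifier pairs."""
    rows = [make_pair_features(*task.resolve(p), scheme) for p in pairs]
    return np.asarray(rows, dtype=float)


def default_scheme(task: TaskSpec) -> PairFeatureScheme:
    """symmetric for homogeneous tasks, concat for heterogeneous."""
    return PairFeatureScheme("symmetric" if task.kind == "homogeneous" else "concat")
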