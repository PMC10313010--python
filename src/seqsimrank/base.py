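"""Common scorer protocol and persistence.

Every trained base model — classical classifier, Siamese matcher, or
interaction matcher — exposes the same surface: ``score_pairs`` maps
(query, candidate) identifier pairs to similarity scores in [0, 1],
deterministically. Models persist to a self-describing pickle archive
holding the family name, feature scheme, chosen grid point, seed, and
fitted parameters; reloading reproduces scores bit-identically on the
same platform.
"""

from __future__ import annotations

import pickle
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import TaskSpec

__all__ = ["PairScorer", "load_scorer"]


class PairScorer(ABC):
    """A trained model scoring (query, candidate) pairs in [0, 1]."""

    #: family name, e.g. "rf", "dssm", "knrm"
    name: str = "base"

    def __init__(self, seed: int = 0, metadata: dict | None = None):
        self.seed = seed
        self.metadata = dict(metadata or {})

    @abstractmethod
    def score_pairs(self, pairs: Sequence[tuple], task: TaskSpec) -> np.ndarray:
        """One similarity score in [0, 1] per pair; deterministic."""

    def save(self, path) -> None:
        archive = {
            "format": "seqsimrank-scorer",
            "family": self.name,
            "class": type(self).__name__,
            "seed": self.seed,
            "metadata": self.metadata,
            "state": self.__getstate__(),
        }
        with Path(path).open("wb") as fh:
            pickle.dump(archive, fh)


def load_scorer(path) -> PairScorer:
    """Reload a persisted scorer archive."""
    with Path(path).open("rb") as fh:
        archive = pickle.load(fh)
    if archive.get("format") != "seqsimrank-scorer":
        raise ValueError(f"{path}: not a scorer archive")
    from . import distribution, representation, interaction  # registry

    for mod in (distribution, representation, interaction):
        cls = getattr(mod, archive["class"], None)
        if cls is not None:
            obj = cls.__new__(cls)
            obj.__setstate__(archive["state"])
            return obj
    raise ValueError(f"unknown scorer class {archive['class']!r}")
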