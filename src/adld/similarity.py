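"""Similarity degree, matching matrix and similarity/dissimilarity matrix.

The similarity degree of a pair is the total number of APs retained in its
ADLD:

    SD = sum of fragment lengths (artery and by-path) + number of free points

Over a collection of n sequences this fills the lower triangle of the
matching matrix d_ij = SD(pair i, j); the similarity/dissimilarity matrix
normalizes each row by the sequence's self-score:

    s_ij = 1 - min(1, d_ij / d_ii)

so s = 0 means indistinguishable (every position retained) and s = 1 means
no retained structure at all.  The normalization by the *row* sequence's
d_ii makes the lower triangle the defined part; the upper triangle is zero
by convention.  d_ii is computed by running the full self-comparison —
internal repeats contribute by-path fragments, so d_ii can exceed the
sequence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Adld, AlignmentParams, build_adld
from .encoding import NumericalSequence

__all__ = [
    "SimilarityMatrix",
    "similarity_degree",
    "matching_matrix",
    "similarity_matrix",
    "compute_similarity",
]

logger = logging.getLogger(__name__)


class DegenerateSequenceError(ValueError):
    """A sequence whose self-comparison retains no points (d_ii = 0)."""


def similarity_degree(adld: Adld) -> int:
    """AP count retained in the diagram: fragment lengths + free points."""
    return adld.total_fragment_length + len(adld.free_points)


def matching_matrix(
    seqs: Sequence[NumericalSequence],
    params: AlignmentParams | None = None,
) -> np.ndarray:
    """Lower-triangular matrix of pairwise similarity degrees.

    Entry (i, j) for i >= j is SD of the pair; the upper triangle is 0 by
    convention.  Each pair is ordered longer-first internally, so the
    result does not depend on collection order beyond the row labelling.
    """
    if params is None:
        params = AlignmentParams()
    n = len(seqs)
    if n < 1:
        raise ValueError("need at least one sequence")
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1):
            d[i, j] = similarity_degree(build_adld(seqs[i], seqs[j], params))
    return d


def similarity_matrix(
    matching: np.ndarray,
    ids: Sequence[str] | None = None,
    *,
    symmetric_norm: bool = False,
) -> np.ndarray:
    """s_ij = 1 - min(1, d_ij / d_ii) on the lower triangle, 0 above.

    ``symmetric_norm=True`` switches the denominator to min(d_ii, d_jj),
    making the underlying quantity symmetric in the pair.  This is a
    variant of the canonical row-normalized definition and is off by
    default.
    """
    d = np.asarray(matching, dtype=float)
    n = d.shape[0]
    diag = np.diag(d)
    if np.any(diag <= 0):
        k = int(np.argmax(diag <= 0))
        name = ids[k] if ids is not None else f"index {k}"
        raise DegenerateSequenceError(
            f"sequence {name} has self-similarity degree 0; it is too short "
            f"or too repetition-free to normalize against"
        )
    s = np.zeros_like(d)
    for i in range(n):
        for j in range(i + 1):
            denom = min(d[i, i], d[j, j]) if symmetric_norm else d[i, i]
            s[i, j] = 1.0 - min(1.0, d[i, j] / denom)
    return s


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise distances over a sequence collection.

    ``matching`` and ``distances`` are lower-triangular (upper triangle 0);
    ``distances`` entries lie in [0, 1] with a zero diagonal.
    """

    ids: tuple[str, ...]
    matching: np.ndarray = field(repr=False)
    distances: np.ndarray = field(repr=False)
    params: AlignmentParams

    @property
    def n(self) -> int:
        return len(self.ids)

    def symmetrized(self) -> np.ndarray:
        """Full symmetric distance matrix (lower triangle mirrored up)."""
        s = self.distances
        return np.tril(s, -1) + np.tril(s, -1).T

    def to_frame(self, precision: int | None = 4) -> pd.DataFrame:
        """Distances as a labelled DataFrame, rounded for reporting."""
        vals = self.distances if precision is None else self.distances.round(precision)
        return pd.DataFrame(vals, index=list(self.ids), columns=list(self.ids))

    def write_csv(self, path: str | Path, precision: int = 4) -> None:
        self.to_frame(precision).to_csv(path, index_label="id")

    def write_phylip(self, path: str | Path, precision: int = 4) -> None:
        """Standard lower-triangular PHYLIP distance format (symmetrized)."""
        full = self.symmetrized()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{full[i, j]:.{precision}f}" for j in range(i))
                fh.write(f"{name.replace(' ', '_')[:50]:<12s} {row}".rstrip() + "\n")


def compute_similarity(
    seqs: Sequence[NumericalSequence],
    params: AlignmentParams | None = None,
) -> SimilarityMatrix:
    """Matching + similarity matrices for a collection, in one pass."""
    if params is None:
        params = AlignmentParams()
    ids = tuple(s.id for s in seqs)
    d = matching_matrix(seqs, params)
    s = similarity_matrix(d, ids)
    return SimilarityMatrix(ids=ids, matching=d, distances=s, params=params)
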