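"""Neighbor-joining trees from a similarity/dissimilarity matrix.

The distance matrix is lower-triangular by convention; it is symmetrized
(lower triangle mirrored up) before the standard Saitou-Nei agglomeration
runs.  Negative branch lengths, which NJ can produce on non-additive
matrices, are clamped to zero with a logged note.  This is a convenience
for downstream tree viewers; no claim is made that any particular
published tree is reproduced node-for-node.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .similarity import SimilarityMatrix

__all__ = ["neighbor_joining", "nj_tree", "write_newick", "read_distance_csv"]

logger = logging.getLogger(__name__)


def neighbor_joining(distances: np.ndarray, ids: list[str] | tuple[str, ...]) -> TreeNode:
    """Unrooted NJ tree from a symmetric distance matrix.

    Requires n >= 3 taxa, a symmetric nonnegative matrix with zero
    diagonal.  Negative branch lengths are clamped to 0 (logged).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")
    if len(ids) != n:
        raise ValueError("ids length must match matrix size")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distance matrix must be nonnegative")
    dm = DistanceMatrix(d, list(ids))
    tree = nj(dm, neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch length(s) to 0", clamped)
    return tree


def nj_tree(sm: SimilarityMatrix) -> TreeNode:
    """NJ tree directly from a :class:`SimilarityMatrix` (symmetrizes it)."""
    return neighbor_joining(sm.symmetrized(), list(sm.ids))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree as Newick with branch lengths.

    IDs containing Newick metacharacters or spaces come out quoted, per
    the format rules scikit-bio implements.
    """
    tree.write(str(path), format="newick")


def read_distance_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square labelled distance CSV (as written by ``write_csv``).

    Returns the symmetrized matrix and the ids; accepts either a full
    symmetric matrix or one with only the lower triangle populated.
    """
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    ids = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("distance CSV must be square with matching row/column ids")
    d = df.to_numpy(dtype=float)
    lower = np.tril(d, -1)
    if np.allclose(d, d.T, atol=1e-12):
        full = d.copy()
    else:
        full = lower + lower.T
    np.fill_diagonal(full, 0.0)
    return full, ids
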