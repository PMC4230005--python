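"""Principal-component scoring of amino acids.

The 20x9 property matrix is column-standardized, its 9x9 Pearson
correlation matrix eigendecomposed, and the leading components (smallest
set whose accumulated contribution rate reaches 85%) are combined into a
single real number per residue:

    TotalScore_i = sum_k  F_ik * CR_k,   k = 1..t

where ``F_ik = x*_i . a_k`` is the score of residue *i* on component *k*
and ``CR_k = lambda_k / sum(lambda)`` its contribution rate.  On the
packaged table this retains t = 4 components and yields 20 pairwise
distinct scores summing to zero (they are linear combinations of
zero-mean z-scores).

Standardization uses the sample standard deviation (divisor m-1 = 19);
eigenvectors are sign-normalized so the largest-magnitude component of
each is positive, which makes the decomposition fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

from .properties import (
    AMINO_ACIDS,
    PROPERTY_NAMES,
    AminoAcidPropertyTable,
    load_default_table,
    property_matrix,
)

__all__ = [
    "PcaScoring",
    "standardize",
    "correlation_matrix",
    "eigendecompose",
    "contribution_rates",
    "select_components",
    "total_scores",
    "compute_scoring",
    "score_table",
]

DEFAULT_ACR_THRESHOLD = 0.85


class DegenerateInputError(ValueError):
    """Raised when an input has no variance to standardize or decompose."""


def standardize(X: np.ndarray) -> np.ndarray:
    """Column z-scores of ``X`` with sample standard deviation (ddof=1).

    Raises :class:`DegenerateInputError` naming the offending property if a
    column is constant.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [PROPERTY_NAMES[j] if j < len(PROPERTY_NAMES) else str(j)
                 for j in bad]
        raise DegenerateInputError(
            f"constant column(s) cannot be standardized: {', '.join(names)}"
        )
    return (X - X.mean(axis=0)) / sd


def correlation_matrix(Xstar: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns of a standardized matrix."""
    Xstar = np.asarray(Xstar, dtype=float)
    R = np.corrcoef(Xstar, rowvar=False)
    # exact symmetry and unit diagonal, independent of accumulation order
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def eigendecompose(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a symmetric correlation matrix, sorted and sign-fixed.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvalues descending and
    ``eigenvectors[:, k]`` the unit eigenvector of ``eigenvalues[k]``,
    sign-normalized so its largest-|component| entry is positive.  Exact
    eigenvalue ties (never the case for the packaged table) are ordered by
    the sign pattern of the normalized vectors for determinism.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("eigendecompose requires a symmetric matrix")
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    # deterministic order within exact ties
    for start in range(len(lam) - 1):
        if lam[start] == lam[start + 1]:
            block = slice(start, start + 2)
            cols = sorted(range(2), key=lambda c: tuple(V[:, block][:, c]),
                          reverse=True)
            V[:, block] = V[:, block][:, cols]
    return lam, V


def contribution_rates(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Contribution rates CR_i = lambda_i / sum(lambda) and their cumsum."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be nonnegative")
    total = lam.sum()
    if total <= 0:
        raise DegenerateInputError("all eigenvalues are zero")
    cr = lam / total
    return cr, np.cumsum(cr)


def select_components(acr: np.ndarray, threshold: float = DEFAULT_ACR_THRESHOLD) -> int:
    """Smallest t with accumulated contribution rate ACR_t >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    acr = np.asarray(acr, dtype=float)
    hit = np.flatnonzero(acr >= threshold - 1e-12)
    if hit.size == 0:
        raise ValueError("no component reaches the threshold (ACR must end at 1)")
    return int(hit[0]) + 1


def total_scores(
    Xstar: np.ndarray,
    eigenvectors: np.ndarray,
    cr: np.ndarray,
    t: int,
    symbols: tuple[str, ...] = AMINO_ACIDS,
) -> dict[str, float]:
    """Per-residue total score from the first ``t`` retained components."""
    if t < 1:
        raise ValueError("must retain at least one component")
    F = np.asarray(Xstar, float) @ np.asarray(eigenvectors, float)[:, :t]
    scores = F @ np.asarray(cr, float)[:t]
    return dict(zip(symbols, scores.tolist()))


@dataclass(frozen=True)
class PcaScoring:
    """Full record of the scoring pipeline run on a property table."""

    standardized: np.ndarray = field(repr=False)
    correlation: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)
    contribution_rates: np.ndarray
    accumulated_rates: np.ndarray
    n_retained: int
    component_scores: np.ndarray = field(repr=False)
    total_scores: Mapping[str, float]


def compute_scoring(
    table: AminoAcidPropertyTable | None = None,
    threshold: float = DEFAULT_ACR_THRESHOLD,
) -> PcaScoring:
    """Run the whole chain table -> X* -> R -> eigen -> CR -> total scores."""
    if table is None:
        table = load_default_table()
    X = property_matrix(table)
    Xstar = standardize(X)
    R = correlation_matrix(Xstar)
    lam, V = eigendecompose(R)
    cr, acr = contribution_rates(lam)
    t = select_components(acr, threshold)
    F = Xstar @ V[:, :t]
    scores = total_scores(Xstar, V, cr, t, table.symbols)
    return PcaScoring(
        standardized=Xstar,
        correlation=R,
        eigenvalues=lam,
        eigenvectors=V,
        contribution_rates=cr,
        accumulated_rates=acr,
        n_retained=t,
        component_scores=F,
        total_scores=scores,
    )


@lru_cache(maxsize=1)
def _default_scores() -> tuple[tuple[str, float], ...]:
    scoring = compute_scoring()
    return tuple(scoring.total_scores.items())


def score_table() -> dict[str, float]:
    """The 20-symbol total-score table from the packaged data (cached)."""
    return dict(_default_scores())
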