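"""Alignment Scatter Diagrams and their diagonal-line reduction.

For an ordered pair of numerical sequences (longer first) a banded dot
plot is built: coordinate (i, j) is an alignment point (AP) when the two
position scores agree within the dissimilarity degree ``epsilon`` and the
coordinate lies within ``w`` diagonals of the main one.  The band width is

    w = xi                if N1 - N2 <= xi
        N1 - N2           otherwise

so a large length difference always fits inside the band.  The full point
set is the Alignment Scatter Diagram (ASD).  Reducing it to maximal
diagonal runs of at least ``delta`` consecutive APs — the similar
fragments (SFs) — plus the leftover main-diagonal APs — the free points
(FPs) — yields the Alignment Diagonal Line Diagram (ADLD).

Runs on the main diagonal (the artery track, offset 0) indicate aligned
identical stretches; runs on a parallel by-path track at offset o = j - i
indicate stretches aligned after an insertion or deletion of |o| residues.
Coordinates are 1-based everywhere in the public contract, matching the
usual dot-plot labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .encoding import NumericalSequence

__all__ = [
    "AlignmentParams",
    "AlignmentPointSet",
    "SimilarFragment",
    "Adld",
    "alignment_width",
    "alignment_points",
    "extract_fragments",
    "free_points",
    "build_adld",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Comparison parameters.

    epsilon : float
        Dissimilarity degree — maximum |score difference| still counted as
        a match.  0 means scores must be exactly equal, i.e. identical
        residues when both sides use the same score table.
    delta : int
        Minimum number of consecutive APs forming a similar fragment.
        With delta = 1 the ADLD degenerates to the full ASD.
    xi : int
        Alignment-width threshold (band half-width floor), in positions.
    """

    epsilon: float = 0.0
    delta: int = 3
    xi: int = 10

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if int(self.delta) != self.delta or self.delta < 1:
            raise ValueError("delta must be an integer >= 1")
        if int(self.xi) != self.xi or self.xi < 1:
            raise ValueError("xi must be an integer >= 1")


def alignment_width(n1: int, n2: int, xi: int) -> int:
    """Band half-width: xi, widened to n1 - n2 when the gap exceeds xi."""
    if n1 < n2:
        raise ValueError("alignment_width requires n1 >= n2 (order the pair)")
    diff = n1 - n2
    return xi if diff <= xi else diff


@dataclass(frozen=True)
class AlignmentPointSet:
    """Banded AP set of one ordered pair (the ASD).

    ``points`` holds 1-based (i, j): i indexes the longer sequence, j the
    shorter.  Padding positions j > n2 never match, so every point has
    j <= n2 in addition to the band constraint |i - j| <= width.
    """

    n1: int
    n2: int
    width: int
    points: frozenset[tuple[int, int]] = field(repr=False)

    def on_track(self, offset: int) -> list[int]:
        """Sorted i-coordinates of APs on track j - i = offset."""
        return sorted(i for i, j in self.points if j - i == offset)


def alignment_points(
    s1: NumericalSequence,
    s2: NumericalSequence,
    params: AlignmentParams,
) -> AlignmentPointSet:
    """Compute the banded AP set for an ordered pair (len(s1) >= len(s2)).

    Only the band of 2w+1 diagonals is ever materialized, never the full
    N1 x N1 matrix.
    """
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot compare empty sequences")
    if n1 < n2:
        raise ValueError("alignment_points requires len(s1) >= len(s2)")
    w = alignment_width(n1, n2, params.xi)
    t1, t2 = s1.scores, s2.scores
    pts: set[tuple[int, int]] = set()
    for o in range(-w, w + 1):
        # j = i + o with 1 <= i <= n1, 1 <= j <= n2
        i_lo = max(1, 1 - o)
        i_hi = min(n1, n2 - o)
        if i_hi < i_lo:
            continue
        ii = np.arange(i_lo, i_hi + 1)
        hit = np.abs(t1[ii - 1] - t2[ii + o - 1]) <= params.epsilon
        pts.update((int(i), int(i + o)) for i in ii[hit])
    return AlignmentPointSet(n1=n1, n2=n2, width=w, points=frozenset(pts))


@dataclass(frozen=True)
class SimilarFragment:
    """A maximal diagonal run of >= delta consecutive APs on one track."""

    track_offset: int
    start: tuple[int, int]
    end: tuple[int, int]

    @property
    def length(self) -> int:
        """Number of APs in the run."""
        return self.end[0] - self.start[0] + 1

    def covers(self, i: int) -> bool:
        """Whether row index i lies inside the run."""
        return self.start[0] <= i <= self.end[0]


def _track_order(width: int) -> Iterable[int]:
    yield 0
    for k in range(1, width + 1):
        yield k
    for k in range(1, width + 1):
        yield -k


def extract_fragments(aps: AlignmentPointSet, delta: int) -> list[SimilarFragment]:
    """Maximal runs of consecutive APs of length >= delta, per track.

    Tracks are scanned offset 0 first, then +1, +2, ..., then -1, -2, ...;
    within a track runs come left to right.  Consecutive means unit
    diagonal steps (i, j) -> (i+1, j+1), with no gap tolerance.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    frags: list[SimilarFragment] = []
    for o in _track_order(aps.width):
        run_start = prev = None
        for i in aps.on_track(o) + [None]:  # sentinel flushes last run
            if run_start is not None and (i is None or i != prev + 1):
                if prev - run_start + 1 >= delta:
                    frags.append(SimilarFragment(
                        track_offset=o,
                        start=(run_start, run_start + o),
                        end=(prev, prev + o),
                    ))
                run_start = None
            if i is not None:
                if run_start is None:
                    run_start = i
                prev = i
    return frags


def free_points(
    aps: AlignmentPointSet,
    fragments: Iterable[SimilarFragment],
) -> list[tuple[int, int]]:
    """Artery-track APs not covered by any artery fragment, left to right."""
    artery = [f for f in fragments if f.track_offset == 0]
    return [
        (i, i)
        for i in aps.on_track(0)
        if not any(f.covers(i) for f in artery)
    ]


@dataclass(frozen=True)
class Adld:
    """The reduced diagram of one sequence pair: fragments + free points."""

    params: AlignmentParams
    pair_ids: tuple[str, str]
    n1: int
    n2: int
    width: int
    fragments: tuple[SimilarFragment, ...]
    free_points: tuple[tuple[int, int], ...]

    @property
    def artery_fragments(self) -> tuple[SimilarFragment, ...]:
        return tuple(f for f in self.fragments if f.track_offset == 0)

    @property
    def bypath_fragments(self) -> tuple[SimilarFragment, ...]:
        return tuple(f for f in self.fragments if f.track_offset != 0)

    @property
    def total_fragment_length(self) -> int:
        return sum(f.length for f in self.fragments)


def build_adld(
    s1: NumericalSequence,
    s2: NumericalSequence,
    params: AlignmentParams | None = None,
) -> Adld:
    """Build the ADLD of a pair, ordering it longer-first automatically.

    Ties in length are broken lexicographically by id so the result is
    deterministic regardless of argument order.
    """
    if params is None:
        params = AlignmentParams()
    if len(s2) > len(s1) or (len(s2) == len(s1) and s2.id < s1.id):
        s1, s2 = s2, s1
    aps = alignment_points(s1, s2, params)
    frags = extract_fragments(aps, params.delta)
    fps = free_points(aps, frags)
    return Adld(
        params=params,
        pair_ids=(s1.id, s2.id),
        n1=aps.n1,
        n2=aps.n2,
        width=aps.width,
        fragments=tuple(frags),
        free_points=tuple(fps),
    )
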