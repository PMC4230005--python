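"""Shared fixtures: printed reference values and a brute-force oracle.

The oracle rebuilds the diagram from the definition — a full dense
N1 x N1 sweep with plain Python loops — independently of the banded
implementation, so the two can be compared on random pairs.
"""

from __future__ import annotations

import numpy as np
import pytest

from adld import (
    AlignmentParams,
    NumericalSequence,
    encode_sequence,
    load_default_table,
    score_table,
)
from adld.scoring import compute_scoring

# ---------------------------------------------------------------------------
# Published reference values (4 dp) used across the suite.

TABLE4_SCORES = {
    "A": -0.9324, "C": -0.5985, "D": -0.6709, "E": -0.2296, "F": 0.4298,
    "G": -1.1780, "H": 0.4476, "I": 0.1435, "K": 0.7868, "L": -0.1205,
    "M": 0.5735, "N": -0.0242, "P": -0.9822, "Q": 0.2848, "R": 1.1169,
    "S": -0.7077, "T": -0.4525, "V": -0.2643, "W": 1.4729, "Y": 0.9050,
}

TABLE2_EIGENVALUES = [3.2237, 1.9132, 1.4048, 1.1876, 0.4959, 0.4467,
                      0.1992, 0.1218, 0.0071]
TABLE2_CR = [0.3582, 0.2126, 0.1561, 0.1320, 0.0551, 0.0496, 0.0221,
             0.0135, 0.0008]
TABLE2_ACR = [0.3582, 0.5708, 0.7269, 0.8588, 0.9139, 0.9635, 0.9857,
              0.9992, 1.0000]

# Leading eigenvector loadings (mW, hI, pK1, pK2, pI, S, cN, F, vR).
A1_LOADINGS = [0.5036, -0.2454, -0.1634, -0.3101, 0.0702, -0.1665,
               -0.3872, -0.4377, 0.4349]

HU, GOR, OPO = "MTMHTTMTTL", "MTMYATMTTL", "MKVINISNTM"

S_HU = [0.5735, -0.4525, 0.5735, 0.4476, -0.4525, -0.4525, 0.5735,
        -0.4525, -0.4525, -0.1205]
S_GOR = [0.5735, -0.4525, 0.5735, 0.9050, -0.9324, -0.4525, 0.5735,
         -0.4525, -0.4525, -0.1205]
S_OPO = [0.5735, 0.7868, -0.2643, 0.1435, -0.0242, 0.1435, -0.7077,
         -0.0242, -0.4525, 0.5735]


# ---------------------------------------------------------------------------
# Fixtures.

@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def scoring():
    return compute_scoring()


@pytest.fixture(scope="session")
def scores():
    return score_table()


@pytest.fixture(scope="session")
def hu_gor_opo():
    return (
        encode_sequence("Hu", HU),
        encode_sequence("Gor", GOR),
        encode_sequence("Opo", OPO),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140753)


# ---------------------------------------------------------------------------
# Brute-force oracle.

def brute_force_diagram(
    s1: NumericalSequence,
    s2: NumericalSequence,
    params: AlignmentParams,
):
    """Dense-matrix reference: (points, fragments, free_points).

    Fragments are returned as (offset, start_i, end_i) tuples sorted the
    same way the implementation sorts (offset 0, +1.., then -1..; left to
    right within a track).  Assumes len(s1) >= len(s2).
    """
    t1, t2 = s1.scores, s2.scores
    n1, n2 = len(t1), len(t2)
    assert n1 >= n2, "oracle requires the ordered pair"
    diff = n1 - n2
    w = params.xi if diff <= params.xi else diff

    points = set()
    for i in range(1, n1 + 1):
        for j in range(1, n1 + 1):
            if abs(i - j) > w or j > n2:
                continue
            if abs(t1[i - 1] - t2[j - 1]) <= params.epsilon:
                points.add((i, j))

    offsets = [0] + list(range(1, w + 1)) + list(range(-1, -w - 1, -1))
    fragments = []
    for o in offsets:
        on_track = sorted(i for i, j in points if j - i == o)
        run = []
        for i in on_track + [None]:
            if run and (i is None or i != run[-1] + 1):
                if len(run) >= params.delta:
                    fragments.append((o, run[0], run[-1]))
                run = []
            if i is not None:
                run.append(i)

    covered = {
        i for o, a, b in fragments if o == 0 for i in range(a, b + 1)
    }
    fps = [(i, i) for i in sorted(i for i, j in points if i == j)
           if i not in covered]
    return points, fragments, fps


def as_tuples(adld):
    """Implementation fragments in the oracle's (offset, start_i, end_i) form."""
    return [(f.track_offset, f.start[0], f.end[0]) for f in adld.fragments]
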