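"""Diagram construction: band, runs, free points, and oracle equivalence."""

import numpy as np
import pytest

from adld import (
    AlignmentParams,
    alignment_points,
    alignment_width,
    build_adld,
    encode_sequence,
    extract_fragments,
    free_points,
)
from adld.synthetic import random_sequence

from conftest import as_tuples, brute_force_diagram


class TestAlignmentWidth:
    @pytest.mark.parametrize(
        "n1, n2, xi, expected",
        [
            (147, 147, 12, 12),   # equal lengths: band floor applies
            (125, 100, 10, 25),   # gap exceeds xi: widen to the gap
            (110, 100, 10, 10),   # boundary: gap == xi keeps xi
            (10, 1, 3, 9),
        ],
    )
    def test_both_branches(self, n1, n2, xi, expected):
        assert alignment_width(n1, n2, xi) == expected

    def test_requires_ordered_pair(self):
        with pytest.raises(ValueError, match="n1 >= n2"):
            alignment_width(5, 9, 10)


class TestAlignmentPoints:
    def test_worked_pair_artery_track(self, hu_gor_opo):
        hu, gor, _ = hu_gor_opo
        aps = alignment_points(hu, gor, AlignmentParams())
        # positions 4 (H vs Y) and 5 (T vs A) differ
        assert aps.on_track(0) == [1, 2, 3, 6, 7, 8, 9, 10]

    def test_identical_sequences_fill_the_diagonal(self, hu_gor_opo):
        hu, _, _ = hu_gor_opo
        aps = alignment_points(hu, hu, AlignmentParams())
        assert aps.on_track(0) == list(range(1, 11))

    def test_epsilon_above_score_spread_fills_the_band(self, hu_gor_opo):
        hu, gor, _ = hu_gor_opo
        aps = alignment_points(hu, gor, AlignmentParams(epsilon=3.0))
        n, w = aps.n1, aps.width
        expected = sum(
            1
            for i in range(1, n + 1)
            for j in range(max(1, i - w), min(n, i + w) + 1)
        )
        assert len(aps.points) == expected

    def test_band_and_bounds_respected(self, rng):
        s1 = encode_sequence("a", random_sequence(40, rng))
        s2 = encode_sequence("b", random_sequence(31, rng))
        params = AlignmentParams(epsilon=0.5, xi=4)
        aps = alignment_points(s1, s2, params)
        assert aps.width == 9  # 40 - 31 > 4
        for i, j in aps.points:
            assert abs(i - j) <= aps.width
            assert 1 <= i <= 40 and 1 <= j <= 31

    def test_monotone_in_epsilon(self, rng):
        s1 = encode_sequence("a", random_sequence(50, rng))
        s2 = encode_sequence("b", random_sequence(50, rng))
        previous = frozenset()
        for eps in (0.0, 0.1, 0.3, 0.6, 1.2, 3.0):
            pts = alignment_points(s1, s2, AlignmentParams(epsilon=eps)).points
            assert previous <= pts
            previous = pts


class TestExtractFragments:
    def test_worked_pair_two_artery_runs(self, hu_gor_opo):
        hu, gor, _ = hu_gor_opo
        aps = alignment_points(hu, gor, AlignmentParams())
        frags = extract_fragments(aps, delta=3)
        assert as_tuples_like(frags) == [(0, 1, 3), (0, 6, 10)]
        assert [f.length for f in frags] == [3, 5]

    def test_delta_one_degenerates_to_full_point_set(self, hu_gor_opo):
        hu, _, opo = hu_gor_opo
        aps = alignment_points(hu, opo, AlignmentParams())
        frags = extract_fragments(aps, delta=1)
        covered = {
            (i, i + f.track_offset)
            for f in frags
            for i in range(f.start[0], f.end[0] + 1)
        }
        assert covered == set(aps.points)

    def test_fragment_count_nonincreasing_in_delta(self, rng):
        s1 = encode_sequence("a", random_sequence(60, rng))
        s2 = encode_sequence("b", apply_every_fifth(s1.residues, rng))
        aps = alignment_points(s1, s2, AlignmentParams())
        counts = [len(extract_fragments(aps, d)) for d in range(1, 8)]
        assert counts == sorted(counts, reverse=True)


class TestFreePoints:
    def test_worked_pair_has_none(self, hu_gor_opo):
        hu, gor, _ = hu_gor_opo
        aps = alignment_points(hu, gor, AlignmentParams())
        frags = extract_fragments(aps, delta=3)
        assert free_points(aps, frags) == []

    def test_delta_one_leaves_none(self, rng):
        s1 = encode_sequence("a", random_sequence(30, rng))
        s2 = encode_sequence("b", random_sequence(30, rng))
        aps = alignment_points(s1, s2, AlignmentParams())
        assert free_points(aps, extract_fragments(aps, 1)) == []

    def test_free_point_count_nondecreasing_in_delta(self, rng):
        s1 = encode_sequence("a", random_sequence(60, rng))
        s2 = encode_sequence("b", apply_every_fifth(s1.residues, rng))
        aps = alignment_points(s1, s2, AlignmentParams())
        counts = [
            len(free_points(aps, extract_fragments(aps, d)))
            for d in range(1, 8)
        ]
        assert counts == sorted(counts)


class TestBuildAdld:
    def test_worked_pair_summary(self, hu_gor_opo):
        hu, gor, _ = hu_gor_opo
        adld = build_adld(hu, gor)
        assert [f.length for f in adld.fragments] == [3, 5]
        assert adld.bypath_fragments == ()
        assert adld.free_points == ()

    def test_self_comparison_has_full_artery_fragment(self, rng):
        s = encode_sequence("s", random_sequence(25, rng))
        adld = build_adld(s, s)
        artery = adld.artery_fragments
        assert artery[0].start == (1, 1) and artery[0].end == (25, 25)

    def test_orders_pair_longer_first(self, rng):
        s_long = encode_sequence("long", random_sequence(40, rng))
        s_short = encode_sequence("short", random_sequence(30, rng))
        a = build_adld(s_short, s_long)
        b = build_adld(s_long, s_short)
        assert a.pair_ids == b.pair_ids == ("long", "short")
        assert as_tuples(a) == as_tuples(b)

    def test_equal_length_tie_broken_lexicographically(self, hu_gor_opo):
        hu, gor, _ = hu_gor_opo
        assert build_adld(hu, gor).pair_ids == ("Gor", "Hu")
        assert build_adld(gor, hu).pair_ids == ("Gor", "Hu")

    def test_empty_sequence_rejected(self, hu_gor_opo):
        from adld.encoding import NumericalSequence

        hu = hu_gor_opo[0]
        empty = NumericalSequence(id="e", residues="", scores=np.array([]))
        with pytest.raises(ValueError):
            alignment_points(hu, empty, AlignmentParams())


class TestOracleEquivalence:
    """Banded implementation vs the dense brute-force reference."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_pairs_match_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n1 = int(rng.integers(5, 61))
        n2 = int(rng.integers(3, n1 + 1))
        eps = float(rng.choice([0.0, 0.05, 0.2, 0.5]))
        delta = int(rng.integers(1, 5))
        xi = int(rng.integers(1, 15))
        params = AlignmentParams(epsilon=eps, delta=delta, xi=xi)
        s1 = encode_sequence("a", random_sequence(n1, rng))
        s2 = encode_sequence("b", random_sequence(n2, rng))

        pts, frags, fps = brute_force_diagram(s1, s2, params)
        aps = alignment_points(s1, s2, params)
        assert set(aps.points) == pts
        adld = build_adld(s1, s2, params)
        assert as_tuples(adld) == frags
        assert list(adld.free_points) == fps


class TestTransposeSymmetry:
    @pytest.mark.parametrize("seed", [3, 14, 159])
    def test_swapping_equal_length_pair_mirrors_fragments(self, seed):
        rng = np.random.default_rng(seed)
        base = random_sequence(45, rng)
        other = apply_every_fifth(base, rng)
        s1 = encode_sequence("a", base)
        s2 = encode_sequence("b", other)
        params = AlignmentParams(xi=6)
        fwd = build_adld(s1, s2, params)
        # force the reverse orientation at the point-set level
        rev_aps = alignment_points(s2, s1, params)
        rev_frags = extract_fragments(rev_aps, params.delta)
        mirrored = sorted(
            (-f.track_offset, f.start[1], f.end[1]) for f in rev_frags
        )
        assert mirrored == sorted(as_tuples(fwd))
        rev_fps = free_points(rev_aps, rev_frags)
        assert len(rev_fps) == len(fwd.free_points)


def apply_every_fifth(residues: str, rng) -> str:
    """Substitute every 5th position with a different residue."""
    from adld.synthetic import apply_recipe, substitute_elsewhere

    out = residues
    for p in range(5, len(residues) + 1, 5):
        out = apply_recipe(out, [substitute_elsewhere(out, p, rng)])
    return out


def as_tuples_like(frags):
    return [(f.track_offset, f.start[0], f.end[0]) for f in frags]
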