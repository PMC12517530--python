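"""The aligners are checked against independent exhaustive-enumeration
oracles: plain recursion over every global alignment path, with no
dynamic programming or memoization."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from melodna import (
    DnaScoringScheme,
    MusicalElement,
    MusicScore,
    MusicScoringScheme,
    align_dna,
    align_music,
    delta_score,
)

SCHEME = MusicScoringScheme()
DNA = DnaScoringScheme()
NEG = float("-inf")


def music_column_score(a, b):
    if a.midi_note != b.midi_note:
        return SCHEME.mismatch
    return SCHEME.exact_match if a.duration == b.duration else SCHEME.near_match


def oracle_music(a, b):
    """Enumerate every global alignment of two element tuples."""

    def go(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            best = max(best, music_column_score(a[i], b[j]) + go(i + 1, j + 1))
        if i < len(a):
            best = max(best, SCHEME.gap + go(i + 1, j))
        if j < len(b):
            best = max(best, SCHEME.gap + go(i, j + 1))
        return best

    return go(0, 0)


def oracle_dna(a, b):
    """Enumerate every global alignment with affine gap costs."""

    def go(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            s = DNA.match if a[i] == b[j] else DNA.mismatch
            best = max(best, s + go(i + 1, j + 1, "m"))
        if i < len(a):
            cost = DNA.gap_extend if state == "x" else DNA.gap_open + DNA.gap_extend
            best = max(best, -cost + go(i + 1, j, "x"))
        if j < len(b):
            cost = DNA.gap_extend if state == "y" else DNA.gap_open + DNA.gap_extend
            best = max(best, -cost + go(i, j + 1, "y"))
        return best

    return go(0, 0, "m")


def el(note, dur=Fraction(1)):
    return MusicalElement(note, Fraction(dur))


small_elements = st.builds(
    el,
    note=st.sampled_from([60, 62, 64]),
    dur=st.sampled_from([Fraction(1), Fraction(1, 2)]),
)
small_scores = st.lists(small_elements, max_size=4).map(tuple)
small_dna = st.text(alphabet="ACGT", min_size=1, max_size=4)


class TestMusicAligner:
    def test_self_alignment_scores_five_per_element(self, ancestor):
        result = align_music(ancestor, ancestor)
        assert result.score == 5 * len(ancestor)
        assert set(result.column_states) == {"exact"}

    def test_near_match_scores_three(self):
        r = align_music([el(69, 1)], [el(69, "1/2")])
        assert r.score == 3
        assert r.column_states == ["near"]

    def test_single_element_vs_empty_is_one_gap(self):
        r = align_music([el(69)], [])
        assert r.score == -2
        assert r.column_states == ["gap"]

    def test_one_exact_one_mismatch(self):
        r = align_music([el(60), el(62)], [el(60), el(64)])
        assert r.score == 5 + 0

    @given(a=small_scores, b=small_scores)
    def test_matches_enumeration_oracle(self, a, b):
        assert align_music(a, b).score == oracle_music(a, b)

    def test_score_equals_sum_of_column_values(self, table):
        rng = np.random.default_rng(23)
        from conftest import random_score

        a = random_score(rng, 12, table)
        b = random_score(rng, 10, table)
        r = align_music(a, b)
        values = {
            "exact": SCHEME.exact_match,
            "near": SCHEME.near_match,
            "mismatch": SCHEME.mismatch,
            "gap": SCHEME.gap,
        }
        assert r.score == sum(values[s] for s in r.column_states)

    def test_reversal_symmetry(self, table):
        rng = np.random.default_rng(29)
        from conftest import random_score

        a = random_score(rng, 9, table).elements
        b = random_score(rng, 11, table).elements
        assert align_music(a, b).score == align_music(a[::-1], b[::-1]).score

    def test_substitution_costs_at_most_five(self, table):
        rng = np.random.default_rng(31)
        from conftest import random_score

        a = random_score(rng, 10, table)
        mutated = list(a.elements)
        mutated[4] = el(86 if mutated[4].midi_note != 86 else 60,
                        mutated[4].duration)
        drop = align_music(a, a).score - align_music(a, mutated).score
        assert 0 < drop <= 5


class TestDnaAligner:
    def test_self_alignment_scores_five_per_base(self):
        seq = "ACGTACGTGG"
        assert align_dna(seq, seq).score == 5 * len(seq)

    def test_single_mismatch(self):
        assert align_dna("ACGT", "ACGA").score == 11

    def test_symmetry(self):
        a, b = "ACGTACC", "AGGTAC"
        assert align_dna(a, b).score == align_dna(b, a).score

    def test_terminal_gaps_are_penalized(self):
        # one terminal gap: 4 matches (20) - open(10.5)
        assert align_dna("ACGTA", "ACGT").score == 20 - 10.5

    @given(a=small_dna, b=small_dna)
    def test_matches_enumeration_oracle(self, a, b):
        assert align_dna(a, b).score == oracle_dna(a, b)

    def test_affine_gaps_prefer_one_long_gap(self):
        # two separate 1-gaps cost 21; one 2-gap costs 11
        r = align_dna("AACCGGTT", "AACCGGTTAA")
        assert r.score == 8 * 5 - (10 + 2 * 0.5)

    def test_rejects_empty_or_invalid(self):
        with pytest.raises(ValueError):
            align_dna("", "ACGT")
        with pytest.raises(ValueError):
            align_dna("ACGN", "ACGT")


class TestDeltaScore:
    def test_identical_winner_gives_zero(self):
        assert delta_score("ACGTACGT", "ACGTACGT") == 0

    def test_single_substitution_costs_nine(self):
        assert delta_score("ACGT", "ACGA") == 9

    def test_nonnegative_for_equal_length_winners(self):
        rng = np.random.default_rng(37)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            a = "".join(rng.choice(bases, 12))
            b = "".join(rng.choice(bases, 12))
            assert delta_score(a, b) >= 0
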