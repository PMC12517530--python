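import numpy as np
import pytest

from melodna import (
    hamming_distance,
    mutate_music,
    mutate_nonsynonymous_dna,
    mutate_point_dna,
    mutate_synonymous_dna,
    reverse_translate,
    run_simulation,
    summarize_traces,
    translate,
)

from conftest import random_score


def element_diffs(a, b):
    return sum(x != y for x, y in zip(a.elements, b.elements))


@pytest.fixture(scope="module")
def dna(table):
    rng = np.random.default_rng(21)
    return reverse_translate(random_score(rng, 30, table), table, rng)


class TestHamming:
    @pytest.mark.parametrize(
        "x,y,expected",
        [("ACGT", "ACGT", 0), ("AAAA", "AAAT", 1), ("ACGT", "TGCA", 4)],
    )
    def test_counts_differing_positions(self, x, y, expected):
        assert hamming_distance(x, y) == expected

    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError, match="length mismatch"):
            hamming_distance("ACG", "ACGT")


class TestMutationOperators:
    def test_synonymous_is_single_silent_point_mutation(self, table, dna):
        for seed in range(30):
            out = mutate_synonymous_dna(dna, table, seed)
            assert hamming_distance(dna, out) == 1
            assert translate(out, table).elements == translate(dna, table).elements
            pos = next(i for i in range(len(dna)) if dna[i] != out[i])
            assert pos % 4 == 3  # wobble position under the default table

    def test_nonsynonymous_changes_exactly_one_element(self, table, dna):
        before = translate(dna, table)
        for seed in range(30):
            out = mutate_nonsynonymous_dna(dna, table, seed)
            after = translate(out, table)
            assert element_diffs(before, after) == 1
            codon_diffs = sum(
                dna[i : i + 4] != out[i : i + 4] for i in range(0, len(dna), 4)
            )
            assert codon_diffs == 1
            assert 1 <= hamming_distance(dna, out) <= 4

    def test_point_mutation_changes_one_base(self, dna):
        for seed in range(30):
            out = mutate_point_dna(dna, seed)
            assert hamming_distance(dna, out) == 1
            assert set(out) <= set("ACGT")

    def test_point_mutation_synonymous_fraction_is_one_quarter(self, table, dna):
        """Only wobble-position hits (1/4 of sites) are silent, and every
        alternative wobble base is a synonym — so P(synonymous) = 1/4."""
        rng = np.random.default_rng(3)
        before = translate(dna, table).elements
        silent = sum(
            translate(mutate_point_dna(dna, rng), table).elements == before
            for _ in range(10_000)
        )
        assert abs(silent / 10_000 - 0.25) < 0.02

    def test_music_mutation_substitutes_one_element(self, table):
        rng = np.random.default_rng(5)
        score = random_score(rng, 25, table)
        for seed in range(30):
            out = mutate_music(score, table, seed)
            assert len(out) == len(score)
            assert element_diffs(score, out) == 1


class TestSimulation:
    def test_event_tallies_match_regime(self, table, ancestor):
        for regime_id, expected in [
            (1, {}),
            (2, {"synonymous": 20}),
            (3, {"nonsynonymous_dna": 20}),
            (4, {"point": 20}),
            (5, {"nonsynonymous_music": 20}),
            (6, {"nonsynonymous_dna": 20, "nonsynonymous_music": 20}),
        ]:
            (trace,) = run_simulation(
                ancestor, regime_id, generations=20, replicates=1,
                seed=42, table=table,
            )
            totals = {k: v for k, v in trace.total_events().items() if v}
            assert totals == expected

    def test_lengths_are_conserved(self, table, ancestor):
        traces = run_simulation(ancestor, 6, 10, 3, seed=8, table=table)
        for t in traces:
            assert all(len(d) == len(t.ancestor_dna) for d in t.dna)
            assert all(len(s) == len(ancestor) for s in t.scores)
            assert t.hamming == [
                hamming_distance(t.ancestor_dna, d) for d in t.dna
            ]

    def test_replicates_are_reproducible(self, table, ancestor):
        a = run_simulation(ancestor, 3, 5, 2, seed=99, table=table)
        b = run_simulation(ancestor, 3, 5, 2, seed=99, table=table)
        assert [t.dna for t in a] == [t.dna for t in b]

    def test_rejects_unknown_regime(self, table, ancestor):
        with pytest.raises(ValueError, match="regime"):
            run_simulation(ancestor, 7, 5, 1, seed=0, table=table)

    def test_monotone_accumulation_under_nonsynonymous_regimes(
        self, table, ancestor
    ):
        """Mean distance to the ancestor creeps upward under regimes that
        fix one nonsynonymous change per generation."""
        for regime_id in (3, 5, 6):
            traces = run_simulation(
                ancestor, regime_id, 20, 10, seed=17, table=table
            )
            means = np.mean([t.hamming for t in traces], axis=0)
            assert means[-1] > means[0]
            # allow saturation noise: no large dips anywhere
            assert np.all(np.diff(means) > -5)


class TestSummarize:
    def test_single_trace_mean_is_itself(self, table, ancestor):
        (trace,) = run_simulation(ancestor, 1, 5, 1, seed=2, table=table)
        df = summarize_traces([trace])
        assert list(df["mean_hamming"]) == [float(h) for h in trace.hamming]
        assert list(df["generation"]) == [1, 2, 3, 4, 5]

    def test_constant_traces_mean_is_constant(self, table, ancestor):
        traces = run_simulation(ancestor, 1, 4, 3, seed=2, table=table)
        for t in traces:
            t.hamming = [10, 10, 10, 10]
        df = summarize_traces(traces)
        assert set(df["mean_hamming"]) == {10.0}

    def test_ragged_traces_rejected(self, table, ancestor):
        t1 = run_simulation(ancestor, 1, 4, 1, seed=2, table=table)[0]
        t2 = run_simulation(ancestor, 1, 5, 1, seed=2, table=table)[0]
        with pytest.raises(ValueError, match="ragged"):
            summarize_traces([t1, t2])
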