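"""Mutation-accumulation simulation over the bidirectional inheritance cycle.

A generation is one full genotype<->phenotype cycle: reverse translation
of the current score into DNA (with the regime's DNA-level action), then
translation back into music (with the regime's music-level action).
Six regimes are defined:

1. zero mutation          — plain cycle, no injected mutations
2. synonymous DNA         — one random codon replaced by a synonym
3. nonsynonymous DNA      — one random codon replaced by a foreign codon
4. random point DNA       — one random single-base substitution
5. nonsynonymous music    — one element replaced during translation
6. nonsynonymous DNA + music — actions of regimes 3 and 5 combined

Divergence is tracked as the Hamming distance between each generation's
DNA and the ancestral DNA (the regimes introduce no indels, so lengths
are conserved). Because reverse translation re-draws every codon, even
the zero-mutation regime sits at a large, flat Hamming plateau — and
synonymous DNA mutations (regime 2) are erased within one generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .code_table import BASES, CodeTable
from .codec import MusicScore, as_rng, reverse_translate, translate

__all__ = [
    "RegimeSpec",
    "REGIMES",
    "EvolutionTrace",
    "hamming_distance",
    "mutate_synonymous_dna",
    "mutate_nonsynonymous_dna",
    "mutate_point_dna",
    "mutate_music",
    "run_simulation",
    "summarize_traces",
]


@dataclass(frozen=True)
class RegimeSpec:
    """One mutational regime: its per-generation DNA and music actions."""

    regime_id: int
    name: str
    dna_action: str  # none | synonymous | nonsynonymous | random_point
    music_action: str  # none | nonsynonymous


REGIMES: dict[int, RegimeSpec] = {
    1: RegimeSpec(1, "zero mutation", "none", "none"),
    2: RegimeSpec(2, "synonymous DNA-level mutation", "synonymous", "none"),
    3: RegimeSpec(3, "nonsynonymous DNA-level mutation", "nonsynonymous", "none"),
    4: RegimeSpec(4, "random DNA-level mutation", "random_point", "none"),
    5: RegimeSpec(5, "nonsynonymous music-level mutation", "none", "nonsynonymous"),
    6: RegimeSpec(
        6,
        "nonsynonymous DNA-level mutation plus nonsynonymous music-level mutation",
        "nonsynonymous",
        "nonsynonymous",
    ),
}

_EVENT_KEYS = ("synonymous", "nonsynonymous_dna", "nonsynonymous_music", "point")


@dataclass
class EvolutionTrace:
    """Per-replicate record of one simulated lineage."""

    regime_id: int
    replicate: int
    ancestor_dna: str
    dna: list[str] = field(default_factory=list)
    scores: list[MusicScore] = field(default_factory=list)
    hamming: list[int] = field(default_factory=list)
    events: list[dict[str, int]] = field(default_factory=list)

    @property
    def generations(self) -> int:
        return len(self.dna)

    def total_events(self) -> dict[str, int]:
        totals = dict.fromkeys(_EVENT_KEYS, 0)
        for tally in self.events:
            for k, v in tally.items():
                totals[k] += v
        return totals


def hamming_distance(x: str, y: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(x) != len(y):
        raise ValueError(
            f"length mismatch: {len(x)} vs {len(y)} (Hamming distance "
            "requires equal lengths)"
        )
    return sum(a != b for a, b in zip(x, y))


def mutate_synonymous_dna(
    dna: str, table: CodeTable, seed=None
) -> str:
    """Replace one random codon by a different synonym (a single point mutation,
    since synonyms differ at exactly one nucleotide)."""
    rng = as_rng(seed)
    codons = [dna[i : i + 4] for i in range(0, len(dna), 4)]
    ci = int(rng.integers(len(codons)))
    current = codons[ci]
    options = [c for c in table.synonyms(table.decode(current)) if c != current]
    codons[ci] = options[rng.integers(len(options))]
    return "".join(codons)


def mutate_nonsynonymous_dna(
    dna: str, table: CodeTable, seed=None
) -> str:
    """Replace one random codon by a codon of a different element,
    uniform over the 252 foreign codons."""
    rng = as_rng(seed)
    codons = [dna[i : i + 4] for i in range(0, len(dna), 4)]
    ci = int(rng.integers(len(codons)))
    element = table.decode(codons[ci])
    foreign = sorted(c for c, e in table.forward.items() if e != element)
    codons[ci] = foreign[rng.integers(len(foreign))]
    return "".join(codons)


def mutate_point_dna(dna: str, seed=None) -> str:
    """Substitute one uniformly chosen position with one of the 3 other bases."""
    if not dna:
        raise ValueError("cannot point-mutate an empty sequence")
    rng = as_rng(seed)
    pos = int(rng.integers(len(dna)))
    alternatives = [b for b in BASES if b != dna[pos]]
    return dna[:pos] + alternatives[rng.integers(3)] + dna[pos + 1 :]


def mutate_music(
    score: MusicScore, table: CodeTable, seed=None
) -> MusicScore:
    """Replace one element by a different element, uniform over the other 63."""
    if len(score) == 0:
        raise ValueError("cannot mutate an empty score")
    rng = as_rng(seed)
    idx = int(rng.integers(len(score)))
    others = [e for e in table.elements if e != score.elements[idx]]
    replacement = others[rng.integers(len(others))]
    elements = list(score.elements)
    elements[idx] = replacement
    return MusicScore(tuple(elements), tempo=score.tempo, volume=score.volume)


def _apply_generation(
    score: MusicScore,
    regime: RegimeSpec,
    table: CodeTable,
    rng: np.random.Generator,
) -> tuple[str, MusicScore, dict[str, int]]:
    """One full cycle: reverse translation + DNA action, then translation
    + music action. Returns (dna, next score, event tally)."""
    events = dict.fromkeys(_EVENT_KEYS, 0)
    dna = reverse_translate(score, table, rng)
    if regime.dna_action == "synonymous":
        dna = mutate_synonymous_dna(dna, table, rng)
        events["synonymous"] += 1
    elif regime.dna_action == "nonsynonymous":
        dna = mutate_nonsynonymous_dna(dna, table, rng)
        events["nonsynonymous_dna"] += 1
    elif regime.dna_action == "random_point":
        dna = mutate_point_dna(dna, rng)
        events["point"] += 1
    elif regime.dna_action != "none":
        raise ValueError(f"unknown DNA action {regime.dna_action!r}")

    next_score = translate(dna, table, tempo=score.tempo, volume=score.volume)
    if regime.music_action == "nonsynonymous":
        next_score = mutate_music(next_score, table, rng)
        events["nonsynonymous_music"] += 1
    elif regime.music_action != "none":
        raise ValueError(f"unknown music action {regime.music_action!r}")
    return dna, next_score, events


def run_simulation(
    ancestor_score: MusicScore,
    regime: RegimeSpec | int,
    generations: int = 20,
    replicates: int = 10,
    seed=None,
    table: CodeTable | None = None,
) -> list[EvolutionTrace]:
    """Evolve the ancestor under one regime for `generations` cycles,
    independently `replicates` times.

    The ancestral DNA is one fresh reverse translation per replicate;
    per-generation Hamming distances are measured against it. Each
    replicate runs on its own child stream of the master seed, so
    traces are individually reproducible.
    """
    if isinstance(regime, int):
        if regime not in REGIMES:
            raise ValueError(f"unknown regime id {regime}; expected 1-6")
        regime = REGIMES[regime]
    if generations < 1 or replicates < 1:
        raise ValueError("generations and replicates must be >= 1")
    if table is None:
        from .code_table import build_default_code_table

        table = build_default_code_table()

    master = np.random.SeedSequence(
        seed if isinstance(seed, int) else None
    ) if not isinstance(seed, np.random.SeedSequence) else seed
    streams = master.spawn(replicates)

    traces = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        ancestor_dna = reverse_translate(ancestor_score, table, rng)
        trace = EvolutionTrace(regime.regime_id, rep, ancestor_dna)
        score = ancestor_score
        for _ in range(generations):
            dna, score, events = _apply_generation(score, regime, table, rng)
            trace.dna.append(dna)
            trace.scores.append(score)
            trace.hamming.append(hamming_distance(ancestor_dna, dna))
            trace.events.append(events)
        traces.append(trace)
    return traces


def summarize_traces(traces: list[EvolutionTrace]) -> pd.DataFrame:
    """Long-form per-generation mean Hamming distance over replicates.

    Returns a DataFrame with columns (regime, generation, mean_hamming),
    one row per regime x generation present in the traces.
    """
    if not traces:
        raise ValueError("no traces to summarize")
    lengths = {t.generations for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"ragged traces: generation counts {sorted(lengths)}")
    rows = [
        {
            "regime": t.regime_id,
            "replicate": t.replicate,
            "generation": g + 1,
            "hamming": h,
        }
        for t in traces
        for g, h in enumerate(t.hamming)
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["regime", "generation"], as_index=False)["hamming"]
        .mean()
        .rename(columns={"hamming": "mean_hamming"})
    )
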