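"""Rounds of evolution with selection through the noisy capture channel.

Each round, a chain of progressively more mutated variants is produced
by feeding the channel its own output (variant k+1 derives from variant
k), and a winner is chosen either by a purifying strategy — the
variant whose music alignment to the original ancestor scores highest,
an executable proxy for a listener panel that consistently prefers the
least mutated version — or uniformly at random (neutral drift). The
winner seeds the next round. Winners are reverse-translated afresh each
round, so DNA-level score changes include synonymous scatter, exactly
as the real system would, while music-level scores do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import MusicScoringScheme, align_music, delta_score
from .audio import NoiseModel, noisy_capture
from .code_table import CodeTable
from .codec import MusicScore, as_rng, reverse_translate

__all__ = [
    "RoundResult",
    "generate_variant_series",
    "select_purifying",
    "select_random",
    "run_rounds",
]


@dataclass
class RoundResult:
    """Outcome of one selection round.

    winner_index is 1-based over the variant chain; delta_dna_score is
    the drop of the winner's DNA alignment score relative to the
    progenitor's self-alignment; music_score_vs_ancestor aligns the
    winning score against the round-0 ancestor.
    """

    round_index: int
    variants: list[MusicScore]
    winner_index: int
    winner_dna: str
    delta_dna_score: float
    music_score_vs_ancestor: float


def generate_variant_series(
    progenitor: MusicScore,
    n: int,
    noise: NoiseModel,
    table: CodeTable,
    seed=None,
) -> list[MusicScore]:
    """Chain of n variants, each one more channel pass than the last."""
    if n < 1:
        raise ValueError("need at least one variant")
    rng = as_rng(seed)
    variants = []
    current = progenitor
    for _ in range(n):
        current = noisy_capture(current, noise, table, rng)
        variants.append(current)
    return variants


def select_purifying(
    variants: list[MusicScore],
    ancestor: MusicScore,
    scheme: MusicScoringScheme = MusicScoringScheme(),
) -> int:
    """1-based index of the variant most similar to the ancestor
    (ties broken toward the earliest, i.e. least-channel-passed, variant)."""
    if not variants:
        raise ValueError("no variants to select from")
    scores = [align_music(v, ancestor, scheme).score for v in variants]
    return int(np.argmax(scores)) + 1


def select_random(variants: list[MusicScore], seed=None) -> int:
    """Uniformly random 1-based index — the neutral-drift arm."""
    if not variants:
        raise ValueError("no variants to select from")
    rng = as_rng(seed)
    return int(rng.integers(len(variants))) + 1


def run_rounds(
    ancestor: MusicScore,
    rounds: int = 4,
    strategy: str = "purifying",
    noise: NoiseModel | None = None,
    table: CodeTable | None = None,
    seed=None,
    variants_per_round: int = 5,
    scheme: MusicScoringScheme = MusicScoringScheme(),
) -> list[RoundResult]:
    """Run rounds of variant generation + selection from the ancestor.

    The channel and the selection draw from separate child streams of
    the master seed, so the purifying and random arms see identical
    round-1 variant chains under the same seed (paired comparison).
    """
    if rounds < 1:
        raise ValueError("need at least one round")
    if strategy not in ("purifying", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if noise is None:
        from .audio import NOISY

        noise = NOISY
    if table is None:
        from .code_table import build_default_code_table

        table = build_default_code_table()

    master = np.random.SeedSequence(seed if isinstance(seed, int) else None)
    channel_rng = np.random.default_rng(master.spawn(1)[0])
    select_rng = np.random.default_rng(master.spawn(1)[0])

    results = []
    progenitor = ancestor
    progenitor_dna = reverse_translate(ancestor, table, channel_rng)
    for r in range(1, rounds + 1):
        variants = generate_variant_series(
            progenitor, variants_per_round, noise, table, channel_rng
        )
        if strategy == "purifying":
            winner_index = select_purifying(variants, ancestor, scheme)
        else:
            winner_index = select_random(variants, select_rng)
        winner = variants[winner_index - 1]
        winner_dna = reverse_translate(winner, table, channel_rng)
        results.append(
            RoundResult(
                round_index=r,
                variants=variants,
                winner_index=winner_index,
                winner_dna=winner_dna,
                delta_dna_score=delta_score(progenitor_dna, winner_dna),
                music_score_vs_ancestor=align_music(
                    winner, ancestor, scheme
                ).score,
            )
        )
        progenitor, progenitor_dna = winner, winner_dna
    return results
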