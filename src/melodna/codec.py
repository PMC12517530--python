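"""Bidirectional conversion between music scores and DNA.

Reverse translation (phenotype -> genotype) chooses, for every element,
one of its four synonymous codons uniformly at random — codon usage of
any preceding DNA generation is deliberately forgotten, which is what
makes synonymous DNA mutations heritable nowhere in this system.
Translation (genotype -> phenotype) decodes codon by codon with 100%
fidelity. Reverse-translated output is screened for homopolymeric
tracts (runs of one base of length >= 7, a synthesis/sequencing hazard)
and recoded synonymously until none remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .code_table import (
    BASES,
    DURATIONS,
    CodecError,
    CodeTable,
    MusicalElement,
)

__all__ = [
    "DEFAULT_TEMPO_BPM",
    "DEFAULT_VOLUME_DBFS",
    "HOMOPOLYMER_LIMIT",
    "MusicScore",
    "RecodingError",
    "as_rng",
    "validate_dna",
    "reverse_translate",
    "translate",
    "longest_homopolymer",
    "recode_homopolymers",
    "snap_to_code",
]

DEFAULT_TEMPO_BPM = 100.0
DEFAULT_VOLUME_DBFS = -20.0

#: Runs of a single base at or above this length trigger recoding.
HOMOPOLYMER_LIMIT = 7

_RECODE_MAX_PASSES = 100


class RecodingError(RuntimeError):
    """Homopolymer recoding failed to converge on some interval."""


@dataclass(frozen=True)
class MusicScore:
    """An ordered monophonic sequence of musical elements plus metadata.

    tempo is in beats per minute (> 0); volume in dBFS (<= 0, where
    0 dBFS is digital full scale).
    """

    elements: tuple[MusicalElement, ...]
    tempo: float = DEFAULT_TEMPO_BPM
    volume: float = DEFAULT_VOLUME_DBFS

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.tempo <= 0:
            raise ValueError(f"tempo must be positive, got {self.tempo}")
        if self.volume > 0:
            raise ValueError(f"volume must be <= 0 dBFS, got {self.volume}")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def total_beats(self) -> Fraction:
        return sum((e.duration for e in self.elements), Fraction(0))


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed (or None) into a numpy Generator; pass Generators through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def validate_dna(dna: str, require_frame: bool = True) -> None:
    """Raise CodecError on bad alphabet (1-based position) or broken frame."""
    for i, base in enumerate(dna):
        if base not in BASES:
            raise CodecError(f"invalid base {base!r} at position {i + 1}")
    if require_frame and len(dna) % 4 != 0:
        raise CodecError(
            f"sequence length {len(dna)} is not divisible by 4 "
            f"(frame error at offset {len(dna) - len(dna) % 4})"
        )


def longest_homopolymer(dna: str) -> int:
    """Length of the longest run of a single repeated base (0 if empty)."""
    best = run = 0
    prev = ""
    for base in dna:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def _homopolymer_runs(dna: str, limit: int) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of maximal runs with length >= limit."""
    runs = []
    start = 0
    for i in range(1, len(dna) + 1):
        if i == len(dna) or dna[i] != dna[start]:
            if i - start >= limit:
                runs.append((start, i))
            start = i
    return runs


def recode_homopolymers(
    dna: str,
    table: CodeTable,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Synonymously re-draw codons overlapping long homopolymer runs.

    Codons not overlapping an offending run are never touched, so the
    decoded element sequence is preserved exactly. Runs are processed
    left to right, re-checking after every pass; a bounded number of
    passes guards against pathological hand-built tables.
    """
    validate_dna(dna)
    rng = as_rng(seed)
    codons = [dna[i : i + 4] for i in range(0, len(dna), 4)]
    for _ in range(_RECODE_MAX_PASSES):
        seq = "".join(codons)
        runs = _homopolymer_runs(seq, HOMOPOLYMER_LIMIT)
        if not runs:
            return seq
        start, end = runs[0]
        for ci in range(start // 4, (end - 1) // 4 + 1):
            element = table.decode(codons[ci])
            options = table.synonyms(element)
            codons[ci] = options[rng.integers(len(options))]
            if longest_homopolymer("".join(codons)) < HOMOPOLYMER_LIMIT:
                break
    seq = "".join(codons)
    runs = _homopolymer_runs(seq, HOMOPOLYMER_LIMIT)
    raise RecodingError(
        f"could not recode homopolymer run(s) {runs} within "
        f"{_RECODE_MAX_PASSES} passes"
    )


def reverse_translate(
    score: MusicScore | Sequence[MusicalElement],
    table: CodeTable,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Convert a score to DNA, drawing each element's codon uniformly at random.

    Elements are processed left to right on the given generator, so runs
    are reproducible bit-for-bit. The result is homopolymer-screened.
    """
    rng = as_rng(seed)
    elements = score.elements if isinstance(score, MusicScore) else score
    codons = []
    for element in elements:
        options = table.synonyms(element)  # raises NotInCodeError if needed
        codons.append(options[rng.integers(len(options))])
    dna = "".join(codons)
    if longest_homopolymer(dna) >= HOMOPOLYMER_LIMIT:
        dna = recode_homopolymers(dna, table, rng)
    return dna


def translate(
    dna: str,
    table: CodeTable,
    tempo: float = DEFAULT_TEMPO_BPM,
    volume: float = DEFAULT_VOLUME_DBFS,
) -> MusicScore:
    """Decode DNA codon by codon into a music score (100% fidelity)."""
    validate_dna(dna)
    elements = tuple(
        table.decode(dna[i : i + 4]) for i in range(0, len(dna), 4)
    )
    return MusicScore(elements, tempo=tempo, volume=volume)


def snap_to_code(element: MusicalElement, table: CodeTable) -> MusicalElement:
    """Map an arbitrary MIDI element onto the nearest in-code element.

    The pitch class is preserved whenever some in-code note shares it,
    shifting to the octave at minimal distance (ties -> lower octave);
    otherwise the nearest in-code note by MIDI-number distance is used.
    Duration snaps independently to the nearest of the four code values
    (ties -> shorter). Total over the MIDI domain; in-code elements are
    fixed points.
    """
    same_class = [
        n for n in table.notes if n % 12 == element.midi_note % 12
    ]
    pool = same_class if same_class else list(table.notes)
    # min() is stable, and pools are ascending: ties resolve to the lower note
    note = min(pool, key=lambda n: abs(n - element.midi_note))
    # DURATIONS is descending (1, 1/2, 1/4, 1/8); reversed -> shorter wins ties
    duration = min(
        reversed(DURATIONS), key=lambda d: abs(d - element.duration)
    )
    return MusicalElement(note, duration)
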