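"""Artificial redundant genetic code relating 4-letter DNA codons to musical elements.

The code maps 256 four-letter codons onto 64 musical elements (16 MIDI
notes x 4 durations), with exact four-fold redundancy and no start/stop
codons ("grammarless"): every codon codes, and every element is encoded
by exactly four synonymous codons that differ at a single nucleotide
(the wobble position, position 4 in the default table).

The default table is deterministic: elements are indexed 0..63 in
note-major, duration-minor order; the index is base-4 encoded into codon
positions 1-3 (digit map 0->A, 1->C, 2->G, 3->T) and position 4 takes
all four bases in alphabet order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "BASES",
    "DURATIONS",
    "DEFAULT_NOTES",
    "MusicalElement",
    "CodeTable",
    "CodeTableError",
    "CodecError",
    "NotInCodeError",
    "build_default_code_table",
    "decode_codon",
    "synonyms",
]

BASES = "ACGT"

#: The four note durations of the code, in beats.
DURATIONS: tuple[Fraction, ...] = (
    Fraction(1),
    Fraction(1, 2),
    Fraction(1, 4),
    Fraction(1, 8),
)

#: Default 16-note subset: C-major diatonic pitches from middle C upward.
DEFAULT_NOTES: tuple[int, ...] = (
    60, 62, 64, 65, 67, 69, 71, 72, 74, 76, 77, 79, 81, 83, 84, 86,
)


class CodeTableError(ValueError):
    """A code table violates a structural invariant."""


class CodecError(ValueError):
    """A codon or DNA sequence is malformed (alphabet, length, frame)."""


class NotInCodeError(KeyError):
    """A musical element lies outside the code's 16-note x 4-duration domain."""


@dataclass(frozen=True, order=True)
class MusicalElement:
    """A (MIDI pitch, duration) pair — the unit of musical phenotype.

    Parameters
    ----------
    midi_note : int
        MIDI note number, 0-127. In-code elements are restricted to the
        table's 16-note subset.
    duration : Fraction
        Note length in beats; in-code durations are 1, 1/2, 1/4 or 1/8.
    """

    midi_note: int
    duration: Fraction

    def __post_init__(self) -> None:
        if not 0 <= self.midi_note <= 127:
            raise ValueError(f"MIDI note {self.midi_note} outside 0-127")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        object.__setattr__(self, "duration", Fraction(self.duration))


def _validate_codon(codon: str) -> None:
    if len(codon) != 4:
        raise CodecError(f"codon {codon!r} has length {len(codon)}, expected 4")
    for i, base in enumerate(codon):
        if base not in BASES:
            raise CodecError(
                f"codon {codon!r} has invalid base {base!r} at position {i + 1}"
            )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class CodeTable:
    """Bidirectional lookup between codons and musical elements.

    Attributes
    ----------
    forward : dict
        Total mapping from all 256 codons to their element.
    reverse : dict
        Mapping from each of the 64 elements to its ordered tuple of 4
        synonymous codons.
    notes : tuple of int
        The 16-note subset, in ascending order.
    """

    def __init__(self, forward: Mapping[str, MusicalElement]) -> None:
        self.forward: dict[str, MusicalElement] = dict(forward)
        rev: dict[MusicalElement, list[str]] = {}
        for codon, element in self.forward.items():
            rev.setdefault(element, []).append(codon)
        self.reverse: dict[MusicalElement, tuple[str, ...]] = {
            e: tuple(sorted(cs)) for e, cs in rev.items()
        }
        self.notes: tuple[int, ...] = tuple(
            sorted({e.midi_note for e in self.reverse})
        )
        self.validate()

    # -- structural invariants -------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise CodeTableError on failure."""
        if len(self.forward) != 256:
            raise CodeTableError(
                f"table has {len(self.forward)} codons, expected 256"
            )
        for codon in self.forward:
            _validate_codon(codon)
        if len(self.reverse) != 64:
            raise CodeTableError(
                f"table has {len(self.reverse)} elements, expected 64"
            )
        if len(self.notes) != 16:
            raise CodeTableError(
                f"table has {len(self.notes)} distinct notes, expected 16"
            )
        expected_elements = {
            MusicalElement(n, d) for n in self.notes for d in DURATIONS
        }
        if set(self.reverse) != expected_elements:
            raise CodeTableError(
                "elements are not the product of 16 notes x 4 durations"
            )
        for element, codons in self.reverse.items():
            if len(codons) != 4:
                raise CodeTableError(
                    f"element {element} has {len(codons)} synonyms, expected 4"
                )
            for a, b in itertools.combinations(codons, 2):
                if _hamming(a, b) != 1:
                    raise CodeTableError(
                        f"synonyms {a}/{b} of {element} differ at "
                        f"{_hamming(a, b)} positions, expected 1"
                    )

    # -- lookups ----------------------------------------------------------

    @property
    def elements(self) -> tuple[MusicalElement, ...]:
        """All 64 elements in note-major, duration-minor order."""
        return tuple(
            MusicalElement(n, d) for n in self.notes for d in DURATIONS
        )

    def decode(self, codon: str) -> MusicalElement:
        _validate_codon(codon)
        return self.forward[codon]

    def synonyms(self, element: MusicalElement) -> tuple[str, ...]:
        try:
            return self.reverse[element]
        except KeyError:
            raise NotInCodeError(
                f"element {element} is not in the code "
                f"(notes {self.notes}, durations {tuple(map(str, DURATIONS))})"
            ) from None

    def __contains__(self, element: MusicalElement) -> bool:
        return element in self.reverse

    # -- TSV round trip ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the table as a 256-row TSV (codon, note, num, den)."""
        lines = ["codon\tmidi_note\tduration_numerator\tduration_denominator"]
        for codon in sorted(self.forward):
            e = self.forward[codon]
            lines.append(
                f"{codon}\t{e.midi_note}\t{e.duration.numerator}"
                f"\t{e.duration.denominator}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodeTable":
        """Load a table from TSV; all invariants are re-validated."""
        lines = Path(path).read_text().splitlines()
        if not lines:
            raise CodeTableError(f"{path}: empty code-table file")
        header = lines[0].split("\t")
        if header[:4] != [
            "codon", "midi_note", "duration_numerator", "duration_denominator",
        ]:
            raise CodeTableError(f"{path}: unexpected header {lines[0]!r}")
        forward: dict[str, MusicalElement] = {}
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CodeTableError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            codon, note, num, den = fields
            if codon in forward:
                raise CodeTableError(f"{path}:{lineno}: duplicate codon {codon}")
            forward[codon] = MusicalElement(
                int(note), Fraction(int(num), int(den))
            )
        return cls(forward)


def build_default_code_table(
    notes: Iterable[int] = DEFAULT_NOTES,
) -> CodeTable:
    """Construct the deterministic default code table.

    Element index i (0..63, note-major, duration-minor) is base-4 encoded
    into codon positions 1-3; position 4 (wobble) takes all four bases,
    so synonyms of one element differ at exactly one nucleotide and any
    two codons of different elements differ in the first three positions.
    """
    notes = tuple(sorted(notes))
    if len(notes) != 16 or len(set(notes)) != 16:
        raise CodeTableError(f"need 16 distinct notes, got {notes}")
    forward: dict[str, MusicalElement] = {}
    for index, (note, duration) in enumerate(
        itertools.product(notes, DURATIONS)
    ):
        prefix = BASES[index // 16] + BASES[(index // 4) % 4] + BASES[index % 4]
        for wobble in BASES:
            forward[prefix + wobble] = MusicalElement(note, duration)
    return CodeTable(forward)


def decode_codon(table: CodeTable, codon: str) -> MusicalElement:
    """Map one codon to its unique musical element (Step 4 semantics)."""
    return table.decode(codon)


def synonyms(table: CodeTable, element: MusicalElement) -> tuple[str, ...]:
    """The ordered 4-codon synonym set of an in-code element."""
    return table.synonyms(element)
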