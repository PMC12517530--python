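"""Pairwise global alignment of music scores and DNA sequences.

Music scores are aligned with a bespoke Needleman-Wunsch variant whose
column scoring distinguishes exact matches (same note and duration, +5),
near matches (same note, different duration, +3), mismatches (different
note regardless of duration, 0) and gaps (-2 per column, linear).

DNA sequences are aligned needle-style: true global alignment with
affine gaps under EDNAFULL-equivalent scoring (match +5, mismatch -4,
gap open 10, gap extend 0.5; a gap of length L costs open + L*extend).
The raw alignment score stands in for a "bitscore" when tracking score
changes (delta) across rounds of selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .code_table import MusicalElement
from .codec import MusicScore, validate_dna

__all__ = [
    "MusicScoringScheme",
    "AlignmentResult",
    "DnaScoringScheme",
    "align_music",
    "align_dna",
    "delta_score",
    "format_alignment",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class MusicScoringScheme:
    exact_match: float = 5.0
    near_match: float = 3.0
    mismatch: float = 0.0
    gap: float = -2.0


@dataclass(frozen=True)
class DnaScoringScheme:
    """EMBOSS-needle defaults for nucleotide sequences."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class AlignmentResult:
    """A global alignment: total score plus the traceback path.

    aligned_pairs holds (left index, right index) per column, with None
    marking a gap on that side; column_states labels each column as
    exact / near / mismatch / gap.
    """

    score: float
    aligned_pairs: list[tuple[int | None, int | None]]
    column_states: list[str]


def _music_column(a: MusicalElement, b: MusicalElement,
                  scheme: MusicScoringScheme) -> tuple[float, str]:
    if a.midi_note != b.midi_note:
        return scheme.mismatch, "mismatch"
    if a.duration == b.duration:
        return scheme.exact_match, "exact"
    return scheme.near_match, "near"


def _elements(x: MusicScore | Sequence[MusicalElement]) -> tuple:
    return x.elements if isinstance(x, MusicScore) else tuple(x)


def align_music(
    a: MusicScore | Sequence[MusicalElement],
    b: MusicScore | Sequence[MusicalElement],
    scheme: MusicScoringScheme = MusicScoringScheme(),
) -> AlignmentResult:
    """Optimal global alignment of two element sequences (linear gaps).

    Ties in the traceback prefer diagonal, then a gap in the second
    sequence, then a gap in the first, so output is deterministic.
    """
    ea, eb = _elements(a), _elements(b)
    n, m = len(ea), len(eb)
    D = np.empty((n + 1, m + 1))
    D[0, :] = scheme.gap * np.arange(m + 1)
    D[:, 0] = scheme.gap * np.arange(n + 1)
    sub = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            sub[i, j] = _music_column(ea[i], eb[j], scheme)[0]
    for i in range(1, n + 1):
        row_prev = D[i - 1]
        for j in range(1, m + 1):
            D[i, j] = max(
                row_prev[j - 1] + sub[i - 1, j - 1],
                row_prev[j] + scheme.gap,
                D[i, j - 1] + scheme.gap,
            )
    pairs: list[tuple[int | None, int | None]] = []
    states: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and D[i, j] == D[i - 1, j - 1] + sub[i - 1, j - 1]
        ):
            pairs.append((i - 1, j - 1))
            states.append(_music_column(ea[i - 1], eb[j - 1], scheme)[1])
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + scheme.gap:
            pairs.append((i - 1, None))
            states.append("gap")
            i -= 1
        else:
            pairs.append((None, j - 1))
            states.append("gap")
            j -= 1
    pairs.reverse()
    states.reverse()
    return AlignmentResult(float(D[n, m]), pairs, states)


def align_dna(
    a: str,
    b: str,
    scheme: DnaScoringScheme = DnaScoringScheme(),
) -> AlignmentResult:
    """Needle-style global DNA alignment with affine gaps (Gotoh).

    Terminal gaps are penalized (true global alignment). Opening a gap
    costs gap_open + gap_extend for its first base; each further base
    costs gap_extend.
    """
    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        validate_dna(seq, require_frame=False)
    n, m = len(a), len(b)
    open_cost = scheme.gap_open + scheme.gap_extend
    ext = scheme.gap_extend

    M = np.full((n + 1, m + 1), NEG_INF)  # ends in a substitution column
    X = np.full((n + 1, m + 1), NEG_INF)  # ends in a gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG_INF)  # ends in a gap in a (b consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_cost - ext * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -open_cost - ext * (j - 1)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - ext,
                          Y[i - 1, j] - open_cost)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - ext,
                          X[i, j - 1] - open_cost)

    # deterministic traceback: prefer M, then X (gap in b), then Y
    finals = (M[n, m], X[n, m], Y[n, m])
    score = max(finals)
    state = "MXY"[int(np.argmax(finals))]
    pairs: list[tuple[int | None, int | None]] = []
    states: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            pairs.append((i - 1, j - 1))
            states.append("exact" if a[i - 1] == b[j - 1] else "mismatch")
            target = M[i, j] - s
            i, j = i - 1, j - 1
            options = (M[i, j], X[i, j], Y[i, j])
        elif state == "X":
            pairs.append((i - 1, None))
            states.append("gap")
            target = X[i, j]
            i -= 1
            options = (M[i, j] - open_cost, X[i, j] - ext, Y[i, j] - open_cost)
        else:
            pairs.append((None, j - 1))
            states.append("gap")
            target = Y[i, j]
            j -= 1
            options = (M[i, j] - open_cost, Y[i, j] - ext, X[i, j] - open_cost)
            state = "MYX"[int(np.argmax(np.isclose(options, target)))]
            if i == 0 and j == 0:
                break
            continue
        if i == 0 and j == 0:
            break
        state = "MXY"[int(np.argmax(np.isclose(options, target)))]
    pairs.reverse()
    states.reverse()
    return AlignmentResult(float(score), pairs, states)


def delta_score(
    progenitor: str,
    winner: str,
    scheme: DnaScoringScheme = DnaScoringScheme(),
) -> float:
    """Score drop of the winner relative to the progenitor's self-alignment.

    delta = score(progenitor, progenitor) - score(progenitor, winner);
    zero iff the winner is identical to the progenitor (self-score is
    the unique maximum under this scheme for a fixed progenitor).
    """
    self_score = scheme.match * len(progenitor)
    return self_score - align_dna(progenitor, winner, scheme).score


def format_alignment(
    result: AlignmentResult,
    a: Sequence,
    b: Sequence,
    symbol=lambda x: str(x),
) -> str:
    """Readable 3-row rendering (top sequence / column states / bottom)."""
    marks = {"exact": "|", "near": ":", "mismatch": ".", "gap": " "}
    top, mid, bot = [], [], []
    for (ia, ib), state in zip(result.aligned_pairs, result.column_states):
        sa = symbol(a[ia]) if ia is not None else "-"
        sb = symbol(b[ib]) if ib is not None else "-"
        w = max(len(sa), len(sb))
        top.append(sa.rjust(w))
        bot.append(sb.rjust(w))
        mid.append(marks[state].rjust(w))
    return "\n".join(" ".join(row) for row in (top, mid, bot))
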