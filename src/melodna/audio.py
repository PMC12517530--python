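"""Audio side of the cycle: MIDI and WAV rendering, and the capture channel.

Scores render to standard MIDI (format 0, one monophonic track) and to
16-bit PCM WAV, each element synthesized as a square wave at its
equal-temperament frequency f = 2**((d-69)/12) * 440 Hz for
duration_beats * 60/tempo seconds, with linear amplitude 10**(dBFS/20).

The loudspeaker -> room -> microphone -> transcription loop is modeled
as a stochastic edit channel acting at the element level, where the
mutations it produces are defined and scored: per element, substitution
or deletion; per position, insertion. Substitutions may scatter outside
the code's octave range, in which case the result is snapped back onto
the nearest in-code element — so channel output is always fully
in-code.
"""

from __future__ import annotations

import io
import struct
import wave
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .code_table import CodeTable, MusicalElement
from .codec import (
    DEFAULT_VOLUME_DBFS,
    MusicScore,
    as_rng,
    snap_to_code,
)

__all__ = [
    "NoiseModel",
    "NOISY",
    "QUIET",
    "note_to_frequency",
    "score_to_midi",
    "midi_to_score",
    "render_wav",
    "noisy_capture",
]

DEFAULT_TICKS_PER_BEAT = 480
DEFAULT_SAMPLE_RATE = 44100
_NOTE_VELOCITY = 64


@dataclass(frozen=True)
class NoiseModel:
    """Element-level stochastic edit channel standing in for audio capture.

    p_sub / p_del apply per element (p_sub + p_del <= 1); p_ins applies
    per position (an element may be inserted after each original
    position); octave_scatter is the probability that a substitution
    lands an octave outside the code's range, exercising octave
    snapping.
    """

    p_sub: float = 0.0
    p_del: float = 0.0
    p_ins: float = 0.0
    octave_scatter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_del", "p_ins", "octave_scatter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_sub + self.p_del > 1.0:
            raise ValueError("p_sub + p_del must be <= 1")


#: High-noise room: frequent substitutions plus occasional indels.
NOISY = NoiseModel(p_sub=0.05, p_del=0.02, p_ins=0.02, octave_scatter=0.1)
#: Quiet room: a perfect channel.
QUIET = NoiseModel()


def note_to_frequency(d: int | float) -> float:
    """Equal-temperament frequency of MIDI note d (A4 = note 69 = 440 Hz)."""
    if not 0 <= d <= 127:
        raise ValueError(f"MIDI note {d} outside 0-127")
    return 2.0 ** ((d - 69) / 12.0) * 440.0


# -- MIDI (standard MIDI file, format 0) --------------------------------


def _varlen(value: int) -> bytes:
    """MIDI variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def score_to_midi(
    score: MusicScore, ticks_per_beat: int = DEFAULT_TICKS_PER_BEAT
) -> bytes:
    """Serialize a score as a format-0 single-track MIDI byte stream.

    One note_on/note_off pair per element (channel 0), a set_tempo meta
    event carrying the score's bpm, and tick durations of
    duration_beats * ticks_per_beat. Re-parsing with midi_to_score
    yields the identical element sequence and tempo.
    """
    track = bytearray()
    usec_per_beat = round(60_000_000 / score.tempo)
    track += _varlen(0) + bytes([0xFF, 0x51, 0x03]) + usec_per_beat.to_bytes(3, "big")
    velocity = max(1, round(127 * 10 ** (score.volume / 20.0)))
    for element in score.elements:
        ticks = element.duration * ticks_per_beat
        if ticks.denominator != 1:
            raise ValueError(
                f"duration {element.duration} not representable at "
                f"{ticks_per_beat} ticks per beat"
            )
        track += _varlen(0) + bytes([0x90, element.midi_note, velocity])
        track += _varlen(int(ticks)) + bytes([0x80, element.midi_note, 0])
    track += _varlen(0) + bytes([0xFF, 0x2F, 0x00])  # end of track
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_beat)
    return header + b"MTrk" + struct.pack(">I", len(track)) + bytes(track)


def midi_to_score(data: bytes) -> MusicScore:
    """Parse a monophonic format-0/1 MIDI byte stream back into a score.

    Note durations are taken as note_on -> matching note_off tick spans
    divided by ticks_per_beat; the first set_tempo event defines the
    bpm (default 120 if absent, per the MIDI standard). Running status
    is handled.
    """
    if data[:4] != b"MThd":
        raise ValueError("not a standard MIDI file (missing MThd)")
    hlen, fmt, ntracks, tpb = struct.unpack(">IHHH", data[4:14])
    if tpb & 0x8000:
        raise ValueError("SMPTE time division is not supported")
    pos = 8 + hlen
    tempo_bpm: float | None = None
    elements: list[MusicalElement] = []
    pending: tuple[int, int] | None = None  # (note, start_tick)

    for _ in range(ntracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("malformed MIDI: expected MTrk chunk")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        p, end = pos + 8, pos + 8 + tlen
        tick = 0
        status = 0

        def read_varlen(p: int) -> tuple[int, int]:
            value = 0
            while True:
                byte = data[p]
                p += 1
                value = (value << 7) | (byte & 0x7F)
                if not byte & 0x80:
                    return value, p

        while p < end:
            delta, p = read_varlen(p)
            tick += delta
            byte = data[p]
            if byte & 0x80:
                status = byte
                p += 1
            if status == 0xFF:  # meta
                meta_type = data[p]
                length, p2 = read_varlen(p + 1)
                payload = data[p2 : p2 + length]
                if meta_type == 0x51 and tempo_bpm is None:
                    tempo_bpm = 60_000_000 / int.from_bytes(payload, "big")
                p = p2 + length
            elif status in (0xF0, 0xF7):  # sysex
                length, p2 = read_varlen(p)
                p = p2 + length
            else:
                kind = status & 0xF0
                nargs = 1 if kind in (0xC0, 0xD0) else 2
                args = data[p : p + nargs]
                p += nargs
                if kind == 0x90 and args[1] > 0:
                    if pending is not None:
                        raise ValueError(
                            "polyphonic MIDI is not supported (overlapping notes)"
                        )
                    pending = (args[0], tick)
                elif kind == 0x80 or (kind == 0x90 and args[1] == 0):
                    if pending is None or pending[0] != args[0]:
                        raise ValueError(
                            f"unmatched note_off for note {args[0]}"
                        )
                    note, start = pending
                    elements.append(
                        MusicalElement(note, Fraction(tick - start, tpb))
                    )
                    pending = None
        pos = end

    if pending is not None:
        raise ValueError(f"note {pending[0]} never released")
    return MusicScore(
        tuple(elements),
        tempo=tempo_bpm if tempo_bpm is not None else 120.0,
        volume=DEFAULT_VOLUME_DBFS,
    )


# -- WAV ----------------------------------------------------------------


def render_wav(
    score: MusicScore, sample_rate: int = DEFAULT_SAMPLE_RATE
) -> bytes:
    """Render a score as mono 16-bit PCM WAV of square-wave tones."""
    amplitude = 10.0 ** (score.volume / 20.0)
    chunks = []
    for element in score.elements:
        seconds = float(element.duration) * 60.0 / score.tempo
        n = round(seconds * sample_rate)
        t = np.arange(n) / sample_rate
        f = note_to_frequency(element.midi_note)
        chunks.append(amplitude * np.sign(np.sin(2 * np.pi * f * t)))
    samples = np.concatenate(chunks) if chunks else np.zeros(0)
    pcm = np.clip(samples * 32767.0, -32768, 32767).astype("<i2")
    buf = io.BytesIO()
    with wave.open(buf, "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(sample_rate)
        w.writeframes(pcm.tobytes())
    return buf.getvalue()


# -- noisy capture channel ----------------------------------------------


def noisy_capture(
    score: MusicScore,
    noise: NoiseModel,
    table: CodeTable,
    seed=None,
) -> MusicScore:
    """Pass a score through the stochastic capture channel.

    Per element, in left-to-right order: delete with p_del, substitute
    with p_sub (a uniformly random different in-code element, scattered
    one octave out of range with probability octave_scatter and snapped
    back), otherwise copy; then insert a random in-code element after
    the position with p_ins. A zero-noise model is the identity.
    """
    rng = as_rng(seed)
    elements = table.elements
    out: list[MusicalElement] = []
    for element in score.elements:
        u = rng.random()
        if u < noise.p_del:
            pass
        elif u < noise.p_del + noise.p_sub:
            others = [e for e in elements if e != element]
            new = others[rng.integers(len(others))]
            if rng.random() < noise.octave_scatter:
                shift = 12 if rng.random() < 0.5 else -12
                shifted = new.midi_note + shift
                if 0 <= shifted <= 127:
                    new = MusicalElement(shifted, new.duration)
            out.append(snap_to_code(new, table))
        else:
            out.append(element)
        if rng.random() < noise.p_ins:
            out.append(elements[rng.integers(len(elements))])
    return MusicScore(tuple(out), tempo=score.tempo, volume=score.volume)
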