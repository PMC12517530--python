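# Methods

## The inheritance model

The system couples a genotype (a DNA string over {A,C,G,T}, length
divisible by 4) to a phenotype (an ordered monophonic sequence of
musical elements, each a MIDI pitch plus a duration) through an
artificial genetic code. One *generation* is a full cycle: reverse
translation (music → DNA) followed by translation (DNA → music).
Translation is deterministic and total — every codon codes, there are
no start/stop codons. Reverse translation chooses each element's codon
uniformly at random among its four synonyms, independently of any
earlier DNA. That single design choice produces the system's two
defining behaviours:

1. **Synonymous mutations are not heritable.** A synonymous DNA change
   survives exactly until the next reverse translation, which re-draws
   the codon from the code table. Distance to the ancestor therefore
   sits on a flat plateau whose height is pure codon scatter: under the
   default table synonyms differ only at the wobble position, so two
   independent encodings of the same score disagree at each codon with
   probability 3/4, giving an expected Hamming distance of 0.75 × L
   elements (46.5 for the 62-element ancestor).
2. **Bidirectional transmission doubles nonsynonymous load.** With one
   nonsynonymous event injected per generation on the DNA side and one
   on the music side, a 20-generation lineage fixes 40 events instead
   of the 20 of either unidirectional regime.

## The code table

64 elements (16 notes × durations 1, 1/2, 1/4, 1/8 beat) map to 256
codons. The default table indexes elements 0..63 in note-major,
duration-minor order, base-4-encodes the index into codon positions
1–3 (0→A, 1→C, 2→G, 3→T), and lets position 4 take all four bases.
Consequences used throughout: synonyms of one element differ at
exactly one position; codons of different elements always differ
within the first three positions; a uniformly random point mutation is
synonymous with probability exactly 1/4 (it must hit the wobble
position, and every alternative wobble base is a synonym). The
note subset is the C-major diatonic scale from middle C
(60, 62, 64, 65, 67, 69, 71, 72, 74, 76, 77, 79, 81, 83, 84, 86),
chosen to cover the packaged melody plus the octave headroom that
snapping needs; both the notes and the full codon assignment are
swappable via a 256-row TSV. Apart from homopolymer avoidance the
assignment is arbitrary — this code is not optimized for error
tolerance the way the natural code is.

Reverse-translated DNA is screened for homopolymeric tracts (runs of
one base of length ≥ 7, which are hostile to synthesis and Sanger
sequencing). Offending runs are repaired left to right by re-drawing
the synonymous codon of each codon overlapping the run, re-checking
after each draw, with a 100-pass cap (a safeguard for pathological
user-supplied tables; the default table always converges, since
prefixes contribute at most three identical bases and a non-matching
wobble base severs any run).

## Mutational regimes

Per generation, regimes act once each at most: (1) nothing; (2) one
random codon replaced by a different synonym — a single silent point
mutation; (3) one random codon replaced by one of the 252 codons of
other elements, uniformly; (4) one uniformly random single-base
substitution; (5) one element replaced by one of the other 63,
uniformly, during translation; (6) actions 3 and 5 together. The
regime-2/3 exception is applied after the full random re-assignment,
on one randomly chosen codon slot. Nonsynonymous choices are uniform
(maximum-entropy default; nothing favours near over far elements).
Divergence is raw Hamming distance to the ancestral DNA, uncorrected
for saturation; regimes introduce no indels, so lengths never change.
The ancestral DNA is itself one fresh reverse translation per
replicate, so generation-1 distances already include the synonymous
plateau.

Replicate comparisons use Welch's two-tailed t-test on the
generation-20 distances (no equal-variance assumption). With 10
replicates per regime the regime-3 vs regime-6 contrast rejects at
α = 0.01 by many orders of magnitude, while regimes 1 vs 2 and 3 vs 5
are identically distributed by construction and should not reject —
any single seeded run of such a comparison still carries the nominal
type-I risk, which is irreducible.

## Aligners

Music scores are aligned with global Needleman–Wunsch under a
column scoring of exact match (same note and duration) +5, near match
(same note, different duration) +3, mismatch (different note,
duration ignored) 0, and a linear gap penalty of −2 per column. A
score's self-alignment is therefore 5 × its element count — 310 for
the 62-element ancestor — and that value is the ceiling against which
round winners are compared. DNA is aligned needle-style: true global
alignment (terminal gaps penalized) with match +5, mismatch −4 and
affine gaps, where a gap of length L costs 10 + 0.5 L. The raw
alignment score plays the role of a bitscore; Δscore subtracts the
progenitor-vs-winner score from the progenitor's self-score, so it is
0 exactly when the winner's DNA is identical and 9 per substituted
base otherwise. Traceback ties prefer diagonal, then a gap in the
second input, then the first; only the optimal score is unique, and
only it is asserted in tests. Both aligners are verified against
exhaustive-enumeration oracles on small inputs.

## Audio and the capture channel

Scores serialize to format-0 MIDI (one note_on/note_off pair per
element, 480 ticks per beat, a set_tempo meta event; defaults 100 bpm
and −20 dBFS) and render to mono 16-bit PCM WAV at 44 100 Hz as square
waves at f = 2^((d−69)/12) × 440 Hz, with linear amplitude
10^(dBFS/20).

The physical loudspeaker → room → recording → transcription loop is
replaced by a stochastic edit channel acting at the element level —
the level at which the mutations it produces are defined and scored.
Per element: deletion with probability `p_del`, substitution with
`p_sub` (uniform over the other 63 elements); per position, insertion
of a uniform random element with `p_ins`. With probability
`octave_scatter` a substitution is shifted one octave before snapping,
exercising the same nearest-octave/nearest-duration repair the real
pipeline needs for out-of-code notes. The "noisy" preset is
p_sub = 0.05, p_del = 0.02, p_ins = 0.02, octave_scatter = 0.1 —
chosen once as a plausible high-noise room in which a 62-element
melody picks up a handful of mutations per capture; the real room's
per-round mutation counts are unquantified, so no numerical
correspondence is claimed, only the qualitative contrast the selection
experiment needs. The "quiet" preset is the identity channel. No
acoustic simulation, onset detection or pitch tracking is attempted.

## Selection rounds

Each round chains five variants through the channel (variant k + 1 is
one more capture of variant k), so later variants carry more
mutations. The purifying strategy picks the variant whose music
alignment against the round-0 ancestor scores highest (ties to the
earliest variant) — the executable proxy for a listener panel that
consistently prefers the least mutated version; the neutral strategy
picks uniformly at random. The winner seeds the next round and is
reverse-translated afresh, as the physical pipeline would, so DNA
Δscores include synonymous wobble scatter (a multiple of 9 even for an
identical winner) while music scores do not. Channel and selection
randomness come from separate child streams of the master seed, so
the two arms see identical round-1 variants under the same seed and
can be compared pairwise. Over 20 paired runs of 4 rounds × 5
variants, round-4 similarity to the ancestor under purifying selection
stochastically dominates the neutral arm (one-sided Wilcoxon
signed-rank).

## The packaged ancestor

The fixture is a 62-element monophonic C-major rendering of the Ode to
Joy theme (four phrases of 15 + 15 + 17 + 15 elements), entirely
inside the default code. Its rhythm is adapted to the four available
durations: quarter notes are 1 beat, the bridge's eighth-note pairs
and phrase-end pickups 1/2 beat, and phrase-final long notes are held
at 1 beat (the code has no duration above 1); the bridge's low G is
raised an octave into the code's range. The melody totals 58.5 beats
(35.1 s at 100 bpm). Only its element count and self-alignment score
(62 and 310) matter to the analyses; any monophonic in-code MIDI file
can replace it via `--ancestor path.mid`.

## Numerical and design notes

- All stochastic operations take an explicit seed or numpy Generator
  and consume randomness left to right, so runs are bit-reproducible;
  simulations spawn one child stream per replicate from the master
  seed.
- Snapping ties prefer the lower octave / nearer note downward and the
  shorter duration; note and duration snap independently.
- Sequence coordinates are 0-based half-open internally; user-facing
  error messages are 1-based.
- Problem sizes used by the shipped analyses — 20 generations × 10
  replicates per regime, 20 paired selection runs of 4 rounds × 5
  variants, and a 62-element ancestor — complete in well under a
  minute on one CPU; all are parameters, not limits.

## What the synthetic setup does and does not show

The generator-side components (the default code table, the fixture
melody, the noise presets) emulate the *structure* of the physical
system, not its measured error process: passing tests demonstrate the
masking of synonymous mutations, the doubled bidirectional load, and
the purifying-selection signal as properties of the model, but say
nothing about real room acoustics, synthesis chemistry, or human
listener behaviour. Polyphony, rests, velocity dynamics, durations
above one beat, and notes outside the 16-note subset are out of scope
by construction.
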