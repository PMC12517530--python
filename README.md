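# melodna

A toy inheritance system with **bidirectional** information transfer
between genotype and phenotype. Genotype is a DNA string over an
artificial redundant genetic code; phenotype is a monophonic musical
score. *Translation* decodes DNA into music with perfect fidelity;
*reverse translation* re-encodes music into DNA by drawing each
element's codon afresh from the code table, with no memory of the
previous generation's codon usage. Because phenotype-level changes are
written back into the genome, the system is Lamarckian — and it lets
you ask, by simulation, what bidirectional transmission does to
mutational load.

The package is for anyone studying molecular-evolution toy models, DNA
digital data storage, or artificial genetic codes. It implements:

- **The code** (`code_table`): 256 four-letter codons for 64 musical
  elements (16 MIDI notes × durations 1, ½, ¼, ⅛ beat), exact
  four-fold redundancy, no start/stop codons, and every synonym pair at
  nucleotide Hamming distance 1 (a wobble position, like position 3 of
  the natural code).
- **The codec** (`codec`): `reverse_translate` (with homopolymer
  screening — runs ≥ 7 of one base are synonymously recoded, a DNA
  synthesis constraint) and `translate`, plus `snap_to_code`, which
  maps arbitrary MIDI elements onto the nearest in-code element
  (octave-preserving pitch snap, nearest duration).
- **Mutation regimes** (`evolution`): six per-generation regimes —
  none, synonymous DNA, nonsynonymous DNA, random point, nonsynonymous
  music, and nonsynonymous DNA + music — tracked as Hamming distance
  HD(x, y) = Σₙ [xₙ ≠ yₙ] to the ancestral DNA.
- **Aligners** (`alignment`): a bespoke Needleman–Wunsch for scores
  (exact match +5, near match +3 for same note/different duration,
  mismatch 0, gap −2) and a needle-style global DNA aligner (match +5,
  mismatch −4, affine gaps open 10 / extend 0.5), with Δscore
  bookkeeping against a progenitor's self-alignment.
- **Audio** (`audio`): square-wave rendering at
  f = 2^((d−69)/12) × 440 Hz to 16-bit PCM WAV, MIDI format-0
  read/write, and a parameterized noisy-capture channel (per-element
  substitution/deletion, per-position insertion, octave scatter) that
  stands in for the loudspeaker → room → microphone loop.
- **Selection rounds** (`selection`): chains of increasingly mutated
  variants through the channel, with a purifying strategy (pick the
  variant most similar to the ancestor — a proxy for a listener panel)
  versus neutral random choice.

## Worked example

```python
import numpy as np
from melodna import (build_default_code_table, ode_to_joy_fixture,
                     reverse_translate, translate, run_simulation, align_music)

table = build_default_code_table()
ancestor = ode_to_joy_fixture()          # 62-element Ode to Joy melody
print("elements:", len(ancestor), "| self-alignment:",
      align_music(ancestor, ancestor).score)

dna = reverse_translate(ancestor, table, seed=42)
print("DNA length:", len(dna))
print("round trip ok:", translate(dna, table).elements == ancestor.elements)

for regime in (1, 3, 6):
    traces = run_simulation(ancestor, regime, generations=20, replicates=10,
                            seed=1234 + regime, table=table)
    gen20 = [t.hamming[-1] for t in traces]
    print(f"regime {regime}: mean Hamming at generation 20 = {np.mean(gen20):.1f}")
```

prints

```
elements: 62 | self-alignment: 310.0
DNA length: 248
round trip ok: True
regime 1: mean Hamming at generation 20 = 45.6
regime 3: mean Hamming at generation 20 = 83.1
regime 6: mean Hamming at generation 20 = 114.7
```

Reading the numbers: the 62-element melody encodes as 62 × 4 = 248
bases and decodes back exactly. Even with **zero** injected mutation
(regime 1), each generation's DNA sits ~46.5 ≈ 0.75 × 62 bases from
the ancestor, because reverse translation re-draws every codon's
wobble base uniformly — this plateau is pure synonymous scatter and
does not grow. One nonsynonymous DNA mutation per generation (regime
3) accumulates real divergence on top of that plateau, and mutating at
both the DNA and the music level (regime 6, 40 nonsynonymous events in
20 generations versus regime 3's 20) roughly doubles the accumulated
load — the cost of bidirectional transmission.

The same operations are available from a shell:

```
melodna encode --ancestor fixture:ode-to-joy --out ode.fasta --seed 42
melodna simulate --regime 6 --generations 20 --replicates 10 --seed 7 --out trace.tsv
melodna evolve --strategy purifying --noise noisy --seed 7 --out rounds.tsv
melodna render --ancestor fixture:ode-to-joy --wav ode.wav
```

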