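# tonalctx

An auditory short-term-memory (ASTM) model of **tonal contextuality**, with a
psychoacoustic stimulus generator and a simulation harness for the classic
harmonic-priming, ERP, probe-tone, melodic, and artificial-grammar paradigms
of music-cognition research.

## The scientific question

Much of the evidence for "musical syntax" comes from experiments in which a
syntactically related chord or tone (a tonic after its key context) is
processed more easily than an unrelated one. `tonalctx` implements the
sensory alternative: a listener who merely accumulates *acoustic* information
in echoic memory will often show the same contrasts, because related events
share harmonic and subharmonic spectra with their context. The model lets you
quantify, for any stimulus set, how much of a "syntactic" effect survives
once this sensory channel is accounted for.

## The model

Audio (44.1 kHz WAV or synthesized in-package) passes through four stages:

1. **Peripheral auditory model** — outer/middle-ear low-pass, 40 gammatone
   channels (ERB-spaced 80 Hz–5 kHz), and a hair-cell stage (half-wave
   rectification, power-law compression, low-pass at the 1250 Hz
   phase-locking limit) producing an auditory nerve image (ANI).
2. **Periodicity pitch** — windowed autocorrelation per channel, summed over
   channels into framed *pitch images*: evidence for a pitch at 1/lag for
   each lag in 0.8–25 ms (100 frames/s). A 600/800/1000 Hz complex peaks at
   5 ms — the missing fundamental at 200 Hz.
3. **Echoic memory** — leaky integration of pitch images,

       p(n) = p_in(n) + p(n−1) · 2^(−1/(sa·T)),

   where `T` is the *half-decay* time. A short decay (default `T_local` =
   0.1 s) gives the Local Pitch Image (the immediate percept); a long decay
   (default `T_global` = 1.5 s) the Global Pitch Image (the accumulated
   context). These two decays are the model's only free parameters.
4. **Tonal contextuality** — `TC(t)` = Pearson correlation between local and
   global images at each frame; Fisher's `z = atanh(r)` for statistics. The
   mean of `TC(t)` over a target event's window (`TC_target`) indexes how
   well that event fits its context: high TC = low tonal tension.

The experiment runner sweeps both decays over 0.1–2.5 s, differences
`TC_target` between matched conditions, and tests each grid cell with a
two-tailed paired t-test (α = 0.05), producing the familiar
hot/cold/white heatmaps.

## Worked example

```python
import tonalctx as tx

# 1. virtual pitch: 600+800+1000 Hz is heard at 200 Hz
audio = tx.synth_complex_tone([600, 800, 1000], duration=1.0)
series = tx.pitch_series(audio)            # periphery + autocorrelation
print(tx.dominant_pitch(series.frame(40))) # 200.06 Hz

# 2. a harmonic-priming simulation at reduced scale
report = tx.reproduce("bp97_tonic_subdom", out_dir="out", scale="reduced")
print(report["verdict"])                                    # 'sensory'
print(report["comparisons"]["related_vs_less_related"])
# {'frac_positive_cells': 1.0, 'frac_significant_cells': 0.8,
#  'mean_diff_at_default': 0.213, 'n_pairs': 2}
```

The first call prints the model's pitch estimate for the missing
fundamental (200.06 Hz, against the nominal 200 Hz). The second synthesizes
eight-chord sequences whose final chord is heard as a tonic (related) or a
subdominant (less related), runs them through the model over a 5×5 decay
grid, and reports that the related target has the higher tonal contextuality
in every off-diagonal grid cell — the sensory account of the global-context
priming effect (`mean_diff_at_default` is the z-difference at the default
0.1/1.5 s decays).

The same interface is available from the shell:

```sh
tonalctx synth --preset leino07 --seed 0 --out stimuli/
tonalctx tc stimuli/inkey_k0.wav --timeline stimuli/inkey_k0.json --out tc.csv
tonalctx sweep --preset slevc09_chords --conditions inkey,out_of_key \
    --grid 0.1:2.5:0.6 --out grids/
tonalctx reproduce occurrence_2003_B --scale reduced --out reproductions/
```

Stimulus presets cover 24 paradigms (`tonalctx.PRESETS`): Shepard-tone chord
pairs, SOA/noise manipulations, eight-chord global-context designs and their
scrambled/occurrence variants, Neapolitan and mistuned cadences,
chorale-style and supertonic/secondary-dominant endings, Bohlen–Pierce
3:5:7 chord streams, probe-tone scale contexts, and pure-tone melodies.

## Layout

| module | contents |
|---|---|
| `tonalctx.synthesis` | tones, timbres (Shepard / additive piano / pure), timelines, WAV+JSON I/O |
| `tonalctx.presets` | the stimulus registry and pairing structure for every simulated study |
| `tonalctx.periphery` | outer/middle ear, gammatone filterbank, hair-cell stage |
| `tonalctx.pitch` | framed summary autocorrelation, pitch images, dominant pitch |
| `tonalctx.memory` | leaky integration at local/global time scales |
| `tonalctx.contextuality` | TC series, Fisher z, target-window aggregation |
| `tonalctx.runner` | decay-grid sweeps, paired statistics, heatmaps, study reproductions |

See `docs/methods.md` for modeling assumptions, parameter choices, and known
limitations.
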