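# Methods

This note records the modeling assumptions, parameter choices, and known
limitations of `tonalctx`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model structure and assumptions

The model treats tonal expectation as a property of auditory sensory memory:
no long-term knowledge, learning, or symbolic representation of keys and
chords enters anywhere. Its currency is the *pitch image* — a vector of
periodicity evidence over autocorrelation lag — and its only free parameters
are the two half-decay times of a leaky integrator. Everything else
(filterbank, hair-cell law, framing) is fixed plumbing whose job is to turn
sound into periodicity evidence with the right qualitative behavior:

* tones more than a critical band apart are resolved by different channels;
  tones within a critical band interfere and beat at their difference
  frequency (990+1100 Hz → 110 Hz);
* harmonically related partials produce a common low-lag peak — the virtual
  pitch (600/800/1000 Hz → 5 ms → 200 Hz);
* fine structure above the phase-locking limit (1250 Hz) is removed, so
  pitch evidence comes from temporal, not place, coding.

These behaviors, not any particular coefficient set, are the tested contract
of the front end.

## Parameters

| parameter | value | units | rationale |
|---|---|---|---|
| channels | 40, ERB-spaced 80–5000 | Hz | covers the musical pitch range; ERB spacing gives critical-band resolvability |
| outer/middle ear LPF | 2nd order, 4 kHz, zero-phase | — | passes the musical range untouched; zero phase keeps event onsets aligned with the timeline |
| compression exponent | 0.3 | — | standard hair-cell surrogate; TC is correlation-based, so the exact law is immaterial (loudness-invariance test) |
| phase-lock LPF | 4th order, 1250 | Hz | the stated upper limit of phase locking |
| internal rates | 22050 (bands), 11025 (ANI) | Hz | resolves all lags of interest at ~0.09 ms while keeping the periphery cheap and the gammatone filters well-conditioned |
| frame window / hop | 64 / 10 | ms | 100 frames/s makes the memory recurrence arithmetic transfer literally (half-decay at frame sa·T+1) |
| lag range | 0.8–25 | ms | ~40–1250 Hz pitch evidence; spans the worked examples |
| T_local, T_global defaults | 0.1, 1.5 | s | the classical echoic-memory settings for probe-tone modeling |
| sweep grid | 0.1–2.5 step 0.1 (full); 5×5 step 0.6 (reduced) | s | full grid = 625 cells; reduced grid for desk-scale runs |
| significance | paired two-tailed t, α=0.05, per cell | — | matches the per-cell heatmap convention; no multiple-testing correction by default |

Frame normalization: each frame of the summary autocorrelation is divided by
its own sum, so every nonempty pitch image is a unit-mass distribution over
lag. Pearson correlation is scale-free anyway; the normalization additionally
makes the *integrated* images independent of absolute level, which the tests
verify to 1e-6 on Fisher-z. Frames whose energy is below 1e-7 of the loudest
frame are flagged *empty* (silence has no pitch) and excluded from window
means; the threshold is relative so that loudness invariance is exact.

Negative autocorrelation values (possible with windowed estimators) are
clipped to zero before summation: pitch evidence is nonnegative.

## Echoic memory

The integrator is the exact recurrence `p(n) = p_in(n) + p(n−1)·2^(−1/(sa·T))`
applied along frames with `scipy.signal.lfilter`; an impulse halves after
exactly `sa·T` steps (closed form, tested to 1e-12), and the recurrence
agrees with direct convolution against the geometric kernel to 1e-10.
Per-trial runs start from a zero state; *continuous* runs (the cadence and
chord-stream paradigms) concatenate the frame series of all items in a
seeded random order, integrate once across the whole stream so state carries
between sequences, and reset only between runs. Per-item values are averaged
over runs. Concatenation happens at the frame level, so the ~64 ms analysis
window at each item boundary sees only its own item; the memory trace itself
is continuous.

## Tonal contextuality and windows

`TC(t)` is the per-frame Pearson correlation between local and global images
over lag bins; frames where either image is empty or constant are marked
undefined rather than filled. Statistics run on `z = atanh(r)` (clipped at
|r| = 1−1e-7), with mean `r` reported alongside. Window conventions follow
the simulated designs: the full event span by default; 200±25 ms post-onset
for the Neapolitan cadences; 0–200 ms (with 200–400 and 400–600 available)
for the ERP-style paradigms. Frame membership uses window-center times.

On the sweep diagonal (`T_local = T_global`) the two images coincide, `r ≡ 1`
and every difference is identically zero, so grid sign fractions are
computed over off-diagonal cells.

## The stimulus generator

The generator emulates the stimulus *designs* of the simulated studies —
their timing, timbre class, key transpositions, pairing structure, and the
harmonic relations that carry each manipulation — not any particular
recorded realization. Where a source study's exact note content is not
published, the presets use generic constructions with the published design
parameters; the constructions were checked against the musical property each
design turns on (e.g., the supertonic-paradigm context shares more component
tones with the supertonic than with the tonic target; the occurrence
paradigm's contexts are built from subdominant-side substitutions; the
Bohlen–Pierce deviant chord preserves the one-shared-tone chain on both
sides, so the probability manipulation is not confounded with chain
structure).

Specific choices:

* **Voicing.** Triads are close root-position chords with the root fixed in
  G3–F#4, so all chords sit in one chorale register. (Pitch-image similarity
  is register-sensitive; letting target registers wander with root pitch
  class confounds the harmonic manipulations.)
* **Shepard tones.** Octave-spaced partials under a raised-cosine envelope
  over log2-frequency, centered on C4, spanning 6 octaves; octave-invariant
  by construction (tested byte-exact).
* **Piano timbre.** Additive synthesis: 10 harmonics, 1/k rolloff, 5 ms
  attack, exponential decay τ = 0.4 s. Deterministic and dependency-free; a
  sampled piano can be substituted by rendering timelines externally and
  feeding WAV files to the `tc` pipeline.
* **Mistuning.** +35 cents on the chord third (configurable) — inside the
  mistuning-detection range, far below a semitone.
* **Tone clusters** (control condition): four chromatically adjacent
  tones starting on the expected root (`presets.CLUSTER`).
* **Melodies.** The pure-tone melody paradigm uses a triad-based tune whose
  critical note repeats an earlier same-octave tone; the within-key change
  moves it to the diatonic lower neighbor (F in C), the out-of-key change to
  the chromatic tone between (F#). The random-melody paradigm draws five
  diatonic tones per sequence from a seeded generator.
* **Counts.** Item counts not printed by the sources are parameterized with
  defaults (one sequence pair per key for the eight-chord designs; 144
  prime–target pairs for the Shepard paradigms; 100-sequence streams for the
  chord-grammar paradigm).

What the generator does **not** emulate: expressive performance, sampled
instrument spectra, room acoustics, loudness calibration in dB SPL, or the
exact chord progressions of studies whose scores are not published. Passing
direction-of-effect tests therefore shows that the *sensory account
mechanism* reproduces each study's contrast under a faithful design, not
that these exact waveforms were used historically.

## Reduced-scale reproduction and statistics

The reproduction suite runs every paradigm at reduced scale: a 5×5 decay
grid, 2 transpositions (24 pairs for the 144-pair paradigm, 20-sequence
streams for the chord-grammar paradigm, 10 random orders for the continuous
designs). Full 25×25 grids over 12 keys (`scale="full"`) are the
long-running mode. Verdicts are assigned from the sign pattern of the
primary contrast: ≥90% positive off-diagonal cells → sensory account; ≤10%
→ cognitive account (the model predicts the *reverse* of behavior); anything
between → mixed. The paired t-test reports a capped statistic (|t| = 1e6,
p = 1e-12) when a difference vector has exactly zero variance, which can
occur on deterministic stimulus sets.

## Known limitations

* Fine similarity orderings among chords that share *no* component tones
  with their prime are not reliably reproduced: whole-tone-related roots
  rank at the bottom of this implementation's similarity landscape, below
  tritone-related roots, for every front-end variant we probed. The
  flattened-seventh priming paradigms (`bs87_*`) therefore come out with the
  reversed sign. Coarse orderings (shared-tone > unshared, in-key >
  out-of-key, graded key distance, V→I subharmonic priming) reproduce.
* In the Neapolitan-cadence paradigm the in-key-minus-deviant difference is
  positive wherever the local decay is short enough (≤ ~0.7 s) for the
  200 ms window to register the deviant, but turns slightly negative at long
  local decays, where a deviant raises the correlation by entering both
  stores together. The pooled grid is therefore ~70% rather than ≥90%
  positive.
* No place coding, roughness, stream segregation, timbre similarity, or
  attentional/interference mechanism: paradigms whose effects hinge on those
  channels are outside the model's reach by design.
* The periphery is behavior-matched, not coefficient-matched, to the
  original auditory toolbox; quantities that depend on exact filter shapes
  (absolute TC magnitudes, heatmap contours) are not comparable
  figure-by-figure, which is why tests assert signs, orderings, and
  closed-form values instead.
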