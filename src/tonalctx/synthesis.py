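"""Psychoacoustic stimulus synthesis: notes, timbres, timelines.

Three timbre families cover the simulated paradigms:

* ``shepard`` -- octave-spaced partials under a fixed raised-cosine envelope
  over log-frequency, giving pitch-class identity without a definite octave
  (the classical construction for chord-priming stimuli);
* ``additive_piano`` -- additive harmonic synthesis with 1/k amplitude
  rolloff and an exponentially decaying envelope, a deterministic stand-in
  for a piano timbre;
* ``pure`` / ``complex`` -- sinusoids and generic harmonic complexes.

All rendering is deterministic; audio is produced at CD rate (44.1 kHz) and
peak-normalized to 0.5 full scale so it is clip-free.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .periphery import AudioSignal

SR = 44100
#: raised-cosine on/off ramp for steady tones, s
RAMP_S = 0.010
A4_HZ = 440.0


def pc_to_freq(pitch_class: float, octave: int = 4) -> float:
    """12-TET frequency of a pitch class (0 = C) at a given octave, A4 = 440 Hz."""
    midi = 12 * (octave + 1) + pitch_class
    return A4_HZ * 2.0 ** ((midi - 69) / 12.0)


def bp_scale_freq(step: int, base: float) -> float:
    """Frequency of a Bohlen-Pierce scale step: the tritave (3:1) split in 13."""
    if base <= 0:
        raise ValueError("base frequency must be positive")
    return base * 3.0 ** (step / 13.0)


@dataclass
class NoteEvent:
    """One tone: either a fixed frequency or a pitch class + octave (12-TET)."""

    onset: float
    duration: float
    amplitude: float = 1.0
    mistune_cents: float = 0.0
    frequency: float | None = None
    pitch_class: int | None = None
    octave: int = 4

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be nonnegative")
        if self.frequency is None and self.pitch_class is None:
            raise ValueError("a note needs a frequency or a pitch class")
        if self.frequency is not None and self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def freq(self) -> float:
        f = self.frequency if self.frequency is not None else pc_to_freq(
            self.pitch_class, self.octave
        )
        return f * 2.0 ** (self.mistune_cents / 1200.0)

    def transposed(self, semitones: int) -> "NoteEvent":
        if self.pitch_class is None:
            raise ValueError("cannot transpose a frequency-defined note")
        pc = self.pitch_class + semitones
        return replace(self, pitch_class=pc % 12, octave=self.octave + pc // 12)


@dataclass
class TimbreSpec:
    """How a note is realized as partials."""

    kind: str = "additive_piano"
    n_partials: int = 10
    rolloff: float = 1.0  # amplitude of partial k is k**-rolloff
    attack: float = 0.005
    release: float = RAMP_S
    decay_tau: float | None = 0.4  # s; None = sustained
    shepard_center: float = 261.6256  # Hz (C4)
    shepard_octaves: int = 6
    omit_partials: tuple[int, ...] = ()  # 1-based indices of partials to drop

    def __post_init__(self) -> None:
        if self.kind not in VALID_TIMBRES:
            raise ValueError(
                f"unknown timbre kind {self.kind!r}; valid kinds: "
                + ", ".join(sorted(VALID_TIMBRES))
            )
        if self.n_partials < 1:
            raise ValueError("n_partials must be >= 1")


VALID_TIMBRES = {"shepard", "additive_piano", "pure", "complex"}

SHEPARD = TimbreSpec(kind="shepard", attack=RAMP_S, decay_tau=None)
PIANO = TimbreSpec(kind="additive_piano")
PURE = TimbreSpec(kind="pure", attack=RAMP_S, decay_tau=None)


@dataclass
class EventTimeline:
    """Ordered chord groups plus the analysis window(s) of the target event."""

    events: list[list[NoteEvent]]
    target_window: tuple[float, float]
    condition_label: str = ""
    key_label: str = ""
    #: extra named event windows (e.g. per-position windows in a cadence)
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: white-noise spans (start, duration, amplitude), e.g. noise-filled SOA gaps
    noise_spans: list[tuple[float, float, float]] = field(default_factory=list)
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_window[1] <= self.target_window[0]:
            raise ValueError("target window must have positive length")

    @property
    def duration(self) -> float:
        d = max((n.onset + n.duration for ch in self.events for n in ch), default=0.0)
        return max(d, max((s + du for s, du, _ in self.noise_spans), default=0.0))

    def transposed(self, semitones: int) -> "EventTimeline":
        return replace(
            self,
            events=[[n.transposed(semitones) for n in ch] for ch in self.events],
        )


def _env(duration: float, timbre: TimbreSpec, sr: int) -> np.ndarray:
    n = int(round(duration * sr))
    env = np.ones(n)
    na = min(int(round(timbre.attack * sr)), n)
    if na > 1:
        env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    if timbre.decay_tau is not None:
        t = np.arange(n) / sr
        env *= np.exp(-np.maximum(t - timbre.attack, 0.0) / timbre.decay_tau)
    nr = min(int(round(timbre.release * sr)), n)
    if nr > 1:
        env[-nr:] *= 0.5 * (1 + np.cos(np.pi * np.arange(nr) / nr))
    return env


def synth_complex_tone(
    freqs, amps=None, duration: float = 1.0, sr: int = SR
) -> AudioSignal:
    """Sum of sinusoids with 10 ms raised-cosine ramps, peak-normalized to 0.5."""
    freqs = list(freqs)
    amps = [1.0] * len(freqs) if amps is None else list(amps)
    if len(amps) != len(freqs):
        raise ValueError("freqs and amps must have equal length")
    for f in freqs:
        if not 0 < f < sr / 2:
            raise ValueError(
                f"partial at {f} Hz is at or above the Nyquist frequency ({sr / 2} Hz)"
            )
    n = int(round(duration * sr))
    t = np.arange(n) / sr
    x = np.zeros(n)
    for f, a in zip(freqs, amps):
        x += a * np.sin(2 * np.pi * f * t)
    nr = min(int(round(RAMP_S * sr)), n)
    if nr > 1:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        x[:nr] *= ramp
        x[-nr:] *= ramp[::-1]
    peak = np.abs(x).max()
    if peak > 0:
        x *= 0.5 / peak
    return AudioSignal(x, sr)


def _partials(note: NoteEvent, timbre: TimbreSpec, sr: int):
    """(freq, amp) pairs realizing the note under the given timbre."""
    detune = 2.0 ** (note.mistune_cents / 1200.0)
    if timbre.kind == "shepard":
        if note.pitch_class is None:
            raise ValueError("shepard notes must be given as pitch classes")
        fc, span = timbre.shepard_center, timbre.shepard_octaves
        base = pc_to_freq(note.pitch_class, 4)
        out = []
        for k in range(-6, 7):
            f = base * 2.0**k * detune
            x = np.log2(f / fc)
            if abs(x) <= span / 2 and f < sr / 2:
                out.append((f, 0.5 * (1 + np.cos(2 * np.pi * x / span))))
        out.sort()
    else:
        f0 = note.freq
        out = []
        for k in range(1, timbre.n_partials + 1):
            f = k * f0
            if f >= sr / 2:
                break
            out.append((f, k**-timbre.rolloff))
        if timbre.kind == "pure":
            out = out[:1]
    out = [(f, a) for i, (f, a) in enumerate(out, start=1)
           if i not in timbre.omit_partials]
    if not out:
        raise ValueError("note has no partials below Nyquist")
    return out


def synth_note(note: NoteEvent, timbre: TimbreSpec, sr: int = SR) -> AudioSignal:
    """Render one note (ignoring its onset), peak-normalized to 0.5 x amplitude."""
    n = int(round(note.duration * sr))
    t = np.arange(n) / sr
    x = np.zeros(n)
    for f, a in _partials(note, timbre, sr):
        x += a * np.sin(2 * np.pi * f * t)
    x *= _env(note.duration, timbre, sr)
    peak = np.abs(x).max()
    if peak > 0:
        x *= 0.5 * note.amplitude / peak
    return AudioSignal(x, sr)


def render_timeline(tl: EventTimeline, timbre: TimbreSpec, sr: int = SR) -> AudioSignal:
    """Additively mix all notes at their onsets; global peak normalized to 0.5."""
    if not tl.events and not tl.noise_spans:
        raise ValueError("cannot render an empty timeline")
    total = int(round(tl.duration * sr)) + 1
    mix = np.zeros(total)
    for chord in tl.events:
        for note in chord:
            y = synth_note(note, timbre, sr).samples
            i0 = int(round(note.onset * sr))
            mix[i0 : i0 + len(y)] += y
    if tl.noise_spans:
        rng = np.random.default_rng(tl.noise_seed)
        for start, dur, amp in tl.noise_spans:
            i0 = int(round(start * sr))
            m = int(round(dur * sr))
            mix[i0 : i0 + m] += amp * rng.standard_normal(m)
    peak = np.abs(mix).max()
    if peak > 0:
        mix *= 0.5 / peak
    return AudioSignal(mix.astype(np.float32), sr)


def write_wav(path, audio: AudioSignal) -> None:
    """Write 16-bit PCM WAV."""
    from scipy.io import wavfile

    x = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(path, audio.sr, (x * 32767).astype(np.int16))


def write_timeline_json(path, tl: EventTimeline) -> None:
    payload = {
        "condition_label": tl.condition_label,
        "key_label": tl.key_label,
        "target_window": list(tl.target_window),
        "windows": {k: list(v) for k, v in tl.windows.items()},
        "events": [
            [
                {
                    "onset": n.onset,
                    "duration": n.duration,
                    "frequency": n.freq,
                    "amplitude": n.amplitude,
                }
                for n in chord
            ]
            for chord in tl.events
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_timeline_json(path) -> EventTimeline:
    with open(path) as fh:
        d = json.load(fh)
    events = [
        [
            NoteEvent(
                onset=n["onset"],
                duration=n["duration"],
                amplitude=n.get("amplitude", 1.0),
                frequency=n["frequency"],
            )
            for n in chord
        ]
        for chord in d["events"]
    ]
    return EventTimeline(
        events=events,
        target_window=tuple(d["target_window"]),
        condition_label=d.get("condition_label", ""),
        key_label=d.get("key_label", ""),
        windows={k: tuple(v) for k, v in d.get("windows", {}).items()},
    )
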