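"""Stimulus presets for the simulated harmonic-priming and ERP paradigms.

Each preset builds a :class:`StimulusSet`: rendered audio plus event
timelines, grouped by condition, with an explicit pairing between matched
items of the contrasted conditions.  Where a source study transposed its
material through the 12 major keys, the preset does the same (``n_keys``
can reduce that for quick runs).  Chord voicings are close root-position
triads around octave 4 unless a timbre is octave-free (Shepard tones).

Everything is deterministic given ``(preset_id, seed)``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .periphery import AudioSignal
from .synthesis import (
    PIANO,
    PURE,
    SHEPARD,
    EventTimeline,
    NoteEvent,
    TimbreSpec,
    bp_scale_freq,
    render_timeline,
)

MAJOR = (0, 4, 7)
MINOR = (0, 3, 7)
CLUSTER = (0, 1, 2, 3)  # four chromatically adjacent tones
PC_NAMES = ["C", "Db", "D", "Eb", "E", "F", "Gb", "G", "Ab", "A", "Bb", "B"]


@dataclass
class StimulusItem:
    item_id: str
    condition: str
    key_label: str
    timeline: EventTimeline
    audio: AudioSignal


@dataclass
class PairedComparison:
    """Matched items of conditions A and B, compared in window ``window``."""

    id_a: str
    id_b: str
    window: str = "target"


@dataclass
class StimulusSet:
    preset_id: str
    seed: int
    items: list[StimulusItem]
    pairing: list[PairedComparison]
    timbre: TimbreSpec
    #: preset's analysis-window convention: event_span | p200 | w0_200
    window_mode: str = "event_span"
    #: echoic-memory reset convention: per_trial | continuous
    reset_policy: str = "per_trial"

    def item(self, item_id: str) -> StimulusItem:
        return self._index()[item_id]

    def _index(self) -> dict[str, StimulusItem]:
        if not hasattr(self, "_idx"):
            self._idx = {it.item_id: it for it in self.items}
        return self._idx

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.condition, None)
        return list(seen)


def _chord(root_pc, quality, onset, dur, octave=4, pcs_only=False, amp=1.0,
           mistuned_degree=None, mistune_cents=35.0):
    """NoteEvents of a close root-position chord.

    ``pcs_only`` leaves octave placement to the timbre (Shepard tones).
    ``mistuned_degree`` mistunes one chord degree by ``mistune_cents``.
    """
    notes = []
    # root placed in G3..F#4 so triads sit in a fixed chorale register
    root_midi = 12 * (octave + 1) + ((root_pc + 5) % 12) - 5
    for i, iv in enumerate(quality):
        midi = root_midi + iv
        cents = mistune_cents if i == mistuned_degree else 0.0
        notes.append(
            NoteEvent(onset=onset, duration=dur, amplitude=amp,
                      pitch_class=midi % 12, octave=midi // 12 - 1,
                      mistune_cents=cents)
        )
    return notes


def _seq_timeline(chords, durs, target_idx, condition, key, pcs_only=False,
                  positions=None, mistuned=None):
    """Timeline of consecutive chords; windows named per listed position."""
    events, t = [], 0.0
    onsets = []
    for (root, quality), d in zip(chords, durs):
        md = None
        if mistuned is not None and len(events) == mistuned:
            md = 1  # mistune the chord's third
        events.append(_chord(root, quality, t, d, pcs_only=pcs_only,
                             mistuned_degree=md))
        onsets.append(t)
        t += d
    tw = (onsets[target_idx], onsets[target_idx] + durs[target_idx])
    windows = {}
    for p in positions or []:
        windows[f"pos{p + 1}"] = (onsets[p], onsets[p] + durs[p])
    return EventTimeline(events=events, target_window=tw,
                         condition_label=condition, key_label=key,
                         windows=windows)


def _render_items(specs, timbre):
    """specs: (item_id, condition, key, timeline) -> rendered StimulusItems."""
    return [
        StimulusItem(i, c, k, tl, render_timeline(tl, timbre))
        for i, c, k, tl in specs
    ]


# ---------------------------------------------------------------------------
# single-prime chord pairs (Shepard timbre)
# ---------------------------------------------------------------------------

def _pair_preset(preset_id, seed, n_pairs, related_shift, unrelated_shift,
                 modes=("maj",), prime_dur=3.0, target_dur=2.0,
                 timbre=SHEPARD, related_quality=MAJOR, unrelated_quality=MAJOR,
                 soa_gaps=None, noise_amp=None):
    """Prime-target chord pairs: related vs unrelated target after one prime.

    ``soa_gaps`` inserts silence (or noise if ``noise_amp``) between prime
    offset and target onset, producing one pair per (root, gap).
    """
    specs, pairing = [], []
    combos = []
    for gap in (soa_gaps or [0.0]):
        for mode in modes:
            for root in range(12):
                combos.append((root, mode, gap))
    reps = -(-n_pairs // len(combos))
    combos = (combos * reps)[:n_pairs]
    for i, (root, mode, gap) in enumerate(combos):
        q = MAJOR if mode == "maj" else MINOR
        key = PC_NAMES[root] + ("" if mode == "maj" else "m")
        t_on = prime_dur + gap
        for cond, shift, tq in (
            ("related", related_shift, related_quality),
            ("unrelated", unrelated_shift, unrelated_quality),
        ):
            events = [
                _chord(root, q, 0.0, prime_dur, pcs_only=True),
                _chord((root + shift) % 12, tq, t_on, target_dur, pcs_only=True),
            ]
            tl = EventTimeline(
                events=events,
                target_window=(t_on, t_on + target_dur),
                condition_label=cond,
                key_label=key,
            )
            if gap > 0 and noise_amp:
                tl.noise_spans = [(prime_dur, gap, noise_amp)]
                tl.noise_seed = seed * 100003 + i
            tag = f"_soa{int(round((prime_dur + gap) * 1000))}" if soa_gaps else ""
            specs.append((f"p{i:03d}{tag}_{cond}", cond, key, tl))
        pairing.append(PairedComparison(specs[-2][0], specs[-1][0]))
    return StimulusSet(preset_id, seed, _render_items(specs, timbre),
                       pairing, timbre)


def bs86_pairs(seed=0, n_pairs=144):
    """Prime/target Shepard chord pairs; related = shares parent keys (V),
    unrelated = tritone-distant."""
    return _pair_preset("bs86_pairs", seed, n_pairs, 7, 6, modes=("maj", "min"))


def bs87_bflat(seed=0, n_pairs=144):
    """Related target with no shared component tones (bVII), unrelated tritone."""
    return _pair_preset("bs87_bflat", seed, n_pairs, 10, 6)


def bs87_nothird(seed=0, n_pairs=144):
    """As bs87_bflat, with the third partial of every tone removed."""
    timbre = replace(SHEPARD, omit_partials=(3,))
    s = _pair_preset("bs87_nothird", seed, n_pairs, 10, 6, timbre=timbre)
    return s


def tb98_soa_silence(seed=0, gaps=(0.0, 0.45, 1.45, 2.45)):
    """50 ms prime, variable silent gap, 2 s target (related V vs tritone)."""
    return _pair_preset("tb98_soa_silence", seed, 12 * len(gaps), 7, 6,
                        prime_dur=0.05, soa_gaps=list(gaps))


def tb98_soa_noise(seed=0, gaps=(0.45, 1.45, 2.45)):
    """As tb98_soa_silence with the gap filled by white noise."""
    return _pair_preset("tb98_soa_noise", seed, 12 * len(gaps), 7, 6,
                        prime_dur=0.05, soa_gaps=list(gaps), noise_amp=0.1)


def tb99_sensorycog(seed=0, n_pairs=12):
    """Spectrally related but syntactically distant target (III, shares one
    tone) vs syntactically close but spectrally disjoint target (II)."""
    s = _pair_preset("tb99_sensorycog", seed, n_pairs, 4, 2)
    for it in s.items:
        it.condition = {"related": "sensory", "unrelated": "cognitive"}[it.condition]
        it.timeline.condition_label = it.condition
    return s


# ---------------------------------------------------------------------------
# eight-chord sequences (piano timbre)
# ---------------------------------------------------------------------------

CHORD_DUR = 0.6
TARGET_DUR = 1.2

# six context chords + shared penultimate + target, written in C; the
# "related" context establishes C major (the target is its tonic), the
# "less related" context establishes G major without ever sounding a C
# chord, so the same final G-C pair is heard as V-I vs I-IV motion.
_BP97_RELATED_CTX = [(0, MAJOR), (5, MAJOR), (7, MAJOR), (0, MAJOR), (2, MINOR), (7, MAJOR)]
_BP97_LESS_CTX = [(7, MAJOR), (2, MAJOR), (4, MINOR), (7, MAJOR), (11, MINOR), (2, MAJOR)]
_FINAL = [(7, MAJOR), (0, MAJOR)]


def _eight_chord_pair(preset_id, seed, n_keys, variants, timbre=PIANO,
                      window_mode="event_span", scramble_block=None, n_orders=1):
    """Build paired 8-chord sequences from ``variants``:
    {condition: (context_chords, target_chord)} with the shared penultimate."""
    specs, pairing = [], []
    rng = np.random.default_rng(seed)
    durs = [CHORD_DUR] * 7 + [TARGET_DUR]
    conds = list(variants)
    for k in range(n_keys):
        key = PC_NAMES[k]
        for o in range(n_orders):
            perm = None
            if scramble_block:
                blocks = [list(range(i, min(i + scramble_block, 6)))
                          for i in range(0, 6, scramble_block)]
                order = rng.permutation(len(blocks))
                perm = [j for b in order for j in blocks[b]]
            ids = []
            for cond in conds:
                ctx, target = variants[cond]
                ctx = list(ctx)
                if perm:
                    ctx = [ctx[j] for j in perm]
                chords = [((r + k) % 12, q) for r, q in ctx] \
                    + [((r + k) % 12, q) for r, q in _FINAL[:-1]] \
                    + [(((_FINAL[-1][0] if target is None else target[0]) + k) % 12,
                        _FINAL[-1][1] if target is None else target[1])]
                tl = _seq_timeline(chords, durs, 7, cond, key)
                iid = f"{cond}_k{k}_o{o}"
                specs.append((iid, cond, key, tl))
                ids.append(iid)
            for x in range(len(ids)):
                for y in range(x + 1, len(ids)):
                    pairing.append(PairedComparison(ids[x], ids[y]))
    return StimulusSet(preset_id, seed, _render_items(specs, timbre), pairing,
                       timbre, window_mode=window_mode)


def bp97_tonic_subdom(seed=0, n_keys=12):
    """Global-context priming: identical final V-I pair heard as tonic
    (related) vs subdominant (less related) ending."""
    return _eight_chord_pair(
        "bp97_tonic_subdom", seed, n_keys,
        {"related": (_BP97_RELATED_CTX, None),
         "less_related": (_BP97_LESS_CTX, None)})


def scrambled_2x2(seed=0, n_keys=12, n_orders=3):
    """bp97 contexts scrambled in blocks of two chords."""
    return _eight_chord_pair(
        "scrambled_2x2", seed, n_keys,
        {"related": (_BP97_RELATED_CTX, None),
         "less_related": (_BP97_LESS_CTX, None)},
        scramble_block=2, n_orders=n_orders)


def scrambled_4x4(seed=0, n_keys=12, n_orders=3):
    """bp97 contexts scrambled in blocks of four chords."""
    return _eight_chord_pair(
        "scrambled_4x4", seed, n_keys,
        {"related": (_BP97_RELATED_CTX, None),
         "less_related": (_BP97_LESS_CTX, None)},
        scramble_block=4, n_orders=n_orders)


def three_level_1999(seed=0, n_keys=12):
    """Context transposed (penultimate fixed) so the same target is the
    tonic, the subdominant of the dominant-key context, or an out-of-key
    chord of a tritone-distant context: three harmonic-relatedness levels."""
    base = _BP97_RELATED_CTX
    shift = lambda s: [((r + s) % 12, q) for r, q in base]
    return _eight_chord_pair(
        "three_level_1999", seed, n_keys,
        {"related": (base, None),
         "moderately_related": (shift(7), None),
         "less_related": (shift(6), None)})


def outofkey_fmri_2003(seed=0, n_keys=12):
    """Tonic-target sequences vs out-of-key-target counterparts."""
    return _eight_chord_pair(
        "outofkey_fmri_2003", seed, n_keys,
        {"related": (_BP97_RELATED_CTX, None),
         "unrelated": (_BP97_RELATED_CTX, (6, MAJOR))})


# contexts engineered so the subdominant target overlaps the context's pitch
# content more than the tonic target does (chord substitutions on the
# subdominant side); in B the subdominant chord itself occurs in the context.
_OCC_CTX_A = [(2, MINOR), (9, MINOR), (10, MAJOR), (2, MINOR), (9, MINOR), (10, MAJOR)]
_OCC_CTX_B = [(2, MINOR), (5, MAJOR), (10, MAJOR), (2, MINOR), (5, MAJOR), (10, MAJOR)]


def occurrence_2003_A(seed=0, n_keys=12):
    """Neither target occurs in the context, but the context is built from
    subdominant-side substitutions."""
    return _eight_chord_pair(
        "occurrence_2003_A", seed, n_keys,
        {"related": (_OCC_CTX_A, (0, MAJOR)),
         "less_related": (_OCC_CTX_A, (5, MAJOR))})


def occurrence_2003_B(seed=0, n_keys=12):
    """The less-related (subdominant) target occurs in the context."""
    return _eight_chord_pair(
        "occurrence_2003_B", seed, n_keys,
        {"related": (_OCC_CTX_B, (0, MAJOR)),
         "less_related": (_OCC_CTX_B, (5, MAJOR))})


# ---------------------------------------------------------------------------
# cadences for the ERP simulations (piano timbre)
# ---------------------------------------------------------------------------

def patel98_keys(seed=0, n_keys=12):
    """Rhythmically varied cadence; target is the tonic of the main key, of a
    nearby key (2 fifths away) or of a distant key (tritone)."""
    beat = 0.5  # 120 beats/min
    ctx = [(0, MAJOR), (5, MAJOR), (7, MAJOR), (0, MAJOR), (9, MINOR),
           (2, MINOR), (7, MAJOR)]
    beats = [1, 0.5, 0.5, 1, 0.25, 0.75, 1]
    durs = [b * beat for b in beats] + [2 * beat]
    targets = {"inkey": 0, "nearby": 2, "distant": 6}
    specs, pairing = [], []
    for k in range(n_keys):
        key = PC_NAMES[k]
        ids = {}
        for cond, shift in targets.items():
            chords = [((r + k) % 12, q) for r, q in ctx] + [((shift + k) % 12, MAJOR)]
            tl = _seq_timeline(chords, durs, len(chords) - 1, cond, key)
            iid = f"{cond}_k{k}"
            ids[cond] = iid
            specs.append((iid, cond, key, tl))
        pairing.append(PairedComparison(ids["inkey"], ids["nearby"]))
        pairing.append(PairedComparison(ids["inkey"], ids["distant"]))
    return StimulusSet("patel98_keys", seed, _render_items(specs, PIANO),
                       pairing, PIANO)


_LEINO_BASE = [(0, MAJOR), (5, MAJOR), (0, MAJOR), (7, MAJOR), (5, MAJOR),
               (7, MAJOR), (0, MAJOR)]


def leino07(seed=0, n_keys=12, mistune_cents=35.0, include_mistuned=True):
    """Seven-chord cadences; a Neapolitan sixth (or a mistuned in-key chord)
    replaces the chord at position 3, 5 or 7.  Positions 3 and 7 carry the
    tonic (incorrect position for a Neapolitan), position 5 the subdominant
    (where a Neapolitan is syntactically acceptable).  Presented continuously
    in random order; the analysis window is 200 +- 25 ms post target onset.
    """
    durs = [CHORD_DUR] * 6 + [TARGET_DUR]
    positions = [2, 4, 6]
    specs, pairing = [], []
    for k in range(n_keys):
        key = PC_NAMES[k]
        base = [((r + k) % 12, q) for r, q in _LEINO_BASE]
        tl = _seq_timeline(base, durs, 6, "inkey", key, positions=positions)
        inkey_id = f"inkey_k{k}"
        specs.append((inkey_id, "inkey", key, tl))
        for p in positions:
            cond = f"neap{p + 1}"
            chords = list(base)
            chords[p] = ((1 + k) % 12, MAJOR)
            tlp = _seq_timeline(chords, durs, 6, cond, key, positions=[p])
            specs.append((f"{cond}_k{k}", cond, key, tlp))
            pairing.append(PairedComparison(inkey_id, f"{cond}_k{k}",
                                            window=f"pos{p + 1}"))
            if include_mistuned:
                cond = f"mist{p + 1}"
                tlm = _seq_timeline(base, durs, 6, cond, key, positions=[p],
                                    mistuned=p)
                for n in tlm.events[p]:
                    if n.mistune_cents:
                        n.mistune_cents = mistune_cents
                specs.append((f"{cond}_k{k}", cond, key, tlm))
                pairing.append(PairedComparison(inkey_id, f"{cond}_k{k}",
                                                window=f"pos{p + 1}"))
    return StimulusSet("leino07", seed, _render_items(specs, PIANO), pairing,
                       PIANO, window_mode="p200", reset_policy="continuous")


_STEIN_CTX = [(0, MAJOR), (5, MAJOR), (0, MAJOR), (7, MAJOR)]


def steinbeis06(seed=0, n_keys=12):
    """Chorale-style phrase ending on the tonic (expected), its relative
    minor substitute (unexpected) or a Neapolitan sixth (very unexpected)."""
    durs = [CHORD_DUR] * 4 + [TARGET_DUR]
    targets = {"expected": (0, MAJOR), "unexpected": (9, MINOR),
               "very_unexpected": (1, MAJOR)}
    specs, pairing = [], []
    for k in range(n_keys):
        key = PC_NAMES[k]
        ids = {}
        for cond, (r, q) in targets.items():
            chords = [((c + k) % 12, cq) for c, cq in _STEIN_CTX] + [((r + k) % 12, q)]
            tl = _seq_timeline(chords, durs, 4, cond, key)
            iid = f"{cond}_k{k}"
            ids[cond] = iid
            specs.append((iid, cond, key, tl))
        pairing.append(PairedComparison(ids["expected"], ids["unexpected"]))
        pairing.append(PairedComparison(ids["expected"], ids["very_unexpected"]))
    return StimulusSet("steinbeis06", seed, _render_items(specs, PIANO),
                       pairing, PIANO, window_mode="w0_200")


# tonic-opening context whose recent chords are supertonic-side (Dm, G): at
# short global decays the memory holds mostly Dm/G material (favoring the
# supertonic and secondary-dominant targets), while long decays retain the
# opening tonic -- the source of the mixed-sign parameter space
_K07_CTX = [(0, MAJOR), (5, MAJOR), (2, MINOR), (7, MAJOR)]


def koelsch07_supertonic(seed=0, n_keys=12):
    """Cadence ending on tonic, supertonic, or secondary dominant; the tonic
    is syntactically most expected but acoustically least primed."""
    durs = [CHORD_DUR] * 4 + [TARGET_DUR]
    targets = {"tonic": (0, MAJOR), "supertonic": (2, MINOR),
               "secondary_dominant": (2, MAJOR)}
    specs, pairing = [], []
    for k in range(n_keys):
        key = PC_NAMES[k]
        ids = {}
        for cond, (r, q) in targets.items():
            chords = [((c + k) % 12, cq) for c, cq in _K07_CTX] + [((r + k) % 12, q)]
            tl = _seq_timeline(chords, durs, 4, cond, key)
            iid = f"{cond}_k{k}"
            ids[cond] = iid
            specs.append((iid, cond, key, tl))
        pairing.append(PairedComparison(ids["tonic"], ids["supertonic"]))
        pairing.append(PairedComparison(ids["tonic"], ids["secondary_dominant"]))
    return StimulusSet("koelsch07_supertonic", seed,
                       _render_items(specs, PIANO), pairing, PIANO,
                       window_mode="w0_200")


# ---------------------------------------------------------------------------
# Bohlen-Pierce chord streams
# ---------------------------------------------------------------------------

BP_BASE_HZ = 220.0
#: BP steps approximating the 3:5:7 chord (3^(6/13) ~ 5/3, 3^(10/13) ~ 7/3)
_BP_CHORD_STEPS = (0, 6, 10)
#: root steps of the standard four-chord sequence; adjacent chords share one
#: frequency component
_BP_STANDARD_ROOTS = (0, 4, 8, 2)
#: deviant root replacing position 3; like the standard chord it shares one
#: frequency with each of its neighbors, so the sequences differ only in
#: their statistics, not in local chain structure
_BP_DEVIANT_ROOT = -2


def _bp_chord_events(root_step, onset, dur):
    return [
        NoteEvent(onset=onset, duration=dur,
                  frequency=bp_scale_freq(root_step + s, BP_BASE_HZ))
        for s in _BP_CHORD_STEPS
    ]


def _bp_sequence(deviant: bool, cond: str) -> EventTimeline:
    roots = list(_BP_STANDARD_ROOTS)
    if deviant:
        roots[2] = _BP_DEVIANT_ROOT
    events = [_bp_chord_events(r, i * CHORD_DUR, CHORD_DUR)
              for i, r in enumerate(roots)]
    return EventTimeline(events=events,
                         target_window=(2 * CHORD_DUR, 3 * CHORD_DUR),
                         condition_label=cond)


def _loui(preset_id, seed, n_sequences, p_deviant):
    n_dev = int(round(p_deviant * n_sequences))
    timbre = PURE
    specs = []
    for i in range(n_sequences - n_dev):
        specs.append((f"std{i:03d}", "standard", "BP", _bp_sequence(False, "standard")))
    for i in range(n_dev):
        specs.append((f"dev{i:03d}", "deviant", "BP", _bp_sequence(True, "deviant")))
    pairing = [PairedComparison(f"std{i:03d}", f"dev{i:03d}") for i in range(n_dev)]
    return StimulusSet(preset_id, seed, _render_items(specs, timbre), pairing,
                       timbre, window_mode="w0_200", reset_policy="continuous")


def loui09_equiprobable(seed=0, n_sequences=100):
    """Bohlen-Pierce 4-chord sequences, standard and deviant equiprobable."""
    return _loui("loui09_equiprobable", seed, n_sequences, 0.5)


def loui09_8020(seed=0, n_sequences=100):
    """Bohlen-Pierce streams with 80% standard / 20% deviant sequences."""
    return _loui("loui09_8020", seed, n_sequences, 0.2)


# ---------------------------------------------------------------------------
# probe-tone and melody paradigms
# ---------------------------------------------------------------------------

MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)
MINOR_SCALE = (0, 2, 3, 5, 7, 8, 11)  # harmonic minor


def _kk_probe(preset_id, seed, scale):
    """Scale context followed (after a pause) by each of the 12 chromatic
    probes; one item per probe, Shepard tones."""
    tone_dur, pause, probe_dur = 0.5, 0.5, 1.0
    specs = []
    for probe in range(12):
        events = []
        t = 0.0
        for deg in list(scale) + [0]:
            events.append([NoteEvent(onset=t, duration=tone_dur, pitch_class=deg)])
            t += tone_dur
        t += pause
        events.append([NoteEvent(onset=t, duration=probe_dur, pitch_class=probe)])
        tl = EventTimeline(events=events, target_window=(t, t + probe_dur),
                           condition_label=f"probe_{probe}", key_label="C")
        specs.append((f"probe{probe:02d}", f"probe_{probe}", "C", tl))
    return StimulusSet(preset_id, seed, _render_items(specs, SHEPARD), [],
                       SHEPARD)


def kk_probe_major(seed=0):
    """Major-scale probe-tone paradigm (12 chromatic probes)."""
    return _kk_probe("kk_probe_major", seed, MAJOR_SCALE)


def kk_probe_minor(seed=0):
    """Minor-scale probe-tone paradigm (12 chromatic probes)."""
    return _kk_probe("kk_probe_minor", seed, MINOR_SCALE)


_TT_MELODY = [60, 64, 67, 64, 60, 67, 64, 62, 60, 60]  # midi, C major triad tune
_TT_CHANGE_POS = 5


def trainor_trehub94(seed=0, n_keys=12):
    """Ten-note pure-tone melody; the critical note is left unchanged, moved
    within the key, or moved out of the key."""
    tone_dur = 0.4
    variants = {"original": 67, "within_key": 65, "out_of_key": 66}
    specs, pairing = [], []
    for k in range(n_keys):
        key = PC_NAMES[k]
        ids = {}
        for cond, m in variants.items():
            notes = list(_TT_MELODY)
            notes[_TT_CHANGE_POS] = m
            events = [
                [NoteEvent(onset=i * tone_dur, duration=tone_dur,
                           pitch_class=(n + k) % 12, octave=(n + k) // 12 - 1)]
                for i, n in enumerate(notes)
            ]
            t0 = _TT_CHANGE_POS * tone_dur
            tl = EventTimeline(events=events, target_window=(t0, t0 + tone_dur),
                               condition_label=cond, key_label=key)
            iid = f"{cond}_k{k}"
            ids[cond] = iid
            specs.append((iid, cond, key, tl))
        pairing.append(PairedComparison(ids["original"], ids["within_key"]))
        pairing.append(PairedComparison(ids["original"], ids["out_of_key"]))
    return StimulusSet("trainor_trehub94", seed, _render_items(specs, PURE),
                       pairing, PURE)


def fedorenko09_melodic(seed=0, n_keys=12, n_sequences=10):
    """Five random diatonic tones then a target: the tonic vs an out-of-key
    tone a semitone above it.  Pure tones, 500 ms each."""
    tone_dur = 0.5
    rng = np.random.default_rng(seed)
    specs, pairing = [], []
    for k in range(n_keys):
        key = PC_NAMES[k]
        for s in range(n_sequences):
            degs = rng.choice(MAJOR_SCALE, size=5)
            ids = {}
            for cond, tpc in (("tonic", 0), ("out_of_key", 1)):
                events = [
                    [NoteEvent(onset=i * tone_dur, duration=tone_dur,
                               pitch_class=int((d + k) % 12), octave=5)]
                    for i, d in enumerate(degs)
                ]
                t0 = 5 * tone_dur
                events.append([NoteEvent(onset=t0, duration=tone_dur,
                                         pitch_class=(tpc + k) % 12, octave=5)])
                tl = EventTimeline(events=events,
                                   target_window=(t0, t0 + tone_dur),
                                   condition_label=cond, key_label=key)
                iid = f"{cond}_k{k}_s{s}"
                ids[cond] = iid
                specs.append((iid, cond, key, tl))
            pairing.append(PairedComparison(ids["tonic"], ids["out_of_key"]))
    return StimulusSet("fedorenko09_melodic", seed,
                       _render_items(specs, PURE), pairing, PURE)


_SLEVC_CTX = [(0, MAJOR), (9, MINOR), (5, MAJOR), (7, MAJOR)]


def slevc09_chords(seed=0, n_keys=12):
    """Chord sequence ending on the tonic vs an out-of-key chord."""
    durs = [CHORD_DUR] * 4 + [TARGET_DUR]
    specs, pairing = [], []
    for k in range(n_keys):
        key = PC_NAMES[k]
        ids = {}
        for cond, r in (("inkey", 0), ("out_of_key", 6)):
            chords = [((c + k) % 12, q) for c, q in _SLEVC_CTX] + [((r + k) % 12, MAJOR)]
            tl = _seq_timeline(chords, durs, 4, cond, key)
            iid = f"{cond}_k{k}"
            ids[cond] = iid
            specs.append((iid, cond, key, tl))
        pairing.append(PairedComparison(ids["inkey"], ids["out_of_key"]))
    return StimulusSet("slevc09_chords", seed, _render_items(specs, PIANO),
                       pairing, PIANO)


PRESETS = {
    "bs86_pairs": bs86_pairs,
    "bs87_bflat": bs87_bflat,
    "bs87_nothird": bs87_nothird,
    "tb98_soa_silence": tb98_soa_silence,
    "tb98_soa_noise": tb98_soa_noise,
    "tb99_sensorycog": tb99_sensorycog,
    "bp97_tonic_subdom": bp97_tonic_subdom,
    "scrambled_2x2": scrambled_2x2,
    "scrambled_4x4": scrambled_4x4,
    "three_level_1999": three_level_1999,
    "outofkey_fmri_2003": outofkey_fmri_2003,
    "occurrence_2003_A": occurrence_2003_A,
    "occurrence_2003_B": occurrence_2003_B,
    "patel98_keys": patel98_keys,
    "leino07": leino07,
    "steinbeis06": steinbeis06,
    "koelsch07_supertonic": koelsch07_supertonic,
    "loui09_equiprobable": loui09_equiprobable,
    "loui09_8020": loui09_8020,
    "kk_probe_major": kk_probe_major,
    "kk_probe_minor": kk_probe_minor,
    "trainor_trehub94": trainor_trehub94,
    "fedorenko09_melodic": fedorenko09_melodic,
    "slevc09_chords": slevc09_chords,
}


def preset_stimuli(preset_id: str, seed: int = 0, **overrides) -> StimulusSet:
    """Build the stimulus set of a simulated paradigm.

    ``overrides`` forward to the preset builder (e.g. ``n_keys=2`` or
    ``n_pairs=24`` for quick runs).
    """
    if preset_id not in PRESETS:
        raise KeyError(
            f"unknown preset {preset_id!r}; available: "
            + ", ".join(sorted(PRESETS))
        )
    return PRESETS[preset_id](seed=seed, **overrides)


def transpose_set(s: StimulusSet, n_keys: int) -> StimulusSet:
    """Replicate a pitch-class-defined set in ``n_keys`` ascending keys."""
    if n_keys == 1:
        return s
    items, pairing = [], []
    for k in range(n_keys):
        for it in s.items:
            tl = it.timeline.transposed(k)
            tl.key_label = PC_NAMES[k] if it.key_label in ("", "C") else it.key_label
            items.append(StimulusItem(
                f"{it.item_id}_t{k}", it.condition, tl.key_label, tl,
                render_timeline(tl, s.timbre)))
        for p in s.pairing:
            pairing.append(PairedComparison(f"{p.id_a}_t{k}", f"{p.id_b}_t{k}",
                                            p.window))
    return StimulusSet(s.preset_id, s.seed, items, pairing, s.timbre,
                       window_mode=s.window_mode, reset_policy=s.reset_policy)
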