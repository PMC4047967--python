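"""Stimulus synthesis: tones, timbres, timelines, presets."""
import numpy as np
import pytest

import tonalctx as tx
from tonalctx.presets import preset_stimuli
from tonalctx.synthesis import PIANO, SHEPARD, NoteEvent, TimbreSpec, synth_note


def spectral_peaks(audio, n=12):
    spec = np.abs(np.fft.rfft(audio.samples * np.hanning(len(audio.samples))))
    freqs = np.fft.rfftfreq(len(audio.samples), 1 / audio.sr)
    order = np.argsort(spec)[::-1]
    return freqs[order[:n]], spec


def test_complex_tone_spectrum_and_normalization():
    a = tx.synth_complex_tone([600, 800, 1000], duration=0.5)
    assert a.sr == 44100
    assert np.abs(a.samples).max() == pytest.approx(0.5)
    spec = np.abs(np.fft.rfft(a.samples))
    freqs = np.fft.rfftfreq(len(a.samples), 1 / a.sr)
    for f in (600, 800, 1000):
        band = spec[np.abs(freqs - f) < 5].max()
        assert band > 100 * spec[np.abs(freqs - 300) < 5].max()


def test_single_partial_is_pure_sinusoid():
    a = tx.synth_complex_tone([440], duration=0.5)
    peaks, _ = spectral_peaks(a, n=1)
    assert peaks[0] == pytest.approx(440, abs=3)


def test_nyquist_violation_names_offender():
    with pytest.raises(ValueError, match="23000"):
        tx.synth_complex_tone([440, 23000])


def test_shepard_octave_invariance():
    lo = NoteEvent(onset=0, duration=0.5, pitch_class=0, octave=3)
    hi = NoteEvent(onset=0, duration=0.5, pitch_class=0, octave=5)
    a = synth_note(lo, SHEPARD)
    b = synth_note(hi, SHEPARD)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_piano_rolloff_and_mistuning():
    # partial k should sit at k*f0 with ~1/k amplitude before the envelope
    note = NoteEvent(onset=0, duration=1.0, frequency=220.0)
    a = synth_note(note, TimbreSpec(kind="additive_piano", decay_tau=None))
    spec = np.abs(np.fft.rfft(a.samples))
    freqs = np.fft.rfftfreq(len(a.samples), 1 / a.sr)
    amp1 = spec[np.abs(freqs - 220) < 2].max()
    amp4 = spec[np.abs(freqs - 880) < 2].max()
    assert amp4 / amp1 == pytest.approx(0.25, rel=0.05)

    # +50 cents moves every partial by the factor 2**(50/1200)
    sharp = synth_note(
        NoteEvent(onset=0, duration=1.0, frequency=220.0, mistune_cents=50),
        TimbreSpec(kind="additive_piano", decay_tau=None),
    )
    spec_s = np.abs(np.fft.rfft(sharp.samples))
    k1 = freqs[np.argmax(spec)]
    k2 = freqs[np.argmax(spec_s)]
    # spectral peaks are quantized to 1 Hz bins at 1 s analysis length
    assert k1 == pytest.approx(220.0, abs=1.0)
    assert k2 == pytest.approx(220.0 * 2 ** (50 / 1200), abs=1.0)


def test_unknown_timbre_kind_lists_valid_kinds():
    with pytest.raises(ValueError, match="shepard"):
        TimbreSpec(kind="bagpipe")


def test_render_timeline_duration_and_linearity():
    # eight 600 ms chords with a 1200 ms final chord span 5.4 s
    s = preset_stimuli("bp97_tonic_subdom", n_keys=1)
    assert s.items[0].audio.duration == pytest.approx(5.4, abs=0.01)

    note = NoteEvent(onset=0.25, duration=0.5, pitch_class=9, octave=4)
    tl1 = tx.EventTimeline(events=[[note]], target_window=(0.25, 0.75))
    tl2 = tx.EventTimeline(events=[[note, note]], target_window=(0.25, 0.75))
    a1 = tx.render_timeline(tl1, PIANO)
    a2 = tx.render_timeline(tl2, PIANO)
    # doubling a note changes nothing after peak normalization
    np.testing.assert_allclose(a1.samples, a2.samples, atol=1e-12)
    # onset padding: leading quarter second is silent
    assert np.abs(a1.samples[: int(0.24 * a1.sr)]).max() == 0

    with pytest.raises(ValueError):
        tx.render_timeline(tx.EventTimeline(events=[], target_window=(0, 1)), PIANO)


def test_bp_scale_closed_form():
    assert tx.bp_scale_freq(0, 220) == pytest.approx(220)
    assert tx.bp_scale_freq(13, 220) == pytest.approx(660)
    assert tx.bp_scale_freq(1, 220) == pytest.approx(220 * 3 ** (1 / 13))
    with pytest.raises(ValueError):
        tx.bp_scale_freq(1, -5)


def test_preset_registry_and_counts():
    with pytest.raises(KeyError, match="bs86_pairs"):
        preset_stimuli("not_a_preset")
    s = preset_stimuli("bs86_pairs")
    assert len(s.pairing) == 144
    assert len(s.items) == 288
    prime_end = s.items[0].timeline.events[0][0].duration
    assert prime_end == pytest.approx(3.0)
    assert s.items[0].timeline.target_window == (3.0, 5.0)

    leino = preset_stimuli("leino07")
    # 12 transpositions x (1 in-key + 3 Neapolitan + 3 mistuned)
    assert len(leino.items) == 84
    tl = leino.item("inkey_k0").timeline
    assert tl.duration == pytest.approx(6 * 0.6 + 1.2)


def test_preset_determinism():
    a = preset_stimuli("fedorenko09_melodic", seed=3, n_keys=1, n_sequences=2)
    b = preset_stimuli("fedorenko09_melodic", seed=3, n_keys=1, n_sequences=2)
    for ia, ib in zip(a.items, b.items):
        assert ia.item_id == ib.item_id
        np.testing.assert_array_equal(ia.audio.samples, ib.audio.samples)


def test_pairing_completeness():
    for pid, kw in [("bs86_pairs", {"n_pairs": 8}),
                    ("bp97_tonic_subdom", {"n_keys": 2}),
                    ("fedorenko09_melodic", {"n_keys": 1, "n_sequences": 3})]:
        s = preset_stimuli(pid, **kw)
        ids = {it.item_id for it in s.items}
        seen_a = set()
        for p in s.pairing:
            assert p.id_a in ids and p.id_b in ids
            seen_a.add(p.id_a)
        related = [it for it in s.items
                   if it.condition in ("related", "tonic")]
        assert len(seen_a) == len(related)


def test_transpose_set_counts_and_octave_equivalence():
    s = preset_stimuli("slevc09_chords", n_keys=1)
    t = tx.transpose_set(s, 12)
    assert len(t.items) == 12 * len(s.items)
    assert tx.transpose_set(s, 1) is s

    n = NoteEvent(onset=0, duration=1, pitch_class=4, octave=4)
    up = n.transposed(12)
    assert up.pitch_class == 4 and up.octave == 5
    assert up.freq == pytest.approx(2 * n.freq)

    bp = preset_stimuli("loui09_8020", n_sequences=4)
    with pytest.raises(ValueError):
        tx.transpose_set(bp, 2)


def test_rendered_audio_is_clip_free():
    for pid, kw in [("steinbeis06", {"n_keys": 1}),
                    ("tb98_soa_noise", {"gaps": (0.45,)})]:
        s = preset_stimuli(pid, **kw)
        for it in s.items:
            assert np.abs(it.audio.samples).max() <= 0.5 + 1e-9
            assert it.audio.sr == 44100
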