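"""Periodicity pitch: summary autocorrelation and virtual pitch."""
import numpy as np
import pytest

import tonalctx as tx
from tonalctx.periphery import ANI_RATE, AuditoryNerveImage, CENTER_FREQS
from tonalctx.pitch import LAG_MIN_S, channel_periodicity, pitch_image_series

from conftest import steady_frame


def synthetic_nerve(rows):
    """Build a minimal AuditoryNerveImage from explicit channel signals."""
    n = max(len(r) for r in rows)
    chans = np.zeros((40, n))
    for i, r in enumerate(rows):
        chans[i, : len(r)] = r
    return AuditoryNerveImage(chans, ANI_RATE, CENTER_FREQS.copy())


def test_periodic_channel_peaks_at_period_multiples():
    t = np.arange(ANI_RATE) / ANI_RATE
    nerve = synthetic_nerve([np.maximum(np.sin(2 * np.pi * 200 * t), 0)])
    acs, lags, _ = channel_periodicity(nerve)
    frame = acs[0, 40]
    lag_s = lags / ANI_RATE
    for period in (0.005, 0.010, 0.015):
        k = np.argmin(np.abs(lag_s - period))
        assert frame[k] > 0.7 * frame.max()


def test_dc_channel_autocorrelation_is_smooth_and_lagless():
    nerve = synthetic_nerve([np.ones(ANI_RATE)])
    acs, lags, _ = channel_periodicity(nerve)
    frame = acs[0, 40]
    # no preferred lag: flat within the taper-induced decay
    assert frame.std() / frame.mean() < 0.5
    assert np.argmax(frame) < 5


def test_white_noise_autocorrelation_is_small_beyond_zero_lag():
    rng = np.random.default_rng(42)
    nerve = synthetic_nerve([rng.standard_normal(ANI_RATE)])
    acs, lags, energies = channel_periodicity(nerve)
    frame = acs[0, 40]
    # lag-0 energy dwarfs any nonzero-lag structure
    assert frame.max() < 0.2 * energies[40] / 1.0


def test_window_longer_than_signal_raises():
    nerve = synthetic_nerve([np.ones(100)])
    with pytest.raises(ValueError, match="pad"):
        channel_periodicity(nerve)


def test_summary_peaks_at_5ms_for_missing_fundamental(complex_series):
    i = steady_frame(complex_series)
    frame = complex_series.frame(i)
    peak_lag = frame.lag_axis[np.argmax(frame.values)]
    assert peak_lag == pytest.approx(0.005, abs=1.5 / ANI_RATE)
    assert tx.dominant_pitch(frame) == pytest.approx(200.0, abs=4.0)


def test_silence_frames_flagged_empty():
    a = tx.AudioSignal(np.zeros(44100), 44100)
    ser = tx.pitch_series(a)
    assert ser.empty.all()
    assert not ser.values.any()
    with pytest.raises(ValueError):
        tx.dominant_pitch(ser.frame(0))


def test_single_channel_summary_equals_normalized_ac():
    t = np.arange(ANI_RATE) / ANI_RATE
    sig = np.maximum(np.sin(2 * np.pi * 150 * t), 0)
    nerve = synthetic_nerve([sig])
    per = channel_periodicity(nerve)
    ser = pitch_image_series(per)
    acs = per[0]
    expect = acs[0, 40] / acs[0, 40].sum()
    np.testing.assert_allclose(ser.values[40], expect, atol=1e-12)


def test_frame_normalization_and_count(complex_series, complex_600_800_1000):
    live = ~complex_series.empty
    sums = complex_series.values[live].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    dur = complex_600_800_1000.duration
    assert complex_series.n_frames == int(np.floor((dur - 0.064) / 0.01)) + 1
    assert complex_series.lag_axis[0] >= LAG_MIN_S - 1e-12
    assert np.all(complex_series.values >= 0)


def test_loudness_invariance_of_pitch_images(complex_600_800_1000):
    half = tx.AudioSignal(complex_600_800_1000.samples * 0.5,
                          complex_600_800_1000.sr)
    s1 = tx.pitch_series(complex_600_800_1000)
    s2 = tx.pitch_series(half)
    assert np.abs(s1.values - s2.values).max() < 1e-2


@pytest.mark.parametrize("f0,harmonics", [
    (120.0, (2, 3, 4)),
    (200.0, (3, 4, 5)),
    (330.0, (4, 5, 6)),
])
def test_virtual_pitch_oracle(f0, harmonics):
    """Any three consecutive harmonics evoke a pitch at the absent f0."""
    a = tx.synth_complex_tone([k * f0 for k in harmonics], duration=0.6)
    ser = tx.pitch_series(a)
    frame = ser.frame(steady_frame(ser, t=0.3))
    bin_hz = f0**2 / ANI_RATE  # one lag bin converted to Hz at this pitch
    assert tx.dominant_pitch(frame) == pytest.approx(f0, abs=max(2 * bin_hz, 2.0))


def test_pure_tone_dominant_pitch():
    a = tx.synth_complex_tone([440], duration=0.5)
    ser = tx.pitch_series(a)
    frame = ser.frame(steady_frame(ser, t=0.25))
    assert tx.dominant_pitch(frame) == pytest.approx(440, rel=0.02)


def test_beating_pair_low_pitch_candidate(beating_pair):
    ser = tx.pitch_series(beating_pair)
    frame = ser.frame(steady_frame(ser))
    low = frame.lag_axis > 1 / 300.0  # pitch candidates below 300 Hz
    k = np.argmax(frame.values[low])
    f = 1.0 / frame.lag_axis[low][k]
    assert f == pytest.approx(110.0, abs=6.0)
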