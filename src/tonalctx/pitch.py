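"""Periodicity pitch: framed autocorrelation per channel, summed into pitch images.

Each analysis frame yields a *pitch image*: a nonnegative vector over
autocorrelation lag, where the value at lag tau is the summed evidence for a
pitch at 1/tau.  Harmonic complexes produce a maximum at the period of the
(possibly missing) fundamental, which is how the model hears virtual pitch:
a 600/800/1000 Hz complex peaks at 5 ms, i.e. 200 Hz.

Framing runs at ``FRAME_RATE`` frames per second with a Hann window.  Each
frame is normalized to unit sum so that downstream correlation measures are
invariant to absolute stimulus level; frames with (near-)zero energy are
flagged empty and kept as all-zero rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .periphery import ANI_RATE, PHASE_LOCK_HZ, AudioSignal, AuditoryNerveImage, ani

#: analysis frame rate, frames per second (the echoic-memory sample rate)
FRAME_RATE = 100
#: analysis window length, s
WINDOW_S = 0.064
#: shortest lag carried in a pitch image, s (the phase-locking limit)
LAG_MIN_S = 1.0 / PHASE_LOCK_HZ
#: longest lag carried in a pitch image, s (~40 Hz pitch floor)
LAG_MAX_S = 0.025
#: frames whose energy is below this fraction of the loudest frame are "empty"
EMPTY_REL_THRESHOLD = 1e-7


@dataclass
class PitchImage:
    """A single frame's summary autocorrelation over lag."""

    values: np.ndarray
    lag_axis: np.ndarray  # s per bin, strictly increasing
    frame_time: float  # s, center of the analysis window

    @property
    def empty(self) -> bool:
        return not np.any(self.values)


@dataclass
class PitchImageSeries:
    """Framed pitch images sharing one lag axis.

    ``values`` is (n_frames, n_lags); ``times`` holds window-center times.
    ``empty`` marks frames with no signal energy (kept as zero rows).
    """

    values: np.ndarray
    lag_axis: np.ndarray
    sa: float = FRAME_RATE
    empty: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.empty is None:
            self.empty = ~np.any(self.values, axis=1)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sa + WINDOW_S / 2

    def frame(self, i: int) -> PitchImage:
        return PitchImage(self.values[i], self.lag_axis, float(self.times[i]))


def _frame_starts(n_samples: int, window: float, hop: float, sr: int) -> np.ndarray:
    win = int(round(window * sr))
    if win > n_samples:
        raise ValueError(
            f"analysis window ({window} s) longer than signal "
            f"({n_samples / sr:.3f} s); pad the signal or shorten the window"
        )
    n_frames = int(np.floor((n_samples / sr - window) / hop)) + 1
    starts = np.round(np.arange(n_frames) * hop * sr).astype(int)
    return starts[starts + win <= n_samples]


def channel_periodicity(
    nerve: AuditoryNerveImage,
    window: float = WINDOW_S,
    hop: float = 1.0 / FRAME_RATE,
    max_lag: float = LAG_MAX_S,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed autocorrelation of every channel.

    Returns ``(acs, lags_samples, energies)`` where ``acs`` is
    (n_channels, n_frames, n_lags) holding autocorrelation values over lags
    ``LAG_MIN_S .. max_lag`` (negative values clipped to zero -- pitch evidence
    is nonnegative by construction), and ``energies`` is (n_frames,) with the
    lag-0 autocorrelation summed over channels (frame energy).
    """
    if window < max_lag:
        raise ValueError("window must be at least as long as the longest lag")
    sr = nerve.sr_ani
    starts = _frame_starts(nerve.channels.shape[1], window, hop, sr)
    win = int(round(window * sr))
    lag_lo = int(np.ceil(LAG_MIN_S * sr))
    lag_hi = int(np.floor(max_lag * sr))
    lags = np.arange(lag_lo, lag_hi + 1)
    nfft = int(2 ** np.ceil(np.log2(win + lag_hi + 1)))
    taper = np.hanning(win)

    acs = np.empty((nerve.channels.shape[0], len(starts), len(lags)))
    energies = np.zeros(len(starts), dtype=np.float64)
    for ch in range(nerve.channels.shape[0]):
        segs = np.lib.stride_tricks.sliding_window_view(nerve.channels[ch], win)[starts]
        segs = segs * taper
        spec = np.fft.rfft(segs, nfft, axis=-1)
        ac = np.fft.irfft((spec * spec.conj()).real, nfft, axis=-1)
        energies += ac[:, 0].astype(np.float64)
        acs[ch] = np.maximum(ac[:, lag_lo : lag_hi + 1], 0.0)
    return acs, lags, energies


def pitch_image_series(
    per_channel: tuple[np.ndarray, np.ndarray, np.ndarray],
    sr: int = ANI_RATE,
    sa: float = FRAME_RATE,
) -> PitchImageSeries:
    """Sum channel autocorrelations and normalize each frame to unit sum.

    Frames whose energy falls below ``EMPTY_REL_THRESHOLD`` of the loudest
    frame are flagged empty and zeroed: correlation against them is
    undefined (silence has no pitch content).
    """
    acs, lags, energies = per_channel
    summary = acs.sum(axis=0, dtype=np.float64)
    sums = summary.sum(axis=1)
    floor = EMPTY_REL_THRESHOLD * (energies.max() if len(energies) else 0.0)
    empty = (energies <= floor) | (sums <= 0)
    out = np.zeros_like(summary)
    live = ~empty
    out[live] = summary[live] / sums[live, None]
    return PitchImageSeries(
        values=out,
        lag_axis=lags / sr,
        sa=sa,
        empty=empty,
    )


def pitch_series(audio: AudioSignal, **kwargs) -> PitchImageSeries:
    """Convenience composition: periphery + periodicity analysis."""
    return pitch_image_series(channel_periodicity(ani(audio), **kwargs))


def dominant_pitch(pi: PitchImage) -> float:
    """Frequency (Hz) of the global maximum lag, with parabolic interpolation."""
    if pi.empty:
        raise ValueError("pitch image is empty; no dominant pitch")
    v = np.asarray(pi.values, dtype=np.float64)
    k = int(np.argmax(v))
    lag = pi.lag_axis[k]
    if 0 < k < len(v) - 1:
        denom = v[k - 1] - 2 * v[k] + v[k + 1]
        if denom < 0:
            delta = 0.5 * (v[k - 1] - v[k + 1]) / denom
            step = pi.lag_axis[1] - pi.lag_axis[0]
            lag = lag + delta * step
    return 1.0 / lag
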