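"""Peripheral auditory model: audio -> simulated auditory-nerve firing probabilities.

The stage chain is the classical one for temporal models of pitch:

1. outer/middle ear          -- low-pass filter (zero phase, so onsets stay put)
2. cochlear filterbank       -- 40 gammatone channels, ERB-spaced 80 Hz .. 5 kHz
3. inner hair cells          -- half-wave rectification, compressive nonlinearity,
                                low-pass at the phase-locking limit (1250 Hz)

The output is an :class:`AuditoryNerveImage`: per-channel nonnegative firing
probability envelopes, decimated to ``ANI_RATE`` for the downstream
autocorrelation stage.  The contract of the stage is behavioral rather than
coefficient-level: two tones more than a critical band apart are resolved in
separate channels, two tones within a critical band interfere and beat at
their frequency difference, and fine structure above the phase-lock limit is
removed from the channel envelopes.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.signal as sig

N_CHANNELS = 40
CF_MIN = 80.0
CF_MAX = 5000.0
#: sample rate of the internal band signals (audio is resampled to this)
MODEL_RATE = 22050
#: sample rate of the auditory nerve image (after hair-cell decimation)
ANI_RATE = 11025
#: phase-locking limit of the hair-cell stage, Hz
PHASE_LOCK_HZ = 1250.0
#: outer/middle ear low-pass cutoff, Hz
OME_CUTOFF_HZ = 4000.0
#: exponent of the compressive hair-cell nonlinearity
COMPRESSION_EXPONENT = 0.3


@dataclass
class AudioSignal:
    """A sampled waveform (dimensionless amplitude, nominal full scale +-1)."""

    samples: np.ndarray
    sr: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sr <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sr


@dataclass
class AuditoryNerveImage:
    """Per-channel firing-probability envelopes at rate ``sr_ani``."""

    channels: np.ndarray  # (N_CHANNELS, n) nonnegative
    sr_ani: int
    center_freqs: np.ndarray  # (N_CHANNELS,) Hz, ascending

    def __post_init__(self) -> None:
        if self.channels.shape[0] != len(self.center_freqs):
            raise ValueError("channel count does not match center frequencies")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center frequencies must be strictly increasing")


def erb_space(lo: float = CF_MIN, hi: float = CF_MAX, n: int = N_CHANNELS) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale (Glasberg & Moore)."""
    ear_q, min_bw = 9.26449, 24.7
    pts = np.linspace(np.log(lo / ear_q + min_bw), np.log(hi / ear_q + min_bw), n)
    return (np.exp(pts) - min_bw) * ear_q


CENTER_FREQS = erb_space()


@lru_cache(maxsize=8)
def _ome_coeffs(sr: int):
    return sig.butter(2, OME_CUTOFF_HZ, fs=sr)


@lru_cache(maxsize=8)
def _gammatone_bank(sr: int):
    return tuple(sig.gammatone(cf, "iir", fs=sr) for cf in CENTER_FREQS)


@lru_cache(maxsize=8)
def _phaselock_coeffs(sr: int):
    return sig.butter(4, PHASE_LOCK_HZ, fs=sr)


def _to_model_rate(a: AudioSignal) -> np.ndarray:
    x = a.samples.astype(np.float32)
    if a.sr == MODEL_RATE:
        return x
    from math import gcd

    g = gcd(a.sr, MODEL_RATE)
    return sig.resample_poly(x, MODEL_RATE // g, a.sr // g).astype(np.float32)


def outer_middle_ear(a: AudioSignal) -> AudioSignal:
    """Low-pass filter simulating outer/middle-ear transmission (zero phase)."""
    b, bb = _ome_coeffs(a.sr)
    if len(a.samples) == 0:
        return AudioSignal(a.samples.copy(), a.sr)
    y = sig.filtfilt(b, bb, a.samples)
    return AudioSignal(y, a.sr)


def cochlear_filterbank(a: AudioSignal) -> np.ndarray:
    """Split a signal into 40 gammatone band signals (rows ordered by CF).

    The input is resampled internally to ``MODEL_RATE``; all band signals are
    returned at that rate.
    """
    x = _to_model_rate(a)
    bands = np.empty((N_CHANNELS, len(x)), dtype=np.float32)
    for i, (b, aa) in enumerate(_gammatone_bank(MODEL_RATE)):
        bands[i] = sig.lfilter(b, aa, x)
    return bands


def hair_cell(bands: np.ndarray, sr: int = MODEL_RATE) -> AuditoryNerveImage:
    """Half-wave rectification, power-law compression, phase-lock low-pass.

    The rectified-compressed band signals are low-passed at ``PHASE_LOCK_HZ``
    (4th-order Butterworth), clipped to be nonnegative, and decimated to
    ``ANI_RATE``.
    """
    rect = np.maximum(np.asarray(bands, dtype=np.float64), 0.0)
    comp = np.power(rect, COMPRESSION_EXPONENT)
    b, a = _phaselock_coeffs(sr)
    env = sig.lfilter(b, a, comp, axis=-1)
    env = np.maximum(env, 0.0)
    step = sr // ANI_RATE
    if sr % ANI_RATE:
        raise ValueError("band rate must be an integer multiple of the ANI rate")
    return AuditoryNerveImage(
        channels=env[:, ::step],
        sr_ani=ANI_RATE,
        center_freqs=CENTER_FREQS.copy(),
    )


def ani(a: AudioSignal) -> AuditoryNerveImage:
    """Full peripheral chain: outer/middle ear -> filterbank -> hair cells."""
    return hair_cell(cochlear_filterbank(outer_middle_ear(a)))
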