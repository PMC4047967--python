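"""Echoic memory: leaky integration of pitch images at two time scales.

The store is a first-order leaky integrator over frames,

    p(n) = p_in(n) + p(n-1) * 2**(-1 / (sa * T)),

where ``sa`` is the frame rate and ``T`` the *half-decay* time: an impulse
decays to half its value after exactly T seconds.  Run with a short T the
output is a Local Pitch Image series (the immediate percept); with a long T,
a Global Pitch Image series (the accumulated pitch context).  These two free
parameters are the model's entire parameter space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sig

from .pitch import FRAME_RATE, PitchImageSeries

#: default half-decay times, s (local, global)
DEFAULT_T_LOCAL = 0.1
DEFAULT_T_GLOBAL = 1.5


@dataclass(frozen=True)
class EchoicParams:
    """Half-decay times (s) of the local and global stores, and frame rate."""

    t_local: float = DEFAULT_T_LOCAL
    t_global: float = DEFAULT_T_GLOBAL
    sa: float = FRAME_RATE

    def __post_init__(self) -> None:
        if self.t_local <= 0 or self.t_global <= 0:
            raise ValueError("half-decay times must be positive")
        if self.sa <= 0:
            raise ValueError("frame rate must be positive")


@dataclass
class IntegratedImages:
    """Local and global integrated pitch-image series (shared framing)."""

    lpi: PitchImageSeries
    gpi: PitchImageSeries
    params: EchoicParams
    #: final frame of each store, for carrying state across continuous runs
    carry_state: tuple[np.ndarray, np.ndarray] | None = None


def decay_factor(T: float, sa: float) -> float:
    """Per-frame retention 2**(-1/(sa*T)) of a store with half-decay T."""
    if T <= 0:
        raise ValueError("half-decay time must be positive")
    return float(2.0 ** (-1.0 / (sa * T)))


def leaky_integrate(
    pi: PitchImageSeries,
    T: float,
    initial_state: np.ndarray | None = None,
) -> PitchImageSeries:
    """Apply the leaky-integration recurrence along the frame axis.

    ``initial_state`` is the store content just before the first frame
    (all-zero by default); it decays under the same law while new input
    accumulates.
    """
    alpha = decay_factor(T, pi.sa)
    x = np.asarray(pi.values, dtype=np.float64)
    if initial_state is not None:
        zi = (alpha * np.asarray(initial_state, dtype=np.float64))[None, :]
        y, _ = sig.lfilter([1.0], [1.0, -alpha], x, axis=0, zi=zi)
    else:
        y = sig.lfilter([1.0], [1.0, -alpha], x, axis=0)
    out = PitchImageSeries(values=y, lag_axis=pi.lag_axis, sa=pi.sa,
                           empty=np.zeros(pi.n_frames, dtype=bool))
    # integrated frames inherit "emptiness" only while the store holds nothing
    out.empty = ~np.any(y, axis=1)
    return out


def local_global(
    pi: PitchImageSeries,
    params: EchoicParams | None = None,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
) -> IntegratedImages:
    """Integrate a pitch-image series at the local and global time scales."""
    p = params or EchoicParams()
    l0, g0 = initial if initial is not None else (None, None)
    lpi = leaky_integrate(pi, p.t_local, l0)
    gpi = leaky_integrate(pi, p.t_global, g0)
    carry = (lpi.values[-1].copy(), gpi.values[-1].copy()) if pi.n_frames else None
    return IntegratedImages(lpi=lpi, gpi=gpi, params=p, carry_state=carry)
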