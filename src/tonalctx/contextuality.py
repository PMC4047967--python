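"""Tonal contextuality: running similarity between local and global pitch images.

TC(t) is the Pearson correlation, over lag bins, between the local (short
half-decay) and global (long half-decay) integrated pitch images at frame t.
High TC means the momentary pitch percept resembles the accumulated pitch
context, i.e. low perceived tonal tension.  Statistics are carried out on
Fisher's z = atanh(r), which is approximately normal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .memory import IntegratedImages

#: |r| is clipped to 1 - R_CLIP before the z-transform
R_CLIP = 1e-7
_VAR_EPS = 1e-18


@dataclass
class TCSeries:
    """Running tonal-contextuality index.

    ``r`` is NaN where undefined (zero-variance or empty frames); ``defined``
    marks usable frames.  ``z`` carries the Fisher transform of ``r``.
    """

    times: np.ndarray
    r: np.ndarray
    z: np.ndarray
    defined: np.ndarray


@dataclass
class TargetWindow:
    """Analysis window for a target event, in absolute stimulus time (s)."""

    start: float
    end: float
    mode: str = "event_span"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed its start")


def fisher_z(r) -> np.ndarray | float:
    """Fisher's z-transform atanh(r), with |r| clipped to 1 - 1e-7."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr[np.isfinite(arr)]) > 1):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -1 + R_CLIP, 1 - R_CLIP))
    out = np.where(np.isnan(arr), np.nan, out)
    return float(out) if np.isscalar(r) else out


def tc_series(img: IntegratedImages) -> TCSeries:
    """Per-frame Pearson correlation between local and global pitch images."""
    lv = np.asarray(img.lpi.values, dtype=np.float64)
    gv = np.asarray(img.gpi.values, dtype=np.float64)
    if lv.shape != gv.shape:
        raise ValueError("local and global series are not aligned")
    lc = lv - lv.mean(axis=1, keepdims=True)
    gc = gv - gv.mean(axis=1, keepdims=True)
    lvar = (lc * lc).sum(axis=1)
    gvar = (gc * gc).sum(axis=1)
    # scale-relative variance floor: constant frames have no correlation
    lfloor = _VAR_EPS * max(lvar.max(initial=0.0), 1e-300)
    gfloor = _VAR_EPS * max(gvar.max(initial=0.0), 1e-300)
    defined = (lvar > lfloor) & (gvar > gfloor)
    defined &= ~img.lpi.empty & ~img.gpi.empty
    r = np.full(lv.shape[0], np.nan)
    num = (lc * gc).sum(axis=1)
    r[defined] = num[defined] / np.sqrt(lvar[defined] * gvar[defined])
    r = np.clip(r, -1.0, 1.0)
    z = np.where(defined, np.arctanh(np.clip(r, -1 + R_CLIP, 1 - R_CLIP)), np.nan)
    return TCSeries(times=img.lpi.times, r=r, z=z, defined=defined)


def tc_target(s: TCSeries, w: TargetWindow, item: str = "") -> tuple[float, float, int]:
    """Mean z (and mean r) over defined frames with time in [start, end).

    Returns ``(mean_z, mean_r, n_defined)``; raises if no defined frame falls
    inside the window.
    """
    in_win = (s.times >= w.start) & (s.times < w.end) & s.defined
    n = int(in_win.sum())
    if n == 0:
        name = f" for item {item!r}" if item else ""
        raise ValueError(
            f"no defined TC frames in window [{w.start:.3f}, {w.end:.3f}) s{name}"
        )
    return float(s.z[in_win].mean()), float(s.r[in_win].mean()), n
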