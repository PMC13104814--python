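"""Slow/fast decomposition of raw fluorescence.

Raw fluorescence factorizes as F(t) = Fslow(t) * (1 + dFF(t)): the slow
baseline Fslow is the 20th percentile of F in a 5-minute window centered
at each frame (tracking pO2-related baseline drift on the minutes
timescale), and the fast component dFF = F/Fslow - 1 carries the
behavior-locked calcium transients.  The reconstruction is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import FluorescenceSet

__all__ = ["Decomposition", "decompose", "rolling_percentile"]


@dataclass
class Decomposition:
    fslow: np.ndarray  # cells x time, > 0
    dff: np.ndarray  # cells x time
    window_s: float
    percentile: float

    def reconstruct(self) -> np.ndarray:
        return self.fslow * (1.0 + self.dff)


def rolling_percentile(
    x: np.ndarray, window: int, percentile: float, edge: str = "shrink"
) -> np.ndarray:
    """Centered rolling percentile of a 1-D trace.

    The window at index i covers [i - (window-1)//2, i + window//2].  With
    ``edge="shrink"`` the window is clipped to the trace; with
    ``edge="reflect"`` the trace is reflect-padded first.  Percentiles use
    linear interpolation between order statistics.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    window = min(window, n)
    lo_half = (window - 1) // 2
    hi_half = window // 2
    if edge == "reflect":
        padded = np.pad(x, (lo_half, hi_half), mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(padded, window)
        return np.percentile(win, percentile, axis=1)
    if edge != "shrink":
        raise ValueError(f"unknown edge mode {edge!r}")
    out = np.empty(n)
    if n >= window:
        win = np.lib.stride_tricks.sliding_window_view(x, window)
        out[lo_half : n - hi_half] = np.percentile(win, percentile, axis=1)
    for i in range(min(lo_half, n)):
        out[i] = np.percentile(x[: i + hi_half + 1], percentile)
    for i in range(max(n - hi_half, 0), n):
        out[i] = np.percentile(x[max(i - lo_half, 0) :], percentile)
    return out


def decompose(
    fluo: FluorescenceSet | np.ndarray,
    window_s: float = 300.0,
    percentile: float = 20.0,
    frame_rate: float | None = None,
    edge: str = "shrink",
) -> Decomposition:
    """Split F (cells x time) into Fslow and dFF.

    Raises on any non-positive fluorescence value, naming the offending
    cell.  Fslow is floored at 1e-6 * median(F) to keep the division
    benign on pathological inputs.
    """
    if isinstance(fluo, FluorescenceSet):
        F = fluo.F
        frame_rate = fluo.frame_rate
    else:
        F = np.asarray(fluo, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for bare arrays")
    if F.ndim == 1:
        F = F[None, :]
    bad = np.flatnonzero((F <= 0).any(axis=1))
    if bad.size:
        raise ValueError(f"non-positive fluorescence in cell(s) {bad.tolist()}")
    window = int(round(window_s * frame_rate))
    if window < 3:
        raise ValueError("baseline window must cover at least 3 frames")

    fslow = np.empty_like(F, dtype=float)
    for i in range(F.shape[0]):
        fslow[i] = rolling_percentile(F[i], window, percentile, edge=edge)
    fslow = np.maximum(fslow, 1e-6 * np.median(F))
    dff = F / fslow - 1.0
    return Decomposition(fslow=fslow, dff=dff, window_s=window_s,
                         percentile=percentile)
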