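"""Shared smoothing / differentiation helpers for angle-channel signals."""

from __future__ import annotations

import numpy as np


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge shrinkage (same length as input)."""
    x = np.asarray(x, dtype=float)
    if window <= 1 or x.size < 2:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def window_samples(window_s: float, t: np.ndarray) -> int:
    """Odd sample count spanning ``window_s`` at the series' median rate."""
    if len(t) < 2 or window_s <= 0:
        return 1
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        return 1
    n = max(1, int(round(window_s / dt)))
    return n if n % 2 == 1 else n + 1


def smoothed_speed(t: np.ndarray, channels: list[np.ndarray], window_s: float) -> np.ndarray:
    """Norm of the smoothed per-channel time derivatives.

    Each channel is smoothed with a centred moving average before
    differentiation and the derivative smoothed again; the Euclidean norm
    across channels is returned.  Smoothing before the norm matters: the norm
    of raw finite-difference noise has a positive mean that averaging after
    the fact cannot remove.
    """
    t = np.asarray(t, dtype=float)
    n = window_samples(window_s, t)
    total = np.zeros_like(t)
    for ch in channels:
        d = np.gradient(moving_average(ch, n), t)
        total += moving_average(d, n) ** 2
    return np.sqrt(total)
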