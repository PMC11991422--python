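"""Movement-episode detection on calibrated angle series.

A session stream, once re-zeroed against its neutral calibration, is a
sequence of excursions from neutral and back.  Episodes are delimited with
speed hysteresis: an episode opens when the smoothed angular speed exceeds a
start threshold and closes when the speed has dropped below a lower stop
threshold *and* every channel is back inside the neutral band.  Each episode
is labelled by its dominant channel and the sign of that channel's extremum,
per the clinical sign convention — never by its position in the protocol, so
a mislabelled protocol slot shows up in the order report instead of being
silently corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _filters
from .kinematics import CHANNELS, AngleSeries
from .simulator import PROTOCOL_ORDER, label_for

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Hysteresis and labelling thresholds (all exposed to config files)."""

    speed_start_deg_s: float = 10.0
    speed_stop_deg_s: float = 5.0
    smooth_window_s: float = 0.25
    neutral_band_deg: float = 3.0
    min_episode_s: float = 0.3


@dataclass(frozen=True)
class MovementEpisode:
    """One labelled excursion from neutral and back."""

    label: str
    start_s: float
    end_s: float
    primary_channel: str
    peak_signed_deg: float
    peak_time_s: float


@dataclass
class OrderFlag:
    kind: str  # "missing" | "extra" | "out_of_order"
    label: str
    detail: str = ""


@dataclass
class OrderReport:
    flags: list[OrderFlag] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def angular_speed(series: AngleSeries, smooth_window_s: float = 0.25) -> np.ndarray:
    """Smoothed overall angular speed in deg/s, same length as the series.

    Euclidean norm of the three channel derivatives; each channel is passed
    through a centred moving average before and after differentiation so the
    speed track stays usable under sensor noise.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 samples")
    return _filters.smoothed_speed(
        series.t, [series.channel(ch) for ch in CHANNELS], smooth_window_s
    )


def _dominant_channel(
    series: AngleSeries, i0: int, i1: int, smooth_n: int = 1
) -> tuple[str, float, int]:
    """Channel with the largest |extremum| in [i0, i1]; protocol-order tie-break.

    Extrema are taken on the smoothed channels — the raw maximum of a noisy
    hold is biased upward by the noise, the smoothed one is not.
    """
    best = None
    for ch in CHANNELS:
        seg = _filters.moving_average(series.channel(ch), smooth_n)[i0 : i1 + 1]
        j = int(np.argmax(np.abs(seg)))
        peak = float(seg[j])
        cand = (abs(peak), ch, peak, i0 + j)
        if best is None or cand[0] > best[0] + 1e-12:
            best = cand
        elif abs(cand[0] - best[0]) <= 1e-12 and best is not None:
            # exact tie: prefer the channel whose label comes first in protocol order
            lab_new = label_for(ch, peak) if peak != 0 else None
            lab_old = label_for(best[1], best[2]) if best[2] != 0 else None
            if lab_new and lab_old and (
                PROTOCOL_ORDER.index(lab_new) < PROTOCOL_ORDER.index(lab_old)
            ):
                logger.info("dominant-channel tie broken by protocol order: %s", lab_new)
                best = cand
    assert best is not None
    return best[1], best[2], best[3]


def segment_episodes(
    series: AngleSeries, config: SegmentationConfig | None = None
) -> list[MovementEpisode]:
    """Detect labelled movement episodes in a calibrated angle series.

    A series that never leaves neutral yields an empty list.  Episodes
    shorter than ``min_episode_s`` (noise blips) are discarded and logged.
    An episode still open at the end of the series is closed at the last
    sample.
    """
    cfg = config or SegmentationConfig()
    if len(series) < 2:
        return []
    speed = angular_speed(series, cfg.smooth_window_s)
    in_band = np.ones(len(series), dtype=bool)
    for ch in CHANNELS:
        in_band &= np.abs(series.channel(ch)) <= cfg.neutral_band_deg

    episodes: list[MovementEpisode] = []
    open_i: int | None = None
    for i in range(len(series)):
        if open_i is None:
            if speed[i] > cfg.speed_start_deg_s:
                open_i = i
        else:
            if speed[i] < cfg.speed_stop_deg_s and in_band[i]:
                episodes.extend(_close(series, open_i, i, cfg))
                open_i = None
    if open_i is not None:
        episodes.extend(_close(series, open_i, len(series) - 1, cfg))
    return episodes


def _close(series: AngleSeries, i0: int, i1: int, cfg: SegmentationConfig):
    start_s = float(series.t[i0])
    end_s = float(series.t[i1])
    if end_s - start_s < cfg.min_episode_s:
        logger.info(
            "discarding %.3fs blip at t=%.2fs (< %.2fs minimum)",
            end_s - start_s, start_s, cfg.min_episode_s,
        )
        return []
    smooth_n = _filters.window_samples(cfg.smooth_window_s, series.t)
    ch, peak, peak_i = _dominant_channel(series, i0, i1, smooth_n)
    if peak == 0.0:
        logger.info("discarding zero-amplitude episode at t=%.2fs", start_s)
        return []
    return [
        MovementEpisode(
            label=label_for(ch, peak),
            start_s=start_s,
            end_s=end_s,
            primary_channel=ch,
            peak_signed_deg=peak,
            peak_time_s=float(series.t[peak_i]),
        )
    ]


def validate_protocol_order(episodes: list[MovementEpisode]) -> OrderReport:
    """Check detected episodes against the six-movement protocol template.

    Flags missing movements, extras (duplicates), and movements present but
    out of protocol order (minimal set, via longest increasing subsequence).
    """
    report = OrderReport()
    labels = [e.label for e in episodes]
    seen: set[str] = set()
    firsts: list[str] = []
    for lab in labels:
        if lab in seen:
            report.flags.append(OrderFlag("extra", lab, "duplicate episode"))
        else:
            seen.add(lab)
            firsts.append(lab)
    for lab in PROTOCOL_ORDER:
        if lab not in seen:
            report.flags.append(OrderFlag("missing", lab, "movement not detected"))
    idx = [PROTOCOL_ORDER.index(lab) for lab in firsts]
    keep = _lis_membership(idx)
    for lab, ok in zip(firsts, keep):
        if not ok:
            report.flags.append(
                OrderFlag("out_of_order", lab, "out of protocol sequence")
            )
    return report


def _lis_membership(idx: list[int]) -> list[bool]:
    """Boolean mask of one longest increasing subsequence of ``idx``."""
    n = len(idx)
    if n == 0:
        return []
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if idx[j] < idx[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = int(np.argmax(best_len))
    mask = [False] * n
    while end != -1:
        mask[end] = True
        end = prev[end]
    return mask
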