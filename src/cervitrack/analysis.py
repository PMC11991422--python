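"""Clinical outputs: signed ROM, durations, asymmetry, compensations, summaries.

ROM here is what a goniometer reads — the signed maximal excursion of the
episode's primary channel from neutral, not a net displacement.  A light
centred smoothing (default 0.25 s) is applied before taking the extremum so
that the reading reflects the held posture rather than the upward-biased
maximum of raw sensor noise; on noise-free data the plateau value is exact.

Normative ranges are configuration, never hard-coded: published norm tables
differ by source and age band, so they are supplied by the user (YAML/JSON
mapping movement -> limit in degrees) and only used to raise exceedance
flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _filters
from .kinematics import CHANNELS, AngleSeries
from .segmentation import MovementEpisode
from .simulator import LABEL_CHANNEL_SIGN, PROTOCOL_ORDER

#: movement label -> anatomical plane
PLANE_OF = {
    "flexion": "sagittal",
    "extension": "sagittal",
    "left_lateral": "frontal",
    "right_lateral": "frontal",
    "left_rotation": "transverse",
    "right_rotation": "transverse",
}


class SignConventionWarning(UserWarning):
    """A ROM value's sign contradicts its movement label's convention."""


@dataclass(frozen=True)
class RomResult:
    """Signed range of motion and duration of one movement episode."""

    label: str
    rom_signed_deg: float
    duration_s: float


@dataclass
class NormativeRanges:
    """Physiological ROM limits in degrees per movement (user configuration)."""

    limits: dict[str, float]

    def __post_init__(self):
        for lab, v in self.limits.items():
            if lab not in LABEL_CHANNEL_SIGN:
                raise ValueError(f"unknown movement {lab!r} in normative ranges")
            if v <= 0:
                raise ValueError(f"normative limit for {lab} must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "NormativeRanges":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("normative-range file must be a mapping")
        return cls({str(k): float(v) for k, v in data.items()})


@dataclass
class CompensationReport:
    """Off-plane co-movements of one episode.

    ``off_plane`` maps each non-primary channel to its signed extremum within
    the episode window and the coupling ratio (off-plane peak / primary
    peak, signed).  Flags record co-movements beyond the neutral band and
    primary ROM beyond the configured physiological norm.
    """

    label: str
    primary_peak_deg: float
    off_plane: dict[str, tuple[float, float]]
    flags: list[str] = field(default_factory=list)


@dataclass
class MovementStats:
    min_deg: float
    max_deg: float
    mean_deg: float
    mean_duration_s: float

    def __post_init__(self):
        if not (self.min_deg <= self.mean_deg + 1e-9 and
                self.mean_deg <= self.max_deg + 1e-9):
            raise ValueError("min <= mean <= max violated")


@dataclass
class SessionSummary:
    """Per-movement min/max/mean aggregation across one or more sessions."""

    movements: dict[str, MovementStats]
    total_duration_s: float
    n_sessions: int


def _window_slice(episode: MovementEpisode, series: AngleSeries) -> np.ndarray:
    mask = (series.t >= episode.start_s) & (series.t <= episode.end_s)
    if not mask.any():
        raise ValueError(
            f"episode window [{episode.start_s}, {episode.end_s}]s is empty"
        )
    return mask


def _signed_extremum(values: np.ndarray) -> float:
    return float(values[int(np.argmax(np.abs(values)))])


def compute_rom(
    episode: MovementEpisode,
    series: AngleSeries,
    smooth_window_s: float = 0.25,
) -> RomResult:
    """Signed ROM of the episode's primary channel and the episode duration."""
    mask = _window_slice(episode, series)
    n = _filters.window_samples(smooth_window_s, series.t)
    smoothed = _filters.moving_average(series.channel(episode.primary_channel), n)
    return RomResult(
        label=episode.label,
        rom_signed_deg=_signed_extremum(smoothed[mask]),
        duration_s=episode.end_s - episode.start_s,
    )


def duration_asymmetry(left: RomResult, right: RomResult) -> tuple[float, float]:
    """Left-minus-right differences for one plane's movement pair.

    Returns ``(duration_diff_s, rom_diff_deg)`` where the ROM difference is
    taken on magnitudes (|left| - |right|).
    """
    if PLANE_OF[left.label] != PLANE_OF[right.label] or left.label == right.label:
        raise ValueError(
            f"{left.label} and {right.label} are not a movement pair of one plane"
        )
    return (
        left.duration_s - right.duration_s,
        abs(left.rom_signed_deg) - abs(right.rom_signed_deg),
    )


def detect_compensations(
    episode: MovementEpisode,
    series: AngleSeries,
    norms: Optional[NormativeRanges] = None,
    neutral_band_deg: float = 5.0,
    smooth_window_s: float = 0.25,
) -> CompensationReport:
    """Off-plane co-movement peaks, coupling ratios and exceedance flags.

    A co-movement flag is raised for an off-plane channel whose |peak|
    exceeds ``neutral_band_deg`` (small co-movements are physiological); a
    norm-exceedance flag when the primary |ROM| exceeds the configured limit
    for the movement.
    """
    mask = _window_slice(episode, series)
    n = _filters.window_samples(smooth_window_s, series.t)
    primary = _signed_extremum(
        _filters.moving_average(series.channel(episode.primary_channel), n)[mask]
    )
    off: dict[str, tuple[float, float]] = {}
    flags: list[str] = []
    for ch in CHANNELS:
        if ch == episode.primary_channel:
            continue
        peak = _signed_extremum(_filters.moving_average(series.channel(ch), n)[mask])
        ratio = peak / primary if primary != 0 else float("nan")
        off[ch] = (peak, ratio)
        if abs(peak) > neutral_band_deg:
            flags.append(f"co_movement:{ch}")
    if norms is not None and episode.label in norms.limits:
        if abs(primary) > norms.limits[episode.label]:
            flags.append("norm_exceeded")
    return CompensationReport(
        label=episode.label, primary_peak_deg=primary, off_plane=off, flags=flags
    )


def summarize_sessions(
    sessions: Sequence[Sequence[RomResult]],
    procedure_durations_s: Optional[Sequence[float]] = None,
) -> SessionSummary:
    """Table-shaped aggregation: per-movement min/max/mean signed ROM,
    mean movement duration, and mean total procedure time.

    If per-session procedure durations are not supplied, each session's total
    is taken as the sum of its movement durations.  A warning is emitted if
    one movement label mixes ROM signs across sessions (a sign-convention
    breach worth inspecting, not an error).
    """
    if not sessions:
        raise ValueError("need at least one session")
    by_label: dict[str, list[RomResult]] = {}
    for sess in sessions:
        for r in sess:
            by_label.setdefault(r.label, []).append(r)
    movements: dict[str, MovementStats] = {}
    for lab, results in by_label.items():
        roms = np.array([r.rom_signed_deg for r in results])
        expected = LABEL_CHANNEL_SIGN[lab][1]
        if np.any(np.sign(roms[roms != 0]) != expected):
            warnings.warn(
                f"{lab}: ROM sign contradicts the clinical convention",
                SignConventionWarning,
                stacklevel=2,
            )
        movements[lab] = MovementStats(
            min_deg=float(roms.min()),
            max_deg=float(roms.max()),
            mean_deg=float(roms.mean()),
            mean_duration_s=float(np.mean([r.duration_s for r in results])),
        )
    if procedure_durations_s is None:
        totals = [sum(r.duration_s for r in sess) for sess in sessions]
    else:
        totals = list(procedure_durations_s)
    return SessionSummary(
        movements=movements,
        total_duration_s=float(np.mean(totals)),
        n_sessions=len(sessions),
    )


@dataclass(frozen=True)
class MovementDelta:
    rom_delta_deg: float
    duration_delta_s: float


def compare_sessions(a: SessionSummary, b: SessionSummary) -> dict[str, MovementDelta]:
    """Per-movement change from summary ``a`` to ``b`` (b minus a)."""
    if set(a.movements) != set(b.movements):
        missing = set(a.movements) ^ set(b.movements)
        raise ValueError(f"movement sets differ: {sorted(missing)}")
    return {
        lab: MovementDelta(
            rom_delta_deg=b.movements[lab].mean_deg - a.movements[lab].mean_deg,
            duration_delta_s=(
                b.movements[lab].mean_duration_s - a.movements[lab].mean_duration_s
            ),
        )
        for lab in sorted(a.movements, key=lambda l: (
            PROTOCOL_ORDER.index(l) if l in PROTOCOL_ORDER else len(PROTOCOL_ORDER)
        ))
    }
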