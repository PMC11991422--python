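"""End-to-end session analysis: calibrate → decompose → segment → report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import analysis, io_report, kinematics, segmentation
from .analysis import NormativeRanges
from .io_report import EpisodeReport, ReportBundle, SessionMeta
from .kinematics import AngleSeries, PoseStream
from .segmentation import MovementEpisode, SegmentationConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the full analysis chain, all surfaced in the CLI config file."""

    calibration_window_s: float = 1.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    rom_smooth_window_s: float = 0.25
    compensation_band_deg: float = 5.0


@dataclass
class SessionAnalysis:
    """Intermediate and final products of one analysed session."""

    series: AngleSeries
    episodes: list[MovementEpisode]
    bundle: ReportBundle


def analyze_stream(
    stream: PoseStream,
    meta: Optional[SessionMeta] = None,
    norms: Optional[NormativeRanges] = None,
    config: Optional[PipelineConfig] = None,
) -> SessionAnalysis:
    """Run the whole chain on an in-memory stream."""
    cfg = config or PipelineConfig()
    meta = meta or SessionMeta()
    calib = kinematics.estimate_neutral(stream, window_s=cfg.calibration_window_s)
    series = kinematics.angles_timeseries(stream, calib)
    episodes = segmentation.segment_episodes(series, cfg.segmentation)
    logger.info(
        "analysed %d samples at %.1f Hz: %d episodes (thresholds %.1f/%.1f deg/s)",
        len(stream), stream.nominal_rate, len(episodes),
        cfg.segmentation.speed_start_deg_s, cfg.segmentation.speed_stop_deg_s,
    )
    order = segmentation.validate_protocol_order(episodes)
    reports = []
    roms = []
    for ep in episodes:
        rom = analysis.compute_rom(ep, series, smooth_window_s=cfg.rom_smooth_window_s)
        comp = analysis.detect_compensations(
            ep, series, norms=norms,
            neutral_band_deg=cfg.compensation_band_deg,
            smooth_window_s=cfg.rom_smooth_window_s,
        )
        roms.append(rom)
        reports.append(EpisodeReport(rom=rom, compensation=comp,
                                     start_s=ep.start_s, end_s=ep.end_s))
    if roms:
        procedure = episodes[-1].end_s - stream.t[0]
        summary = analysis.summarize_sessions([roms], [procedure])
    else:
        summary = analysis.SessionSummary(movements={}, total_duration_s=0.0,
                                          n_sessions=1)
    bundle = ReportBundle(
        meta=meta,
        episodes=reports,
        summary=summary,
        order_flags=[f"{f.kind}:{f.label}" for f in order.flags],
        config={
            "calibration_window_s": cfg.calibration_window_s,
            "speed_start_deg_s": cfg.segmentation.speed_start_deg_s,
            "speed_stop_deg_s": cfg.segmentation.speed_stop_deg_s,
            "smooth_window_s": cfg.segmentation.smooth_window_s,
            "neutral_band_deg": cfg.segmentation.neutral_band_deg,
            "min_episode_s": cfg.segmentation.min_episode_s,
            "rom_smooth_window_s": cfg.rom_smooth_window_s,
            "compensation_band_deg": cfg.compensation_band_deg,
            "seed": meta.seed,
        },
    )
    return SessionAnalysis(series=series, episodes=episodes, bundle=bundle)


def analyze_session_dir(
    session_dir: str | Path,
    norms: Optional[NormativeRanges] = None,
    config: Optional[PipelineConfig] = None,
) -> SessionAnalysis:
    """Read a session directory and analyse it."""
    stream, meta = io_report.read_session(session_dir)
    return analyze_stream(stream, meta=meta, norms=norms, config=config)
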