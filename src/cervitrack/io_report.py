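"""Session file formats, report serialization, trajectory plot.

A recorded session lives in two local files (the desk-scale stand-in for a
cloud time-series store): a samples CSV ``t_s,qw,qx,qy,qz[,px,py,pz]`` —
quaternion scalar-first, declared in the header to avoid the w-last/w-first
ambiguity across ecosystems — and a metadata JSON (user, session, device,
rate, seed).  Floats are written with 17 significant digits so the
write→read round trip reproduces the stream bit-for-bit and every downstream
analysis result is identical before and after serialization.

The trajectory plot reproduces the in-app posturographic view: two fixed
orthogonal reference lines crossing at the calibrated neutral origin and the
moving head trace drawn over them.  The 90-degree grid geometry is a
property of the plot *model* (line directions), asserted there — pixel
output is presentation only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import CompensationReport, RomResult, SessionSummary
from .kinematics import CHANNELS, AngleSeries, PoseStream
from .segmentation import MovementEpisode

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["t_s", "qw", "qx", "qy", "qz"]
POSITION_COLUMNS = ["px", "py", "pz"]
FLOAT_FMT = "%.17g"

CHANNEL_AXIS_LABEL = {
    "flexion_extension": "flexion (+) / extension (−) [deg]",
    "lateral_flexion": "left (+) / right (−) lateral flexion [deg]",
    "rotation": "right (+) / left (−) rotation [deg]",
}


class SessionFormatError(ValueError):
    """Malformed session file (missing column, unparseable value)."""


class SessionValidationError(ValueError):
    """Well-formed file whose content violates a stream invariant."""


@dataclass
class SessionMeta:
    user_id: str = "anonymous"
    session_id: str = "session-0"
    device: str = "simulated"
    rate_hz: float = 60.0
    seed: Optional[int] = None
    quaternion_order: str = "wxyz"


def write_session(stream: PoseStream, meta: SessionMeta, out_dir: str | Path) -> dict[str, Path]:
    """Write a session to ``<out_dir>/samples.csv`` + ``<out_dir>/meta.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = {"t_s": stream.t}
    for i, c in enumerate(["qw", "qx", "qy", "qz"]):
        cols[c] = stream.quat_wxyz[:, i]
    if stream.pos is not None:
        for i, c in enumerate(POSITION_COLUMNS):
            cols[c] = stream.pos[:, i]
    samples_path = out_dir / "samples.csv"
    pd.DataFrame(cols).to_csv(samples_path, index=False, float_format=FLOAT_FMT)
    meta_path = out_dir / "meta.json"
    meta_obj = {
        "user_id": meta.user_id,
        "session_id": meta.session_id,
        "device": meta.device,
        "rate_hz": meta.rate_hz,
        "seed": meta.seed,
        "quaternion_order": meta.quaternion_order,
    }
    meta_path.write_text(json.dumps(meta_obj, indent=2, sort_keys=True) + "\n")
    return {"samples": samples_path, "meta": meta_path}


def read_session(session_dir: str | Path) -> tuple[PoseStream, SessionMeta]:
    """Read a session directory back into a stream + metadata.

    Raises :class:`SessionFormatError` (with the offending line where it can
    be located) for structural problems and :class:`SessionValidationError`
    for invariant breaches such as non-monotonic timestamps.
    """
    session_dir = Path(session_dir)
    samples_path = session_dir / "samples.csv"
    meta_path = session_dir / "meta.json"
    if not samples_path.exists():
        raise SessionFormatError(f"missing samples file {samples_path}")
    try:
        df = pd.read_csv(samples_path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise SessionFormatError(f"cannot parse {samples_path}: {exc}") from exc
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(
            f"{samples_path}: missing required column(s) {missing}"
        )
    for c in df.columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise SessionFormatError(
                f"{samples_path}: non-numeric value in column {c!r} at line {line}"
            )
        df[c] = coerced
    if df[SAMPLE_COLUMNS].isna().any().any():
        raise SessionFormatError(f"{samples_path}: missing values in required columns")

    meta = SessionMeta()
    if meta_path.exists():
        obj = json.loads(meta_path.read_text())
        meta = SessionMeta(
            user_id=obj.get("user_id", "anonymous"),
            session_id=obj.get("session_id", "session-0"),
            device=obj.get("device", "unknown"),
            rate_hz=float(obj.get("rate_hz", 60.0)),
            seed=obj.get("seed"),
            quaternion_order=obj.get("quaternion_order", "wxyz"),
        )
    if meta.quaternion_order != "wxyz":
        raise SessionFormatError(
            f"unsupported quaternion order {meta.quaternion_order!r}"
        )
    t = df["t_s"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise SessionValidationError(
            f"{samples_path}: timestamps not strictly increasing at row {i + 2}"
        )
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy()
    pos = None
    if all(c in df.columns for c in POSITION_COLUMNS):
        pos = df[POSITION_COLUMNS].to_numpy()
    try:
        stream = PoseStream(t=t, quat_wxyz=quat, pos=pos, nominal_rate=meta.rate_hz)
    except ValueError as exc:
        raise SessionValidationError(f"{samples_path}: {exc}") from exc
    return stream, meta


# --------------------------------------------------------------------------
# trajectory plot


@dataclass
class ReferenceLine:
    """One fixed reference line of the posturographic grid through the origin."""

    direction: tuple[float, float]
    color: str = "gold"


@dataclass
class TrajectoryPlotModel:
    """Geometry behind the rendered plot; the 90-degree grid lives here."""

    x_channel: str
    y_channel: str
    reference_lines: list[ReferenceLine]
    trace_x: np.ndarray
    trace_y: np.ndarray
    episode_spans: list[tuple[float, float, str]]

    def reference_angle_deg(self) -> float:
        (a, b), (c, d) = (l.direction for l in self.reference_lines[:2])
        dot = a * c + b * d
        na = math.hypot(a, b)
        nb = math.hypot(c, d)
        return math.degrees(math.acos(max(-1.0, min(1.0, dot / (na * nb)))))


def build_trajectory_model(
    series: AngleSeries,
    episodes: Sequence[MovementEpisode] = (),
    x_channel: str = "rotation",
    y_channel: str = "flexion_extension",
) -> TrajectoryPlotModel:
    if len(series) == 0:
        raise ValueError("empty series")
    return TrajectoryPlotModel(
        x_channel=x_channel,
        y_channel=y_channel,
        reference_lines=[
            ReferenceLine(direction=(1.0, 0.0)),
            ReferenceLine(direction=(0.0, 1.0)),
        ],
        trace_x=series.channel(x_channel),
        trace_y=series.channel(y_channel),
        episode_spans=[(e.start_s, e.end_s, e.label) for e in episodes],
    )


def render_trajectory_plot(
    series: AngleSeries,
    episodes: Sequence[MovementEpisode] = (),
    path: str | Path = "trajectory.png",
    x_channel: str = "rotation",
    y_channel: str = "flexion_extension",
) -> tuple[Path, TrajectoryPlotModel]:
    """Render the posturographic grid + head trace and a time-series panel.

    Left panel: the fixed orthogonal (yellow) reference lines crossing at
    the neutral origin with the measured (red) head trace over them.  Right
    panel: the three angle channels over time with detected episode spans
    shaded.  Returns the output path and the plot model.
    """
    from matplotlib.figure import Figure

    model = build_trajectory_model(series, episodes, x_channel, y_channel)
    fig = Figure(figsize=(11, 5))
    ax_grid, ax_time = fig.subplots(1, 2)

    lim = max(10.0, 1.1 * max(np.abs(model.trace_x).max(), np.abs(model.trace_y).max()))
    for line in model.reference_lines:
        dx, dy = line.direction
        ax_grid.plot([-lim * dx, lim * dx], [-lim * dy, lim * dy],
                     color=line.color, lw=2, zorder=1)
    ax_grid.plot(model.trace_x, model.trace_y, color="red", lw=1, zorder=2)
    ax_grid.set_xlim(-lim, lim)
    ax_grid.set_ylim(-lim, lim)
    ax_grid.set_aspect("equal")
    ax_grid.set_xlabel(CHANNEL_AXIS_LABEL[x_channel])
    ax_grid.set_ylabel(CHANNEL_AXIS_LABEL[y_channel])
    ax_grid.set_title("head trace on posturographic grid")

    for ch in CHANNELS:
        ax_time.plot(series.t, series.channel(ch), label=CHANNEL_AXIS_LABEL[ch], lw=1)
    for start, end, label in model.episode_spans:
        ax_time.axvspan(start, end, color="0.85", zorder=0)
    ax_time.set_xlabel("time [s]")
    ax_time.set_ylabel("angle [deg]")
    ax_time.legend(fontsize=7, loc="upper right")
    ax_time.set_title("angle channels and detected episodes")

    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    return path, model


# --------------------------------------------------------------------------
# report bundle


@dataclass
class EpisodeReport:
    rom: RomResult
    compensation: CompensationReport
    start_s: float
    end_s: float


@dataclass
class ReportBundle:
    """Everything one analysed session produces, ready for export."""

    meta: SessionMeta
    episodes: list[EpisodeReport]
    summary: SessionSummary
    order_flags: list[str] = field(default_factory=list)
    plot_paths: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def _round6(x: float) -> float:
    return round(float(x), 6)


def _bundle_to_obj(bundle: ReportBundle) -> dict:
    labels = [e.rom.label for e in bundle.episodes]
    if len(labels) != len(set(labels)):
        # duplicates are legal (repeated movements) but each episode object
        # must appear exactly once; identity is (label, start)
        keys = [(e.rom.label, e.start_s) for e in bundle.episodes]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate episode in bundle")
    return {
        "meta": {
            "user_id": bundle.meta.user_id,
            "session_id": bundle.meta.session_id,
            "device": bundle.meta.device,
            "rate_hz": _round6(bundle.meta.rate_hz),
            "seed": bundle.meta.seed,
        },
        "episodes": [
            {
                "label": e.rom.label,
                "start_s": _round6(e.start_s),
                "end_s": _round6(e.end_s),
                "rom_signed_deg": _round6(e.rom.rom_signed_deg),
                "duration_s": _round6(e.rom.duration_s),
                "compensation": {
                    "off_plane": {
                        ch: {"peak_signed_deg": _round6(p), "coupling_ratio": _round6(r)}
                        for ch, (p, r) in sorted(e.compensation.off_plane.items())
                    },
                    "flags": list(e.compensation.flags),
                },
            }
            for e in bundle.episodes
        ],
        "summary": {
            "movements": {
                lab: {
                    "min_deg": _round6(s.min_deg),
                    "max_deg": _round6(s.max_deg),
                    "mean_deg": _round6(s.mean_deg),
                    "mean_duration_s": _round6(s.mean_duration_s),
                }
                for lab, s in sorted(bundle.summary.movements.items())
            },
            "total_duration_s": _round6(bundle.summary.total_duration_s),
            "n_sessions": bundle.summary.n_sessions,
        },
        "order_flags": list(bundle.order_flags),
        "plots": sorted(bundle.plot_paths),
        "config": bundle.config,
    }


_REQUIRED_TOP = {"meta", "episodes", "summary", "order_flags", "plots", "config"}


def _validate_report_obj(obj: dict) -> None:
    missing = _REQUIRED_TOP - set(obj)
    if missing:
        raise ValueError(f"report schema violation: missing {sorted(missing)}")
    for e in obj["episodes"]:
        for key in ("label", "start_s", "end_s", "rom_signed_deg", "duration_s",
                    "compensation"):
            if key not in e:
                raise ValueError(f"report schema violation: episode missing {key!r}")


def summary_to_frame(summary: SessionSummary) -> pd.DataFrame:
    from .simulator import PROTOCOL_ORDER

    rows = []
    order = {lab: i for i, lab in enumerate(PROTOCOL_ORDER)}
    for lab in sorted(summary.movements, key=lambda l: order.get(l, len(order))):
        s = summary.movements[lab]
        rows.append(
            {
                "movement": lab,
                "min_deg": _round6(s.min_deg),
                "max_deg": _round6(s.max_deg),
                "mean_deg": _round6(s.mean_deg),
                "mean_duration_s": _round6(s.mean_duration_s),
            }
        )
    return pd.DataFrame(
        rows, columns=["movement", "min_deg", "max_deg", "mean_deg", "mean_duration_s"]
    )


def export_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write ``report.json`` + ``summary.csv``; deterministic byte-for-byte.

    The JSON is schema-validated before anything is written; keys are sorted
    and floats fixed to six decimals so re-exporting an identical bundle
    yields identical files.  An empty episode list produces a header-only
    summary CSV with a logged warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obj = _bundle_to_obj(bundle)
    _validate_report_obj(obj)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    df = summary_to_frame(bundle.summary)
    if df.empty:
        logger.warning("no episodes detected; summary CSV is header only")
    summary_path = out_dir / "summary.csv"
    df.to_csv(summary_path, index=False, float_format="%.6f")
    return {"report": report_path, "summary": summary_path}
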