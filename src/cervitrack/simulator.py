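"""Synthetic head-pose streams: examination sessions and rig-validation trials.

Two generators share one trajectory model:

* :func:`simulate_protocol` — a full six-movement cervical examination
  (flexion, extension, left side bend, right side bend, left rotation,
  right rotation, in that fixed order), with optional cross-plane
  compensation couplings and per-channel Gaussian angle noise;
* :func:`simulate_rig_trial` — the desk digital twin of a skull model on a
  goniometer stand performing one pure single-plane excursion, noise free.

Voluntary movement is modelled with the standard minimum-jerk polynomial
(zero velocity and acceleration at both endpoints); clean angle channels are
built first, noise added in angle space (so sigma stays interpretable in
degrees), and each sample is then composed into an orientation quaternion.
Both generators return the ground truth used by the recovery tests: episode
windows, true signed peaks, injected couplings, and — for rig trials — the
goniometer reading, i.e. the true peak rounded to the instrument's
whole-degree resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import kinematics
from .kinematics import CHANNELS, PoseStream

#: protocol order of the examination, fixed by the test procedure
PROTOCOL_ORDER = (
    "flexion",
    "extension",
    "left_lateral",
    "right_lateral",
    "left_rotation",
    "right_rotation",
)

#: movement label -> (primary angle channel, clinical sign of the excursion)
LABEL_CHANNEL_SIGN: dict[str, tuple[str, int]] = {
    "flexion": ("flexion_extension", +1),
    "extension": ("flexion_extension", -1),
    "left_lateral": ("lateral_flexion", +1),
    "right_lateral": ("lateral_flexion", -1),
    "left_rotation": ("rotation", -1),
    "right_rotation": ("rotation", +1),
}


def label_for(channel: str, sign: float) -> str:
    """Movement label of a signed excursion on an anatomical channel."""
    for label, (ch, s) in LABEL_CHANNEL_SIGN.items():
        if ch == channel and s == (1 if sign >= 0 else -1):
            return label
    raise KeyError(channel)


@dataclass
class MovementSpec:
    """One commanded maximal movement of the protocol.

    ``coupling`` maps an off-plane channel name to a signed dimensionless
    ratio c: the off-plane channel receives c times the signed primary
    profile (a compensatory co-movement).
    """

    label: str
    peak_deg: float
    rise_s: float = 1.5
    hold_s: float = 1.0
    coupling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABEL_CHANNEL_SIGN:
            raise ValueError(f"unknown movement label {self.label!r}")
        if self.peak_deg < 0:
            raise ValueError("peak_deg is an unsigned magnitude")
        if self.rise_s <= 0:
            raise ValueError("rise_s must be positive")
        primary = LABEL_CHANNEL_SIGN[self.label][0]
        for ch, c in self.coupling.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown coupling channel {ch!r}")
            if ch == primary:
                raise ValueError("coupling must target an off-plane channel")
            if abs(c) >= 1:
                raise ValueError("|coupling ratio| must be < 1")

    @property
    def signed_peak_deg(self) -> float:
        return LABEL_CHANNEL_SIGN[self.label][1] * self.peak_deg

    @property
    def primary_channel(self) -> str:
        return LABEL_CHANNEL_SIGN[self.label][0]


#: mid-range healthy adult peaks, degrees (configurable fixtures)
DEFAULT_PEAKS = {
    "flexion": 45.0,
    "extension": 55.0,
    "left_lateral": 35.0,
    "right_lateral": 35.0,
    "left_rotation": 65.0,
    "right_rotation": 65.0,
}


@dataclass
class ProtocolConfig:
    """Conditions of one simulated examination session."""

    movements: list[MovementSpec]
    rest_s: float = 2.0
    lead_s: float = 1.5
    noise_sd_deg: float = 0.5
    rate_hz: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        labels = [m.label for m in self.movements]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate movement labels")


def default_protocol(
    seed: int = 0,
    noise_sd_deg: float = 0.5,
    peaks: Optional[dict[str, float]] = None,
    couplings: Optional[dict[str, dict[str, float]]] = None,
    rise_s: float = 1.5,
    hold_s: float = 1.0,
    rest_s: float = 2.0,
    rate_hz: float = 60.0,
) -> ProtocolConfig:
    """Six-movement protocol in the canonical order with default peaks."""
    peaks = {**DEFAULT_PEAKS, **(peaks or {})}
    couplings = couplings or {}
    movements = [
        MovementSpec(
            label=lab,
            peak_deg=peaks[lab],
            rise_s=rise_s,
            hold_s=hold_s,
            coupling=dict(couplings.get(lab, {})),
        )
        for lab in PROTOCOL_ORDER
    ]
    return ProtocolConfig(
        movements=movements,
        rest_s=rest_s,
        noise_sd_deg=noise_sd_deg,
        rate_hz=rate_hz,
        seed=seed,
    )


@dataclass
class RigTrialSpec:
    """One single-plane excursion of the skull-model validation rig."""

    plane: str
    angle_deg: float
    rate_hz: float = 60.0
    settle_s: float = 1.5
    rise_s: float = 1.0
    hold_s: float = 2.0

    def __post_init__(self):
        if self.plane not in CHANNELS:
            raise ValueError(f"plane must be one of {CHANNELS}")


@dataclass
class GroundTruthEpisode:
    label: str
    start_s: float
    end_s: float
    peak_signed_deg: float
    couplings: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Simulator annotations consumed by the recovery tests and reports."""

    episodes: list[GroundTruthEpisode]
    rate_hz: float
    noise_sd_deg: float = 0.0
    seed: Optional[int] = None
    goniometer_reading_deg: Optional[int] = None

    def to_json(self) -> str:
        obj = {
            "rate_hz": self.rate_hz,
            "noise_sd_deg": self.noise_sd_deg,
            "seed": self.seed,
            "goniometer_reading_deg": self.goniometer_reading_deg,
            "episodes": [
                {
                    "label": e.label,
                    "start_s": round(e.start_s, 6),
                    "end_s": round(e.end_s, 6),
                    "peak_signed_deg": round(e.peak_signed_deg, 6),
                    "couplings": e.couplings,
                }
                for e in self.episodes
            ],
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            episodes=[
                GroundTruthEpisode(
                    label=e["label"],
                    start_s=e["start_s"],
                    end_s=e["end_s"],
                    peak_signed_deg=e["peak_signed_deg"],
                    couplings=dict(e.get("couplings", {})),
                )
                for e in obj["episodes"]
            ],
            rate_hz=obj["rate_hz"],
            noise_sd_deg=obj.get("noise_sd_deg", 0.0),
            seed=obj.get("seed"),
            goniometer_reading_deg=obj.get("goniometer_reading_deg"),
        )


def minimum_jerk_profile(t, rise_s: float, peak: float):
    """Minimum-jerk angle profile: 0 at t=0, ``peak`` at t>=rise_s.

    theta(tau) = peak * (10 tau^3 - 15 tau^4 + 6 tau^5), tau = t/rise_s
    clipped to [0, 1]; velocity and acceleration vanish at both endpoints.
    """
    tau = np.clip(np.asarray(t, dtype=float) / rise_s, 0.0, 1.0)
    out = peak * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return float(out) if np.isscalar(t) else out


def _excursion_profile(t_rel: np.ndarray, rise_s: float, hold_s: float, peak: float) -> np.ndarray:
    """Rise to peak, hold, mirrored minimum-jerk return to zero."""
    up = minimum_jerk_profile(t_rel, rise_s, peak)
    down_start = rise_s + hold_s
    down = minimum_jerk_profile(t_rel - down_start, rise_s, peak)
    return up - down


def _compose_stream(
    t: np.ndarray,
    channels: dict[str, np.ndarray],
    rate_hz: float,
) -> PoseStream:
    rot = kinematics._compose_rotation(
        channels["flexion_extension"],
        channels["lateral_flexion"],
        channels["rotation"],
    )
    xyzw = rot.as_quat()
    wxyz = xyzw[:, [3, 0, 1, 2]]
    return PoseStream(t=t, quat_wxyz=wxyz, nominal_rate=rate_hz)


def simulate_protocol(cfg: ProtocolConfig) -> tuple[PoseStream, GroundTruth]:
    """Synthesize a full examination session stream with ground truth.

    The head holds neutral for ``lead_s`` (the calibration window), then
    performs each movement — minimum-jerk rise to the signed peak, hold,
    mirrored return — followed by ``rest_s`` of neutral. Coupled off-plane
    channels receive their ratio times the signed primary profile. Gaussian
    noise of sd ``noise_sd_deg`` is added per channel before composing
    quaternions. Deterministic for a fixed seed.
    """
    dt = 1.0 / cfg.rate_hz
    spans = []
    t_cursor = cfg.lead_s
    for m in cfg.movements:
        dur = 2 * m.rise_s + m.hold_s
        spans.append((t_cursor, t_cursor + dur, m))
        t_cursor += dur + cfg.rest_s
    total = t_cursor
    n = int(round(total * cfg.rate_hz))
    t = np.arange(n) * dt

    channels = {ch: np.zeros(n) for ch in CHANNELS}
    episodes = []
    for start, end, m in spans:
        profile = _excursion_profile(t - start, m.rise_s, m.hold_s, m.signed_peak_deg)
        profile[(t < start) | (t > end)] = 0.0
        channels[m.primary_channel] += profile
        for ch, c in m.coupling.items():
            channels[ch] += c * profile
        episodes.append(
            GroundTruthEpisode(
                label=m.label,
                start_s=start,
                end_s=end,
                peak_signed_deg=m.signed_peak_deg,
                couplings=dict(m.coupling),
            )
        )

    if cfg.noise_sd_deg > 0:
        rng = np.random.default_rng(cfg.seed)
        for ch in CHANNELS:
            channels[ch] = channels[ch] + rng.normal(0.0, cfg.noise_sd_deg, n)

    stream = _compose_stream(t, channels, cfg.rate_hz)
    gt = GroundTruth(
        episodes=episodes,
        rate_hz=cfg.rate_hz,
        noise_sd_deg=cfg.noise_sd_deg,
        seed=cfg.seed,
    )
    return stream, gt


def simulate_rig_trial(spec: RigTrialSpec) -> tuple[PoseStream, GroundTruth]:
    """Digital twin of one goniometer rig trial.

    Noise-free: neutral settle, smooth rise to exactly ``angle_deg`` on the
    commanded plane, then hold.  The ground-truth goniometer reading is the
    commanded angle rounded to the instrument's whole-degree scale.
    """
    dt = 1.0 / spec.rate_hz
    total = spec.settle_s + spec.rise_s + spec.hold_s
    n = int(round(total * spec.rate_hz))
    t = np.arange(n) * dt
    channels = {ch: np.zeros(n) for ch in CHANNELS}
    channels[spec.plane] = minimum_jerk_profile(
        t - spec.settle_s, spec.rise_s, spec.angle_deg
    )
    stream = _compose_stream(t, channels, spec.rate_hz)
    label = label_for(spec.plane, spec.angle_deg) if spec.angle_deg != 0 else "neutral"
    gt = GroundTruth(
        episodes=[
            GroundTruthEpisode(
                label=label,
                start_s=spec.settle_s,
                end_s=total,
                peak_signed_deg=spec.angle_deg,
            )
        ],
        rate_hz=spec.rate_hz,
        goniometer_reading_deg=int(round(spec.angle_deg)),
    )
    return stream, gt
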