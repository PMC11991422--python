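"""Quaternion head-pose algebra and anatomical cervical angle decomposition.

Orientation frame (right-handed): X = subject's right, Y = up, Z = posterior.
An orientation quaternion maps head-frame vectors into the world frame.  A
calibrated relative orientation is decomposed intrinsically as
yaw(Y) -> pitch(X) -> roll(Z), which places each anatomical movement on a
single Euler axis and puts gimbal lock at |flexion-extension| = 90 deg, well
outside cervical range of motion.

Clinical sign convention (applied after Euler extraction):

* flexion-extension: flexion (chin down) positive, extension negative;
* lateral flexion (side bend): left positive, right negative;
* rotation: right positive, left negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.spatial.transform import Rotation

UNIT_NORM_TOL = 1e-6
GIMBAL_WARN_DEG = 85.0
#: order of the angle channels everywhere in the package
CHANNELS = ("flexion_extension", "lateral_flexion", "rotation")


class NonUnitQuaternionWarning(UserWarning):
    """Input quaternion was renormalised beyond the unit-norm tolerance."""


class GimbalProximityWarning(UserWarning):
    """|flexion-extension| approached the 90 deg Euler singularity."""


class RateMismatchWarning(UserWarning):
    """Observed sampling interval deviates >10% from the nominal rate."""


class CalibrationError(ValueError):
    """Head motion detected inside the neutral-calibration window."""


@dataclass(frozen=True)
class Quaternion:
    """Unit quaternion ``w + xi + yj + zk``; q and -q are the same orientation."""

    w: float
    x: float
    y: float
    z: float

    @property
    def norm(self) -> float:
        return float(np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2))

    def normalized(self) -> "Quaternion":
        """Unit-norm canonical form with the first nonzero component >= 0."""
        n = self.norm
        if n == 0.0:
            raise ValueError("zero quaternion has no orientation")
        comp = np.array([self.w, self.x, self.y, self.z]) / n
        for c in comp:
            if c != 0.0:
                if c < 0.0:
                    comp = -comp
                break
        return Quaternion(*comp)

    def as_rotation(self) -> Rotation:
        return Rotation.from_quat([self.x, self.y, self.z, self.w])

    @classmethod
    def from_rotation(cls, r: Rotation) -> "Quaternion":
        x, y, z, w = r.as_quat()
        return cls(w, x, y, z).normalized()

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float) -> "Quaternion":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return cls.from_rotation(
            Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
        )


@dataclass(frozen=True)
class PoseSample:
    """One timestamped head pose; position is optional and unused by analysis."""

    t: float
    q: Quaternion
    p: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t}")


@dataclass
class PoseStream:
    """Timestamped unit-quaternion orientations at a nominal rate (default 60 Hz).

    Arrays are primary storage: ``t`` (seconds, strictly increasing) and
    ``quat_wxyz`` with one row per sample in w,x,y,z order.
    """

    t: np.ndarray
    quat_wxyz: np.ndarray
    pos: Optional[np.ndarray] = None
    nominal_rate: float = 60.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.quat_wxyz = np.asarray(self.quat_wxyz, dtype=float)
        if self.quat_wxyz.ndim != 2 or self.quat_wxyz.shape[1] != 4:
            raise ValueError("quat_wxyz must be (N, 4)")
        if len(self.t) != len(self.quat_wxyz):
            raise ValueError("t and quat_wxyz lengths differ")
        if len(self.t) == 0:
            raise ValueError("empty pose stream")
        if np.any(self.t < 0):
            raise ValueError("negative timestamps")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(
                    f"timestamps not strictly increasing at sample {i + 1}"
                )
            med = float(np.median(dt))
            if abs(med - 1.0 / self.nominal_rate) > 0.1 / self.nominal_rate:
                warnings.warn(
                    f"median interval {med:.4f}s deviates >10% from nominal "
                    f"{1.0 / self.nominal_rate:.4f}s",
                    RateMismatchWarning,
                    stacklevel=2,
                )
        norms = np.linalg.norm(self.quat_wxyz, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero quaternion in stream")
        # renormalise only rows that need it, so an already-unit stream
        # round-trips bit-for-bit through serialization
        off = np.abs(norms - 1.0) > 1e-12
        if np.any(off):
            self.quat_wxyz = self.quat_wxyz.astype(float, copy=True)
            self.quat_wxyz[off] /= norms[off, None]

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def samples(self) -> Iterator[PoseSample]:
        for i in range(len(self.t)):
            w, x, y, z = self.quat_wxyz[i]
            p = None if self.pos is None else self.pos[i]
            yield PoseSample(float(self.t[i]), Quaternion(w, x, y, z), p)

    def rotations(self) -> Rotation:
        xyzw = self.quat_wxyz[:, [1, 2, 3, 0]]
        return Rotation.from_quat(xyzw)


@dataclass(frozen=True)
class NeutralCalibration:
    """Reference (neutral) head orientation everything is measured against."""

    q_ref: Quaternion

    def __post_init__(self):
        object.__setattr__(self, "q_ref", self.q_ref.normalized())


@dataclass(frozen=True)
class AnatomicalAngles:
    """Signed cervical angles in degrees, each in (-180, 180]."""

    flexion_extension: float
    lateral_flexion: float
    rotation: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.flexion_extension, self.lateral_flexion, self.rotation)


@dataclass
class AngleSeries:
    """Per-sample anatomical angles aligned with the source stream's clock."""

    t: np.ndarray
    flexion_extension: np.ndarray
    lateral_flexion: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        lengths = {len(self.t), len(self.flexion_extension),
                   len(self.lateral_flexion), len(self.rotation)}
        if len(lengths) != 1:
            raise ValueError("channel lengths differ")

    def __len__(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_s": self.t, **{name: getattr(self, name) for name in CHANNELS}}
        )


def _check_unit(q: Quaternion, name: str) -> Quaternion:
    n = q.norm
    if n == 0.0:
        raise ValueError(f"{name} is the zero quaternion")
    if abs(n - 1.0) > UNIT_NORM_TOL:
        warnings.warn(
            f"{name} norm {n:.3g} off unity; renormalising",
            NonUnitQuaternionWarning,
            stacklevel=3,
        )
    return q.normalized()


def relative_orientation(q: Quaternion, calib: NeutralCalibration) -> Quaternion:
    """Head orientation re-zeroed against the calibrated neutral.

    Returns ``q_ref^-1 * q`` — identity when the head sits exactly at the
    calibrated starting position.
    """
    q = _check_unit(q, "q")
    rel = calib.q_ref.as_rotation().inv() * q.as_rotation()
    return Quaternion.from_rotation(rel)


def _decompose_rotation(r: Rotation) -> np.ndarray:
    """(fe, lat, rot) in degrees from a Rotation (vectorised).

    Intrinsic Y-X-Z Euler extraction, then the clinical sign map: the
    internal pitch about +X is extension-positive and the yaw about +Y is
    left-rotation-positive, so both flip sign.
    """
    ypr = r.as_euler("YXZ", degrees=True)
    ypr = np.atleast_2d(ypr)
    fe = -ypr[:, 1]
    lat = ypr[:, 2]
    rot = -ypr[:, 0]
    return np.column_stack([fe, lat, rot])


def decompose_angles(q_rel: Quaternion) -> AnatomicalAngles:
    """Signed anatomical angles of a calibrated relative orientation."""
    q_rel = _check_unit(q_rel, "q_rel")
    fe, lat, rot = _decompose_rotation(q_rel.as_rotation())[0]
    if abs(fe) > GIMBAL_WARN_DEG:
        warnings.warn(
            f"flexion-extension {fe:.1f} deg is within 5 deg of gimbal lock",
            GimbalProximityWarning,
            stacklevel=2,
        )
    return AnatomicalAngles(float(fe), float(lat), float(rot))


def _compose_rotation(fe, lat, rot) -> Rotation:
    fe = np.asarray(fe, dtype=float)
    euler = np.stack(
        [-np.asarray(rot, float), -fe, np.asarray(lat, float)], axis=-1
    )
    return Rotation.from_euler("YXZ", euler, degrees=True)


def compose_from_angles(a: AnatomicalAngles) -> Quaternion:
    """Orientation whose decomposition is exactly ``a`` (inverse of
    :func:`decompose_angles` away from gimbal lock)."""
    if not all(np.isfinite(a.as_tuple())):
        raise ValueError("angles must be finite")
    return Quaternion.from_rotation(
        _compose_rotation(a.flexion_extension, a.lateral_flexion, a.rotation)
    )


def angles_from_stream_quats(quat_wxyz: np.ndarray, calib: NeutralCalibration) -> np.ndarray:
    """Vectorised (N, 3) decomposition of a quaternion block against a neutral."""
    xyzw = np.asarray(quat_wxyz)[:, [1, 2, 3, 0]]
    rel = calib.q_ref.as_rotation().inv() * Rotation.from_quat(xyzw)
    return _decompose_rotation(rel)


def estimate_neutral(
    stream: PoseStream,
    window_s: float = 1.0,
    still_threshold_deg_s: float = 10.0,
    smooth_window_s: float = 0.25,
) -> NeutralCalibration:
    """Neutral orientation from the initial still window of a session.

    The first ``window_s`` seconds are checked for stillness (smoothed
    angular speed below ``still_threshold_deg_s``); the hemisphere-aligned
    component mean of the window's quaternions is then normalised.

    Raises
    ------
    CalibrationError
        If the head moves inside the window, naming the offending span.
    """
    from . import _filters

    if stream.duration_s < window_s:
        raise CalibrationError(
            f"stream covers {stream.duration_s:.2f}s < window {window_s:.2f}s"
        )
    mask = stream.t <= stream.t[0] + window_s
    t = stream.t[mask]
    quats = stream.quat_wxyz[mask]
    first = Quaternion(*quats[0]).normalized()
    angles = angles_from_stream_quats(quats, NeutralCalibration(first))
    speed = _filters.smoothed_speed(t, [angles[:, i] for i in range(3)], smooth_window_s)
    if np.any(speed > still_threshold_deg_s):
        bad = np.flatnonzero(speed > still_threshold_deg_s)
        raise CalibrationError(
            "motion during neutral calibration: smoothed angular speed "
            f"{speed[bad].max():.1f} deg/s over t = "
            f"[{t[bad[0]]:.2f}, {t[bad[-1]]:.2f}]s exceeds "
            f"{still_threshold_deg_s:g} deg/s"
        )
    # hemisphere-align every sample to the first before averaging components
    signs = np.where(quats @ quats[0] < 0, -1.0, 1.0)
    mean = (quats * signs[:, None]).mean(axis=0)
    return NeutralCalibration(Quaternion(*mean).normalized())


def angles_timeseries(stream: PoseStream, calib: NeutralCalibration) -> AngleSeries:
    """Decompose every sample of a stream against the neutral calibration."""
    angles = angles_from_stream_quats(stream.quat_wxyz, calib)
    near_lock = np.flatnonzero(np.abs(angles[:, 0]) > GIMBAL_WARN_DEG)
    if near_lock.size:
        warnings.warn(
            f"{near_lock.size} samples near gimbal lock "
            f"(first at index {near_lock[0]})",
            GimbalProximityWarning,
            stacklevel=2,
        )
    return AngleSeries(
        t=stream.t.copy(),
        flexion_extension=angles[:, 0],
        lateral_flexion=angles[:, 1],
        rotation=angles[:, 2],
    )
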