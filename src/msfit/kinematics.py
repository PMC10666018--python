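"""Joint angles and their time derivatives from skeleton sequences.

Angles are 3D interior angles at a center joint between the bone vectors to a
proximal and a distal joint, in degrees within [0, 180]. Velocity and
acceleration come from finite differences on the actual timestamps (central on
interior points, one-sided at the edges), which keeps them meaningful when
frames are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, ParameterError, ValidationError
from .preprocessing import Series
from .skeleton import JOINT_INDEX, Frame, SkeletonSequence

_ZERO_BONE = 1e-12


@dataclass(frozen=True)
class JointTriple:
    """Proximal–center–distal joint triple defining one anatomical angle."""

    proximal: str
    center: str
    distal: str

    def __post_init__(self) -> None:
        names = (self.proximal, self.center, self.distal)
        for name in names:
            if name not in JOINT_INDEX:
                raise ValidationError(f"unknown joint name: {name!r}")
        if len(set(names)) != 3:
            raise ValidationError(f"joint triple must be 3 distinct joints: {names}")


#: Default anatomical triples; per-exercise configs may override or extend.
DEFAULT_TRIPLES: dict[str, JointTriple] = {
    "knee_left": JointTriple("HipLeft", "KneeLeft", "AnkleLeft"),
    "knee_right": JointTriple("HipRight", "KneeRight", "AnkleRight"),
    "elbow_left": JointTriple("ShoulderLeft", "ElbowLeft", "WristLeft"),
    "elbow_right": JointTriple("ShoulderRight", "ElbowRight", "WristRight"),
    "shoulder_left": JointTriple("SpineShoulder", "ShoulderLeft", "ElbowLeft"),
    "shoulder_right": JointTriple("SpineShoulder", "ShoulderRight", "ElbowRight"),
    "hip_left": JointTriple("SpineBase", "HipLeft", "KneeLeft"),
    "hip_right": JointTriple("SpineBase", "HipRight", "KneeRight"),
    "neck": JointTriple("Head", "Neck", "SpineShoulder"),
    "trunk": JointTriple("SpineBase", "SpineMid", "SpineShoulder"),
}


@dataclass
class AngleSeries:
    """Per-frame angle trajectory for one joint triple.

    ``angles`` is in degrees; frames whose geometry was degenerate are NaN.
    ``timestamps`` (optional) carries the source frame times for
    timestamp-aware differentiation.
    """

    triple: JointTriple
    angles: np.ndarray
    fs: float
    timestamps: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        valid = self.angles[np.isfinite(self.angles)]
        if valid.size and (valid.min() < -1e-9 or valid.max() > 180 + 1e-9):
            raise ValidationError("angles must lie in [0, 180] degrees")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.angles)


def _interior_angle(p: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    u = p - c
    v = d - c
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _ZERO_BONE or nv < _ZERO_BONE:
        raise DegenerateGeometryError("zero-length bone vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def joint_angle(frame: Frame, triple: JointTriple) -> float:
    """Interior angle (degrees) at ``triple.center`` for one frame."""
    return _interior_angle(
        frame.position(triple.proximal),
        frame.position(triple.center),
        frame.position(triple.distal),
    )


def angle_series(seq: SkeletonSequence, triple: JointTriple) -> AngleSeries:
    """Frame-wise joint angle over a sequence.

    Degenerate frames are flagged as NaN rather than failing the whole series.
    """
    angles = np.empty(len(seq))
    for i, frame in enumerate(seq):
        try:
            angles[i] = joint_angle(frame, triple)
        except DegenerateGeometryError:
            angles[i] = np.nan
    return AngleSeries(
        triple=triple,
        angles=angles,
        fs=seq.nominal_fs,
        timestamps=seq.timestamps if len(seq) else None,
    )


def derivative(series: Series | AngleSeries, order: int = 1) -> Series:
    """First or second time derivative of a series (deg/s or deg/s^2).

    Central differences on interior points, one-sided at the edges
    (``np.gradient`` semantics). For an :class:`AngleSeries` carrying
    timestamps, the denominators come from the actual frame times.
    """
    if order not in (1, 2):
        raise ParameterError("derivative order must be 1 or 2")
    values = series.values if isinstance(series, Series) else series.angles
    if len(values) < 3:
        raise ParameterError("derivative needs at least 3 samples")
    t = getattr(series, "timestamps", None)
    # Scalar spacing keeps the constant-input derivative exactly zero; the
    # non-uniform formula only kicks in when real timestamps are available.
    spacing = (1.0 / series.fs,) if t is None else (np.asarray(t, dtype=float),)
    out = np.gradient(values, *spacing)
    if order == 2:
        out = np.gradient(out, *spacing)
    return Series(values=out, fs=series.fs)
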