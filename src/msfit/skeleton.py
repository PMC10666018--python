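"""Domain types and I/O for 25-joint skeleton streams.

A stream is a time-stamped sequence of frames, each holding the 3D camera-space
position of 25 named joints (meters; x right, y up, z away from the sensor),
nominally sampled at 30 Hz. Two plain-text serializations are supported:

* ``v1`` — one frame per line: timestamp followed by 75 coordinates in the
  fixed joint order, whitespace- or comma-separated, preceded by a
  ``#msfit-skeleton v1 fs=<Hz>`` header;
* CSV with named columns ``t,<Joint>_x,<Joint>_y,<Joint>_z``.

Per-joint tracking state is an in-memory annotation only; it is not serialized,
so a read-back stream reports every joint as tracked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .errors import FormatError, ParameterError, ValidationError

#: The closed set of 25 joint identifiers, in canonical serialization order.
JOINT_NAMES: tuple[str, ...] = (
    "SpineBase",
    "SpineMid",
    "SpineShoulder",
    "Neck",
    "Head",
    "ShoulderLeft",
    "ElbowLeft",
    "WristLeft",
    "HandLeft",
    "HandTipLeft",
    "ThumbLeft",
    "ShoulderRight",
    "ElbowRight",
    "WristRight",
    "HandRight",
    "HandTipRight",
    "ThumbRight",
    "HipLeft",
    "KneeLeft",
    "AnkleLeft",
    "FootLeft",
    "HipRight",
    "KneeRight",
    "AnkleRight",
    "FootRight",
)

N_JOINTS = len(JOINT_NAMES)

#: Joint name -> row index into a frame's position array.
JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

# Sensor capture range and the recommended standing band, meters (closed
# intervals at both ends).
CAPTURE_RANGE_M = (0.5, 4.5)
RECOMMENDED_BAND_M = (2.0, 3.0)


def _as_positions(positions) -> np.ndarray:
    arr = np.asarray(positions, dtype=float)
    if arr.shape != (N_JOINTS, 3):
        raise ValidationError(
            f"positions must have shape ({N_JOINTS}, 3), got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("joint positions must be finite")
    return arr


@dataclass
class Frame:
    """One skeleton sample: a timestamp plus 25 joint positions.

    Parameters
    ----------
    timestamp : float
        Seconds since the start of the recording.
    positions : (25, 3) array_like
        Joint positions in meters, rows ordered as :data:`JOINT_NAMES`.
    tracked : (25,) bool array, optional
        True where the joint was directly tracked, False where inferred.
        Defaults to all-tracked.
    """

    timestamp: float
    positions: np.ndarray
    tracked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamp = float(self.timestamp)
        if not math.isfinite(self.timestamp):
            raise ValidationError("timestamp must be finite")
        self.positions = _as_positions(self.positions)
        if self.tracked is None:
            self.tracked = np.ones(N_JOINTS, dtype=bool)
        else:
            self.tracked = np.asarray(self.tracked, dtype=bool)
            if self.tracked.shape != (N_JOINTS,):
                raise ValidationError(f"tracked must have shape ({N_JOINTS},)")

    def position(self, joint: str) -> np.ndarray:
        """Return the (x, y, z) position of a named joint."""
        try:
            return self.positions[JOINT_INDEX[joint]]
        except KeyError:
            raise ValidationError(f"unknown joint name: {joint!r}") from None


@dataclass
class SkeletonSequence:
    """An ordered run of frames with strictly increasing timestamps."""

    frames: list[Frame]
    nominal_fs: float = 30.0

    def __post_init__(self) -> None:
        if self.nominal_fs <= 0:
            raise ValidationError("nominal_fs must be > 0")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        """Stacked (n_frames, 25, 3) position array."""
        if not self.frames:
            return np.empty((0, N_JOINTS, 3))
        return np.stack([f.positions for f in self.frames])


@dataclass(frozen=True)
class PlacementCheck:
    in_capture_range: bool
    in_recommended_band: bool


def subject_distance(frame: Frame) -> float:
    """Distance of the subject from the sensor: the z-coordinate of SpineBase."""
    return float(frame.position("SpineBase")[2])


def placement_check(frame: Frame) -> PlacementCheck:
    """Check subject distance against the capture range and recommended band.

    Both intervals are closed: 0.5–4.5 m capture range, 2–3 m recommended.
    """
    d = subject_distance(frame)
    return PlacementCheck(
        in_capture_range=CAPTURE_RANGE_M[0] <= d <= CAPTURE_RANGE_M[1],
        in_recommended_band=RECOMMENDED_BAND_M[0] <= d <= RECOMMENDED_BAND_M[1],
    )


def estimate_frame_rate(seq: SkeletonSequence) -> float:
    """Estimate the sampling rate as the median of reciprocal inter-frame intervals.

    The median makes the estimate robust to a small number of dropped frames.

    Raises
    ------
    ParameterError
        If the sequence has fewer than 2 frames.
    """
    if len(seq) < 2:
        raise ParameterError("frame-rate estimation needs at least 2 frames")
    dt = np.diff(seq.timestamps)
    return float(np.median(1.0 / dt))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_V1_HEADER_PREFIX = "#msfit-skeleton v1"


def _parse_v1_header(line: str) -> float:
    fs = 30.0
    for token in line.split():
        if token.startswith("fs="):
            try:
                fs = float(token[3:])
            except ValueError:
                raise FormatError(f"bad fs in header: {line!r}") from None
    if fs <= 0:
        raise FormatError("header fs must be > 0")
    return fs


def _parse_frame_line(line: str, lineno: int) -> Frame:
    fields = line.replace(",", " ").split()
    if len(fields) != 1 + 3 * N_JOINTS:
        raise FormatError(
            f"line {lineno}: expected {1 + 3 * N_JOINTS} fields, got {len(fields)}"
        )
    try:
        vals = np.array([float(x) for x in fields], dtype=float)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric field ({exc})") from None
    if not np.all(np.isfinite(vals)):
        raise FormatError(f"line {lineno}: non-finite value")
    return Frame(timestamp=vals[0], positions=vals[1:].reshape(N_JOINTS, 3))


def _read_csv_stream(path: str, on_error: str) -> SkeletonSequence:
    import pandas as pd

    df = pd.read_csv(path)
    expected = ["t"] + [f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"CSV stream missing columns: {missing[:5]} ...")
    frames: list[Frame] = []
    for i, row in enumerate(df[expected].to_numpy(dtype=float)):
        if not np.all(np.isfinite(row)):
            if on_error == "skip":
                continue
            raise FormatError(f"CSV row {i}: non-finite value")
        frames.append(Frame(timestamp=row[0], positions=row[1:].reshape(N_JOINTS, 3)))
    return SkeletonSequence(frames=frames, nominal_fs=30.0)


def read_skeleton_stream(
    path: str, on_error: Literal["skip", "fail"] = "skip"
) -> SkeletonSequence:
    """Read a skeleton stream from a ``v1`` or CSV text file.

    Parameters
    ----------
    path : str
        Path to the stream file.
    on_error : {"skip", "fail"}
        Whether malformed frame records are dropped or raise
        :class:`~msfit.errors.FormatError`. Non-monotone timestamps always
        raise, regardless of ``on_error``.
    """
    if on_error not in ("skip", "fail"):
        raise ParameterError(f"on_error must be 'skip' or 'fail', got {on_error!r}")

    with open(path) as fh:
        lines = fh.read().splitlines()

    first_content = next((ln for ln in lines if ln.strip()), "")
    if first_content.startswith("t,") and "_x" in first_content:
        seq = _read_csv_stream(path, on_error)
    else:
        fs = 30.0
        frames = []
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(_V1_HEADER_PREFIX):
                fs = _parse_v1_header(line)
                continue
            if line.startswith("#"):
                continue
            try:
                frames.append(_parse_frame_line(line, lineno))
            except (FormatError, ValidationError):
                if on_error == "fail":
                    raise
        try:
            seq = SkeletonSequence(frames=frames, nominal_fs=fs)
        except ValidationError as exc:
            raise FormatError(str(exc)) from None

    ts = seq.timestamps
    if len(ts) >= 2 and np.any(np.diff(ts) <= 0):
        raise FormatError("stream timestamps are not strictly increasing")
    return seq


def write_skeleton_stream(
    seq: SkeletonSequence, path: str, fmt: Literal["v1", "csv"] = "v1"
) -> None:
    """Write a sequence to disk in the ``v1`` line format or the CSV variant."""
    if fmt == "v1":
        with open(path, "w") as fh:
            fh.write(f"{_V1_HEADER_PREFIX} fs={seq.nominal_fs:g}\n")
            for frame in seq:
                coords = " ".join(repr(float(v)) for v in frame.positions.ravel())
                fh.write(f"{float(frame.timestamp)!r} {coords}\n")
    elif fmt == "csv":
        import pandas as pd

        cols = ["t"] + [f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"]
        rows = [
            np.concatenate(([frame.timestamp], frame.positions.ravel()))
            for frame in seq
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        raise ParameterError(f"unknown format {fmt!r}")
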