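"""Synthetic articulated-skeleton gesture streams with known ground truth.

A fixed-anthropometry standing model (1.70 m stature) is driven by sinusoidal
joint-angle trajectories on the scored joints of a catalog exercise:

    theta(t) = theta0 - A * cos(2*pi*t / T)

so every stream starts exactly at a repetition boundary (the angle minimum),
and the interior angle measured back from the generated positions equals the
drive analytically. Executions derived from a template can be perturbed with
an amplitude scale, per-repetition phase jitter, and additive Gaussian
position noise — all reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np

from .catalog import Catalog, ExerciseDefinition, load_catalog
from .errors import ParameterError
from .game import CHILD_MAP
from .scoring import GestureTemplate
from .sessions import SessionRecord
from .skeleton import JOINT_INDEX, JOINT_NAMES, N_JOINTS, Frame, SkeletonSequence

#: Neutral standing pose (x right, y up, z toward camera offset), meters,
#: for a 1.70 m stature; z is relative to the subject plane.
NEUTRAL_POSE: dict[str, tuple[float, float, float]] = {
    "SpineBase": (0.0, 0.95, 0.0),
    "SpineMid": (0.0, 1.16, 0.0),
    "SpineShoulder": (0.0, 1.37, 0.0),
    "Neck": (0.0, 1.43, 0.0),
    "Head": (0.0, 1.56, 0.0),
    "ShoulderLeft": (-0.18, 1.37, 0.0),
    "ElbowLeft": (-0.21, 1.10, 0.0),
    "WristLeft": (-0.23, 0.86, 0.0),
    "HandLeft": (-0.24, 0.78, 0.0),
    "HandTipLeft": (-0.24, 0.70, 0.0),
    "ThumbLeft": (-0.21, 0.76, 0.03),
    "ShoulderRight": (0.18, 1.37, 0.0),
    "ElbowRight": (0.21, 1.10, 0.0),
    "WristRight": (0.23, 0.86, 0.0),
    "HandRight": (0.24, 0.78, 0.0),
    "HandTipRight": (0.24, 0.70, 0.0),
    "ThumbRight": (0.21, 0.76, 0.03),
    "HipLeft": (-0.09, 0.92, 0.0),
    "KneeLeft": (-0.10, 0.50, 0.0),
    "AnkleLeft": (-0.10, 0.08, 0.0),
    "FootLeft": (-0.10, 0.03, 0.12),
    "HipRight": (0.09, 0.92, 0.0),
    "KneeRight": (0.10, 0.50, 0.0),
    "AnkleRight": (0.10, 0.08, 0.0),
    "FootRight": (0.10, 0.03, 0.12),
}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic gesture generator.

    ``amplitude_deg=None`` uses each scored joint's catalog default amplitude;
    a number overrides the amplitude of every scored joint uniformly.
    """

    exercise_id: str
    amplitude_deg: float | None = None
    period_s: float = 2.0
    n_reps: int = 5
    fs: float = 30.0
    amplitude_scale: float = 1.0
    phase_jitter_sd_s: float = 0.0
    noise_sd_m: float = 0.0
    subject_distance_m: float = 2.5
    seed: int = 0
    n_template_samples: int = 101  # odd count puts a sample exactly mid-cycle

    def __post_init__(self) -> None:
        if self.period_s <= 0 or self.fs <= 0:
            raise ParameterError("period_s and fs must be > 0")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if self.amplitude_deg is not None and self.amplitude_deg <= 0:
            raise ParameterError("amplitude_deg must be > 0")


def _neutral_positions(distance_m: float) -> np.ndarray:
    pos = np.array([NEUTRAL_POSE[name] for name in JOINT_NAMES], dtype=float)
    pos[:, 2] += distance_m
    return pos


def _descendants(joint: str) -> list[str]:
    out: list[str] = []
    stack = list(CHILD_MAP.get(joint, ()))
    while stack:
        j = stack.pop()
        out.append(j)
        stack.extend(CHILD_MAP.get(j, ()))
    return out


def _drive_basis(neutral: np.ndarray, proximal: str, center: str, distal: str):
    """Orthonormal (e1, e2) spanning the drive plane at a joint, plus bone length.

    e1 points from the center joint toward the proximal one; e2 is the unit
    projection of the camera z-axis (fallback x-axis) orthogonal to e1. The
    distal joint is placed at ``C + L*(cos(theta)*e1 + sin(theta)*e2)`` so the
    interior angle at the center equals theta exactly.
    """
    c = neutral[JOINT_INDEX[center]]
    p = neutral[JOINT_INDEX[proximal]]
    d = neutral[JOINT_INDEX[distal]]
    e1 = p - c
    e1 = e1 / np.linalg.norm(e1)
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])):
        e2 = ref - np.dot(ref, e1) * e1
        norm = np.linalg.norm(e2)
        if norm > 1e-6:
            e2 = e2 / norm
            break
    length = float(np.linalg.norm(d - c))
    return e1, e2, length


def _synthesize_stream(
    exercise: ExerciseDefinition,
    amplitudes: dict[str, float],
    params: GeneratorParams,
    amplitude_scale: float,
    phase_jitter_sd_s: float,
    noise_sd_m: float,
    rng: np.random.Generator | None,
) -> SkeletonSequence:
    T, fs = params.period_s, params.fs
    n_frames = int(round(params.n_reps * T * fs)) + 1
    t = np.arange(n_frames) / fs
    neutral = _neutral_positions(params.subject_distance_m)

    if phase_jitter_sd_s > 0:
        if rng is None:
            raise ParameterError("phase jitter requires a seeded rng")
        offsets = rng.normal(0.0, phase_jitter_sd_s, size=params.n_reps)
    else:
        offsets = np.zeros(params.n_reps)
    rep_idx = np.minimum((t / T).astype(int), params.n_reps - 1)
    t_eff = t - offsets[rep_idx]

    positions = np.repeat(neutral[None, :, :], n_frames, axis=0)
    for joint in exercise.scored_joints:
        trip = joint.triple
        e1, e2, length = _drive_basis(neutral, trip.proximal, trip.center, trip.distal)
        theta = np.radians(
            joint.neutral_deg
            - amplitude_scale * amplitudes[joint.key] * np.cos(2 * np.pi * t_eff / T)
        )
        center = neutral[JOINT_INDEX[trip.center]]
        new_distal = (
            center[None, :]
            + length * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
        )
        di = JOINT_INDEX[trip.distal]
        shift = new_distal - neutral[di]
        positions[:, di, :] = new_distal
        for child in _descendants(trip.distal):
            positions[:, JOINT_INDEX[child], :] = neutral[JOINT_INDEX[child]] + shift

    if noise_sd_m > 0:
        if rng is None:
            raise ParameterError("position noise requires a seeded rng")
        positions = positions + rng.normal(0.0, noise_sd_m, size=positions.shape)

    frames = [Frame(timestamp=t[i], positions=positions[i]) for i in range(n_frames)]
    return SkeletonSequence(frames=frames, nominal_fs=fs)


def generate_template(
    params: GeneratorParams, catalog: Catalog | None = None
) -> tuple[GestureTemplate, SkeletonSequence]:
    """Ideal angle template plus the noise-free skeleton stream realizing it."""
    catalog = catalog or load_catalog()
    exercise = catalog[params.exercise_id]

    amplitudes = {
        j.key: (params.amplitude_deg if params.amplitude_deg is not None else j.amplitude_deg)
        for j in exercise.scored_joints
    }
    grid = np.linspace(0.0, 1.0, params.n_template_samples)
    trajectories = {
        j.key: j.neutral_deg - amplitudes[j.key] * np.cos(2 * np.pi * grid)
        for j in exercise.scored_joints
    }
    template = GestureTemplate(
        exercise_id=exercise.id,
        grid=grid,
        trajectories=trajectories,
        triples={j.key: j.triple for j in exercise.scored_joints},
        weights={j.key: j.weight for j in exercise.scored_joints},
        duration_s=params.period_s,
        meta={"params": params, "amplitudes": amplitudes, "exercise": exercise},
    )
    stream = _synthesize_stream(
        exercise, amplitudes, params, 1.0, 0.0, 0.0, rng=None
    )
    return template, stream


def generate_execution(
    template: GestureTemplate,
    amplitude_scale: float = 1.0,
    phase_jitter_sd_s: float = 0.0,
    noise_sd_m: float = 0.0,
    seed: int = 0,
) -> SkeletonSequence:
    """A perturbed execution of a generated template's gesture."""
    try:
        params: GeneratorParams = template.meta["params"]
        amplitudes: dict[str, float] = template.meta["amplitudes"]
        exercise: ExerciseDefinition = template.meta["exercise"]
    except KeyError:
        raise ParameterError(
            "template lacks generator metadata; use generate_template first"
        ) from None
    rng = np.random.default_rng(seed)
    return _synthesize_stream(
        exercise,
        amplitudes,
        params,
        amplitude_scale,
        phase_jitter_sd_s,
        noise_sd_m,
        rng=rng,
    )


def true_boundaries(params: GeneratorParams) -> list[int]:
    """Ground-truth repetition boundary frame indices of a generated stream."""
    return [
        int(round(k * params.period_s * params.fs)) for k in range(params.n_reps + 1)
    ]


def generate_calibration_stream(
    duration_s: float = 6.0,
    distance_m: float = 2.5,
    noise_sd_m: float = 0.0,
    fs: float = 30.0,
    seed: int = 0,
) -> SkeletonSequence:
    """A standing-still, arms-down stream suitable for calibration."""
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    neutral = _neutral_positions(distance_m)
    positions = np.repeat(neutral[None, :, :], n, axis=0)
    if noise_sd_m > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, noise_sd_m, size=(n, N_JOINTS, 3))
    frames = [Frame(timestamp=t[i], positions=positions[i]) for i in range(n)]
    return SkeletonSequence(frames=frames, nominal_fs=fs)


def generate_session_log(
    n_days: int,
    sessions_per_day: int,
    minutes_per_session: float,
    seed: int = 0,
    start_date: date = date(2023, 1, 2),  # a Monday
) -> list[SessionRecord]:
    """Deterministic synthetic session log for mission and adherence tests."""
    if n_days < 0 or sessions_per_day < 0:
        raise ParameterError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    hours = [9, 18, 12, 15, 20]
    log: list[SessionRecord] = []
    for day in range(n_days):
        for k in range(sessions_per_day):
            minute = int(rng.integers(0, 30))
            start = datetime.combine(
                start_date + timedelta(days=day),
                datetime.min.time(),
            ) + timedelta(hours=hours[k % len(hours)], minutes=minute)
            log.append(
                SessionRecord(start=start, duration_min=float(minutes_per_session))
            )
    return log
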