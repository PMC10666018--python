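"""Gamification state machine: coins, city itinerary, missions, calibration.

Coins are earned per correct repetition and spent to unlock the next city of a
linear travel itinerary; the unlocked set is always a prefix of the itinerary
and the first city starts unlocked. Missions are achievements defined by
predicates over the session log; the built-in "Methodic" mission requires two
sessions per day on five consecutive calendar days. Calibration requires the
subject to stand still, arms along the body, inside the capture range for a
minimum duration, and yields reference bone lengths and neutral angles reused
in later sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Callable

import numpy as np

from .errors import ParameterError, ValidationError
from .kinematics import DEFAULT_TRIPLES, angle_series
from .sessions import SessionRecord
from .skeleton import (
    CAPTURE_RANGE_M,
    JOINT_INDEX,
    SkeletonSequence,
    placement_check,
)

DEFAULT_COINS_PER_CORRECT = 1
DEFAULT_UNLOCK_COST = 50

#: Parent -> children joint hierarchy (used for bone lengths and by the
#: synthetic generator's forward kinematics).
CHILD_MAP: dict[str, tuple[str, ...]] = {
    "SpineBase": ("SpineMid", "HipLeft", "HipRight"),
    "SpineMid": ("SpineShoulder",),
    "SpineShoulder": ("Neck", "ShoulderLeft", "ShoulderRight"),
    "Neck": ("Head",),
    "ShoulderLeft": ("ElbowLeft",),
    "ElbowLeft": ("WristLeft",),
    "WristLeft": ("HandLeft",),
    "HandLeft": ("HandTipLeft", "ThumbLeft"),
    "ShoulderRight": ("ElbowRight",),
    "ElbowRight": ("WristRight",),
    "WristRight": ("HandRight",),
    "HandRight": ("HandTipRight", "ThumbRight"),
    "HipLeft": ("KneeLeft",),
    "KneeLeft": ("AnkleLeft",),
    "AnkleLeft": ("FootLeft",),
    "HipRight": ("KneeRight",),
    "KneeRight": ("AnkleRight",),
    "AnkleRight": ("FootRight",),
}

BONE_EDGES: tuple[tuple[str, str], ...] = tuple(
    (parent, child) for parent, children in CHILD_MAP.items() for child in children
)


@dataclass(frozen=True)
class City:
    name: str
    region: str = ""
    unlock_cost: int = DEFAULT_UNLOCK_COST

    def __post_init__(self) -> None:
        if self.unlock_cost < 0:
            raise ValidationError("unlock_cost must be >= 0")


def default_itinerary() -> list[City]:
    """Linear default itinerary starting in Italy and branching into Europe."""
    names = [
        ("Rome", "Italy"),
        ("Florence", "Italy"),
        ("Bologna", "Italy"),
        ("Venice", "Italy"),
        ("Milan", "Italy"),
        ("Athens", "Greece"),
        ("Paris", "France"),
        ("Barcelona", "Spain"),
        ("London", "United Kingdom"),
        ("Berlin", "Germany"),
    ]
    return [City(name=n, region=r) for n, r in names]


@dataclass(frozen=True)
class Mission:
    """An achievement: a named predicate with parameters over the session log."""

    id: str
    name: str
    rule: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.params.values():
            if isinstance(v, (int, float)) and v <= 0:
                raise ValidationError(f"mission {self.id}: parameters must be positive")


MissionPredicate = Callable[[list[SessionRecord], dict], bool]

MISSION_RULES: dict[str, MissionPredicate] = {}


def mission_rule(name: str) -> Callable[[MissionPredicate], MissionPredicate]:
    def register(fn: MissionPredicate) -> MissionPredicate:
        MISSION_RULES[name] = fn
        return fn

    return register


@mission_rule("daily_streak")
def _daily_streak(log: list[SessionRecord], params: dict) -> bool:
    """>= sessions_per_day sessions on each of >= consecutive_days calendar days."""
    per_day = int(params.get("sessions_per_day", 2))
    streak_days = int(params.get("consecutive_days", 5))
    counts: dict = {}
    for s in log:
        day = s.start.date()
        counts[day] = counts.get(day, 0) + 1
    qualifying = sorted(d for d, c in counts.items() if c >= per_day)
    run = 0
    prev = None
    for day in qualifying:
        run = run + 1 if prev is not None and day - prev == timedelta(days=1) else 1
        if run >= streak_days:
            return True
        prev = day
    return False


@mission_rule("total_sessions")
def _total_sessions(log: list[SessionRecord], params: dict) -> bool:
    return len(log) >= int(params.get("count", 10))


@mission_rule("total_minutes")
def _total_minutes(log: list[SessionRecord], params: dict) -> bool:
    return sum(s.duration_min for s in log) >= float(params.get("minutes", 150))


def default_missions() -> list[Mission]:
    return [
        Mission(
            id="methodic",
            name="Methodic",
            rule="daily_streak",
            params={"sessions_per_day": 2, "consecutive_days": 5},
        ),
    ]


@dataclass(frozen=True)
class CalibrationProfile:
    bone_lengths_m: dict[str, float]
    neutral_angles_deg: dict[str, float]
    subject_distance_m: float


@dataclass(frozen=True)
class CalibrationResult:
    ok: bool
    reasons: tuple[str, ...] = ()
    profile: CalibrationProfile | None = None
    window: tuple[int, int] | None = None


@dataclass(frozen=True)
class PlayerState:
    coins: int = 0
    unlocked_cities: tuple[str, ...] = ()
    completed_missions: frozenset[str] = frozenset()
    calibrated: bool = False
    calibration: CalibrationProfile | None = None

    def __post_init__(self) -> None:
        if self.coins < 0:
            raise ValidationError("coins must be >= 0")


def new_player(itinerary: list[City]) -> PlayerState:
    """Fresh state with the first itinerary city unlocked."""
    if not itinerary:
        raise ParameterError("itinerary must be nonempty")
    return PlayerState(unlocked_cities=(itinerary[0].name,))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

STILLNESS_THRESHOLD_M_S = 0.05
WRIST_BELOW_HIP_TOL_M = 0.15
TRUNK_VERTICAL_TOL_DEG = 15.0


def _frame_posture_ok(positions: np.ndarray) -> bool:
    def at(name: str) -> np.ndarray:
        return positions[JOINT_INDEX[name]]

    arms_down = (
        at("WristLeft")[1] <= at("HipLeft")[1] + WRIST_BELOW_HIP_TOL_M
        and at("WristRight")[1] <= at("HipRight")[1] + WRIST_BELOW_HIP_TOL_M
    )
    trunk = at("SpineShoulder") - at("SpineBase")
    norm = np.linalg.norm(trunk)
    if norm < 1e-9:
        return False
    tilt = np.degrees(np.arccos(np.clip(trunk[1] / norm, -1.0, 1.0)))
    return arms_down and tilt <= TRUNK_VERTICAL_TOL_DEG


def calibrate(
    seq: SkeletonSequence,
    min_duration_s: float = 5.0,
    stillness_threshold: float = STILLNESS_THRESHOLD_M_S,
) -> CalibrationResult:
    """Search for a still, standing, in-range window of at least ``min_duration_s``.

    On success the result carries reference bone lengths and neutral angles
    averaged over the window; these remain valid for later sessions. On
    failure, ``reasons`` lists which conditions could not be met
    (``duration``, ``stillness``, ``posture``, ``range``).
    """
    n = len(seq)
    if n == 0:
        return CalibrationResult(ok=False, reasons=("duration",))
    ts = seq.timestamps
    pos = seq.positions

    speed_ok = np.ones(n, dtype=bool)
    if n >= 2:
        dt = np.diff(ts)[:, None]
        speeds = np.linalg.norm(np.diff(pos, axis=0), axis=2) / dt
        per_frame = speeds.max(axis=1)  # fastest joint between frames i, i+1
        speed_ok[1:] = per_frame < stillness_threshold

    posture_ok = np.array([_frame_posture_ok(p) for p in pos])
    range_ok = np.array([placement_check(f).in_capture_range for f in seq])
    good = speed_ok & posture_ok & range_ok

    # Longest run of good frames.
    best_start = best_len = cur_start = cur_len = 0
    for i, g in enumerate(good):
        if g:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0

    if best_len >= 2 and ts[best_start + best_len - 1] - ts[best_start] >= min_duration_s:
        a, b = best_start, best_start + best_len - 1
        window_pos = pos[a : b + 1]
        bones = {
            f"{p}-{c}": float(
                np.mean(
                    np.linalg.norm(
                        window_pos[:, JOINT_INDEX[c]] - window_pos[:, JOINT_INDEX[p]],
                        axis=1,
                    )
                )
            )
            for p, c in BONE_EDGES
        }
        sub = SkeletonSequence(frames=seq.frames[a : b + 1], nominal_fs=seq.nominal_fs)
        neutral = {
            key: float(np.nanmean(angle_series(sub, triple).angles))
            for key, triple in DEFAULT_TRIPLES.items()
        }
        distance = float(np.mean(window_pos[:, JOINT_INDEX["SpineBase"], 2]))
        return CalibrationResult(
            ok=True,
            profile=CalibrationProfile(
                bone_lengths_m=bones,
                neutral_angles_deg=neutral,
                subject_distance_m=distance,
            ),
            window=(a, b),
        )

    reasons = []
    total_span = ts[-1] - ts[0] if n >= 2 else 0.0
    if total_span < min_duration_s:
        reasons.append("duration")
    if not speed_ok.all():
        reasons.append("stillness")
    if not posture_ok.any():
        reasons.append("posture")
    if not range_ok.any():
        reasons.append("range")
    if not reasons:
        reasons.append("stillness")
    return CalibrationResult(ok=False, reasons=tuple(reasons))


def apply_calibration(state: PlayerState, result: CalibrationResult) -> PlayerState:
    if not result.ok:
        return state
    return replace(state, calibrated=True, calibration=result.profile)


# ---------------------------------------------------------------------------
# Coins, cities, missions
# ---------------------------------------------------------------------------


def award_coins(
    state: PlayerState,
    scores,
    coins_per_correct: int = DEFAULT_COINS_PER_CORRECT,
) -> PlayerState:
    """Add ``coins_per_correct`` per correct repetition; incorrect ones earn 0."""
    if coins_per_correct < 0:
        raise ParameterError("coins_per_correct must be >= 0")
    earned = coins_per_correct * sum(1 for s in scores if s.correct)
    return replace(state, coins=state.coins + earned)


@dataclass(frozen=True)
class UnlockOutcome:
    state: PlayerState
    unlocked: bool
    city: str | None = None
    reason: str | None = None


def try_unlock_next_city(state: PlayerState, itinerary: list[City]) -> UnlockOutcome:
    """Spend coins on the next itinerary city if affordable; else report why not."""
    if not itinerary:
        raise ParameterError("itinerary must be nonempty")
    names = [c.name for c in itinerary]
    if list(state.unlocked_cities) != names[: len(state.unlocked_cities)]:
        raise ValidationError("unlocked cities are not a prefix of the itinerary")
    nxt = len(state.unlocked_cities)
    if nxt >= len(itinerary):
        return UnlockOutcome(state=state, unlocked=False, reason="itinerary exhausted")
    city = itinerary[nxt]
    if state.coins < city.unlock_cost:
        return UnlockOutcome(
            state=state,
            unlocked=False,
            city=city.name,
            reason=f"insufficient funds: {state.coins} < {city.unlock_cost}",
        )
    new_state = replace(
        state,
        coins=state.coins - city.unlock_cost,
        unlocked_cities=state.unlocked_cities + (city.name,),
    )
    return UnlockOutcome(state=new_state, unlocked=True, city=city.name)


def evaluate_missions(
    state: PlayerState,
    session_log: list[SessionRecord],
    mission_set: list[Mission] | None = None,
) -> PlayerState:
    """Add every mission whose predicate holds over the log to the completed set."""
    missions = default_missions() if mission_set is None else mission_set
    completed = set(state.completed_missions)
    for mission in missions:
        try:
            predicate = MISSION_RULES[mission.rule]
        except KeyError:
            raise ParameterError(f"unknown mission rule {mission.rule!r}") from None
        if predicate(session_log, mission.params):
            completed.add(mission.id)
    return replace(state, completed_missions=frozenset(completed))


# ---------------------------------------------------------------------------
# State persistence (plain YAML)
# ---------------------------------------------------------------------------


def save_state(state: PlayerState, path: str) -> None:
    import yaml

    blob = {
        "coins": state.coins,
        "unlocked_cities": list(state.unlocked_cities),
        "completed_missions": sorted(state.completed_missions),
        "calibrated": state.calibrated,
    }
    if state.calibration is not None:
        blob["calibration"] = {
            "bone_lengths_m": state.calibration.bone_lengths_m,
            "neutral_angles_deg": state.calibration.neutral_angles_deg,
            "subject_distance_m": state.calibration.subject_distance_m,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(blob, fh)


def load_state(path: str) -> PlayerState:
    import yaml

    with open(path) as fh:
        blob = yaml.safe_load(fh)
    calibration = None
    if "calibration" in blob:
        calibration = CalibrationProfile(
            bone_lengths_m=blob["calibration"]["bone_lengths_m"],
            neutral_angles_deg=blob["calibration"]["neutral_angles_deg"],
            subject_distance_m=blob["calibration"]["subject_distance_m"],
        )
    return PlayerState(
        coins=int(blob["coins"]),
        unlocked_cities=tuple(blob["unlocked_cities"]),
        completed_missions=frozenset(blob["completed_missions"]),
        calibrated=bool(blob.get("calibrated", False)),
        calibration=calibration,
    )
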