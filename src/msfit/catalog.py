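"""Exercise catalog and difficulty-scaled protocols.

The built-in catalog covers the Pilates repertoire of the tool: breathing,
posture, and balance exercises performed sitting, standing, or kneeling. Each
entry carries the scored joint triples with their neutral angle and default
angular amplitude (degrees) used both for scoring templates and for the
synthetic generator. Everything is overridable from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ParameterError, ValidationError
from .kinematics import DEFAULT_TRIPLES, JointTriple

CATEGORIES = ("breathing", "posture", "balance")
POSITIONS = ("sitting", "standing", "kneeling")

DEFAULT_BASE_REPS = 5


@dataclass
class ScoredJoint:
    """One scored triple with its neutral angle and default drive amplitude."""

    key: str
    triple: JointTriple
    neutral_deg: float
    amplitude_deg: float
    weight: float = 1.0


@dataclass
class ExerciseDefinition:
    id: str
    name: str
    category: str
    position: str
    scored_joints: list[ScoredJoint]
    base_reps: int = DEFAULT_BASE_REPS
    complexity_level: int = 1

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.id}: category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.position not in POSITIONS:
            raise ValidationError(
                f"{self.id}: position must be one of {POSITIONS}, got {self.position!r}"
            )
        if self.base_reps < 1:
            raise ValidationError(f"{self.id}: base_reps must be >= 1")
        if self.complexity_level < 1:
            raise ValidationError(f"{self.id}: complexity_level must be >= 1")
        if not self.scored_joints:
            raise ValidationError(f"{self.id}: needs at least one scored joint")


def _sj(key: str, neutral: float, amplitude: float, weight: float = 1.0) -> ScoredJoint:
    return ScoredJoint(
        key=key,
        triple=DEFAULT_TRIPLES[key],
        neutral_deg=neutral,
        amplitude_deg=amplitude,
        weight=weight,
    )


def _default_exercises() -> list[ExerciseDefinition]:
    E = ExerciseDefinition
    return [
        E("side_to_side_1", "Side to side 1", "balance", "standing",
          [_sj("trunk", 140.0, 20.0)], complexity_level=1),
        E("spine_stretch_1", "Spine Stretch 1", "posture", "sitting",
          [_sj("trunk", 130.0, 25.0)], complexity_level=1),
        E("sitting_mermaid_1", "Sitting Mermaid 1", "breathing", "sitting",
          [_sj("elbow_left", 90.0, 40.0)], complexity_level=1),
        E("kneeling_mermaid_1", "Kneeling Mermaid 1", "breathing", "kneeling",
          [_sj("elbow_right", 90.0, 40.0)], complexity_level=2),
        E("one_leg_circle_1", "One leg circle 1", "balance", "standing",
          [_sj("hip_left", 100.0, 30.0)], complexity_level=2),
        E("scapola_position_1", "Scapola Position 1", "posture", "sitting",
          [_sj("shoulder_left", 70.0, 25.0, 0.5),
           _sj("shoulder_right", 70.0, 25.0, 0.5)], complexity_level=1),
        E("arm_circles_sitting_1", "Arm circles (sitting) 1", "breathing", "sitting",
          [_sj("shoulder_left", 60.0, 35.0, 0.5),
           _sj("shoulder_right", 60.0, 35.0, 0.5)], complexity_level=1),
        E("arm_circles_standing_1", "Arm circles (standing) 1", "breathing", "standing",
          [_sj("shoulder_left", 60.0, 35.0, 0.5),
           _sj("shoulder_right", 60.0, 35.0, 0.5)], complexity_level=2),
        E("arch_and_curl_1", "Arch and curl 1", "posture", "sitting",
          [_sj("trunk", 135.0, 25.0)], complexity_level=1),
        E("spine_twist_1", "Spine Twist 1", "posture", "standing",
          [_sj("trunk", 145.0, 15.0)], complexity_level=2),
        E("elephant_1", "Elephant 1", "posture", "standing",
          [_sj("trunk", 110.0, 30.0)], complexity_level=3),
        E("hip_circle_1", "Hip circle 1", "balance", "standing",
          [_sj("hip_left", 100.0, 20.0)], complexity_level=2),
        E("side_leg_kick_1", "Side leg kick 1", "balance", "standing",
          [_sj("hip_right", 100.0, 30.0)], complexity_level=2),
        E("single_leg_extension_1", "Single leg extension 1", "balance", "standing",
          [_sj("knee_left", 100.0, 35.0)], complexity_level=3),
    ]


@dataclass
class Catalog:
    exercises: dict[str, ExerciseDefinition] = field(default_factory=dict)

    def __contains__(self, exercise_id: str) -> bool:
        return exercise_id in self.exercises

    def __getitem__(self, exercise_id: str) -> ExerciseDefinition:
        try:
            return self.exercises[exercise_id]
        except KeyError:
            raise ParameterError(f"unknown exercise: {exercise_id!r}") from None

    def __len__(self) -> int:
        return len(self.exercises)

    def ids(self) -> list[str]:
        return list(self.exercises)

    def names(self) -> list[str]:
        return [e.name for e in self.exercises.values()]


def _exercise_from_config(exercise_id: str, cfg: dict) -> ExerciseDefinition:
    joints = []
    for j in cfg.get("scored_joints", []):
        key = j["key"]
        triple = (
            JointTriple(*j["triple"]) if "triple" in j else DEFAULT_TRIPLES[key]
        )
        joints.append(
            ScoredJoint(
                key=key,
                triple=triple,
                neutral_deg=float(j.get("neutral_deg", 100.0)),
                amplitude_deg=float(j.get("amplitude_deg", 30.0)),
                weight=float(j.get("weight", 1.0)),
            )
        )
    return ExerciseDefinition(
        id=exercise_id,
        name=cfg.get("name", exercise_id),
        category=cfg["category"],
        position=cfg["position"],
        scored_joints=joints,
        base_reps=int(cfg.get("base_reps", DEFAULT_BASE_REPS)),
        complexity_level=int(cfg.get("complexity_level", 1)),
    )


def load_catalog(config_path: str | None = None) -> Catalog:
    """Built-in default catalog, optionally merged with YAML overrides.

    Override entries replace same-id defaults wholesale and may add new
    exercises; an empty override file leaves the defaults unchanged.
    """
    catalog = Catalog(exercises={e.id: e for e in _default_exercises()})
    if config_path is not None:
        with open(config_path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValidationError("catalog config must be a mapping of id -> block")
        for exercise_id, cfg in overrides.items():
            catalog.exercises[exercise_id] = _exercise_from_config(exercise_id, cfg)
    return catalog


def dump_catalog(catalog: Catalog, path: str) -> None:
    """Serialize a catalog to the same YAML schema ``load_catalog`` accepts."""
    blob = {}
    for e in catalog.exercises.values():
        blob[e.id] = {
            "name": e.name,
            "category": e.category,
            "position": e.position,
            "base_reps": e.base_reps,
            "complexity_level": e.complexity_level,
            "scored_joints": [
                {
                    "key": j.key,
                    "triple": [j.triple.proximal, j.triple.center, j.triple.distal],
                    "neutral_deg": j.neutral_deg,
                    "amplitude_deg": j.amplitude_deg,
                    "weight": j.weight,
                }
                for j in e.scored_joints
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(blob, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Difficulty-scaled protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """The exercise prescription issued for one city."""

    city_index: int
    items: tuple[tuple[str, int], ...]  # (exercise_id, reps)


@dataclass(frozen=True)
class DifficultyRule:
    """Linear difficulty schedule.

    Repetitions grow by ``reps_step`` per city; exercises whose complexity
    exceeds ``1 + (city_index - 1) // complexity_unlock_every`` are excluded.
    """

    reps_step: int = 1
    complexity_unlock_every: int = 2

    def reps(self, base_reps: int, city_index: int) -> int:
        return base_reps + self.reps_step * (city_index - 1)

    def allowed_complexity(self, city_index: int) -> int:
        return 1 + (city_index - 1) // self.complexity_unlock_every


def protocol_for_city(
    city_index: int,
    catalog: Catalog,
    rule: DifficultyRule | None = None,
    max_city_index: int | None = None,
) -> Protocol:
    """Issue the protocol for a city index (1-based).

    Replaying an already-unlocked city reissues the identical protocol — the
    schedule depends only on ``city_index``, never on player progress.
    """
    rule = rule or DifficultyRule()
    if city_index < 1:
        raise ParameterError("city_index must be >= 1")
    if max_city_index is not None and city_index > max_city_index:
        raise ParameterError(
            f"city_index {city_index} beyond itinerary of {max_city_index}"
        )
    allowed = rule.allowed_complexity(city_index)
    items = tuple(
        (e.id, rule.reps(e.base_reps, city_index))
        for e in catalog.exercises.values()
        if e.complexity_level <= allowed
    )
    return Protocol(city_index=city_index, items=items)
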