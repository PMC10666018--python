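"""Session records, use-data aggregation, and adherence reporting.

Weeks are ISO-8601 weeks (Monday–Sunday). The weekly recommendation threshold
is 150 minutes of exercise. An exercise counts as "skipped" when it was issued
in the session's protocol but has zero scored repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

from .errors import ValidationError

WEEKLY_RECOMMENDED_MINUTES = 150.0


@dataclass(frozen=True)
class ExercisePerformance:
    exercise_id: str
    n_reps: int
    n_correct: int
    mean_error_pct: float

    def __post_init__(self) -> None:
        if self.n_reps < 0 or self.n_correct < 0:
            raise ValidationError("rep counts must be nonnegative")
        if self.n_correct > self.n_reps:
            raise ValidationError("n_correct cannot exceed n_reps")


@dataclass(frozen=True)
class SessionRecord:
    start: datetime
    duration_min: float
    exercises_performed: tuple[ExercisePerformance, ...] = ()
    exercises_skipped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValidationError("duration must be >= 0 minutes")


def iso_week(ts: datetime) -> str:
    """ISO week key, e.g. '2023-W05'."""
    year, week, _ = ts.isocalendar()
    return f"{year}-W{week:02d}"


@dataclass(frozen=True)
class WeeklyAdherence:
    minutes: float
    meets_recommendation: bool


def weekly_adherence(
    log: list[SessionRecord],
    week: str,
    recommended_minutes: float = WEEKLY_RECOMMENDED_MINUTES,
) -> WeeklyAdherence:
    """Total exercise minutes in one ISO week versus the recommendation."""
    minutes = sum(s.duration_min for s in log if iso_week(s.start) == week)
    return WeeklyAdherence(
        minutes=minutes, meets_recommendation=minutes >= recommended_minutes
    )


@dataclass
class UseReport:
    """Aggregated use data shared with the user and clinician."""

    n_sessions: int = 0
    total_minutes: float = 0.0
    sessions_per_week: dict[str, int] = field(default_factory=dict)
    minutes_per_week: dict[str, float] = field(default_factory=dict)
    n_exercises_performed: int = 0
    n_exercises_skipped: int = 0
    unlocked_cities_ratio: float = 0.0
    completed_missions_ratio: float = 0.0
    mean_correct_ratio: float = 0.0
    mean_error_pct: float = 0.0


def use_report(
    log: list[SessionRecord],
    state=None,
    itinerary=None,
    mission_set=None,
) -> UseReport:
    """Aggregate a session log into a :class:`UseReport`.

    ``state`` (a :class:`~msfit.game.PlayerState`), ``itinerary``, and
    ``mission_set`` are optional; when given, the unlocked-city and
    completed-mission ratios are filled in.
    """
    report = UseReport()
    report.n_sessions = len(log)
    report.total_minutes = float(sum(s.duration_min for s in log))
    for s in log:
        wk = iso_week(s.start)
        report.sessions_per_week[wk] = report.sessions_per_week.get(wk, 0) + 1
        report.minutes_per_week[wk] = (
            report.minutes_per_week.get(wk, 0.0) + s.duration_min
        )
        report.n_exercises_performed += len(s.exercises_performed)
        report.n_exercises_skipped += len(s.exercises_skipped)

    total_reps = sum(p.n_reps for s in log for p in s.exercises_performed)
    total_correct = sum(p.n_correct for s in log for p in s.exercises_performed)
    if total_reps:
        report.mean_correct_ratio = total_correct / total_reps
        weighted = sum(
            p.mean_error_pct * p.n_reps for s in log for p in s.exercises_performed
        )
        report.mean_error_pct = weighted / total_reps

    if state is not None and itinerary:
        report.unlocked_cities_ratio = len(state.unlocked_cities) / len(itinerary)
    if state is not None and mission_set:
        report.completed_missions_ratio = len(state.completed_missions) / len(
            mission_set
        )
    return report


# ---------------------------------------------------------------------------
# CSV log I/O. One row per session; performed exercises are packed as
# 'id:reps:correct:err' items separated by ';'.
# ---------------------------------------------------------------------------


def write_session_log(log: list[SessionRecord], path: str) -> None:
    import pandas as pd

    rows = []
    for s in log:
        performed = ";".join(
            f"{p.exercise_id}:{p.n_reps}:{p.n_correct}:{p.mean_error_pct:.4f}"
            for p in s.exercises_performed
        )
        rows.append(
            {
                "start": s.start.isoformat(),
                "duration_min": s.duration_min,
                "performed": performed,
                "skipped": ";".join(s.exercises_skipped),
            }
        )
    pd.DataFrame(rows, columns=["start", "duration_min", "performed", "skipped"]).to_csv(
        path, index=False
    )


def read_session_log(path: str) -> list[SessionRecord]:
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False)
    log = []
    for _, row in df.iterrows():
        performed = []
        if row.get("performed"):
            for item in str(row["performed"]).split(";"):
                eid, reps, correct, err = item.split(":")
                performed.append(
                    ExercisePerformance(eid, int(reps), int(correct), float(err))
                )
        skipped = tuple(x for x in str(row.get("skipped", "")).split(";") if x)
        log.append(
            SessionRecord(
                start=datetime.fromisoformat(str(row["start"])),
                duration_min=float(row["duration_min"]),
                exercises_performed=tuple(performed),
                exercises_skipped=skipped,
            )
        )
    return log
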