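"""Gesture-correctness scoring against reference angle templates.

A :class:`GestureTemplate` stores, for each scored joint triple, a reference
angle trajectory on a normalized time grid, together with a weight and the
trajectory's range of motion (ROM). A user's execution is compared joint by
joint after time normalization; the per-joint error is the ROM-normalized mean
absolute angle deviation in percent,

    e_j = mean_t | theta_user(t) - theta_ref(t) | / ROM_j * 100,

and the overall error is the weight-convex combination ``sum_j w_j * e_j``.
An execution counts as *correct* when the overall error is strictly below the
threshold (default 5%).

Time normalization is linear by default (start and end of the user series
mapped onto the template grid); dynamic time warping is available as an
alternative alignment for executions at uneven speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ParameterError, ScoringError, TemplateError
from .kinematics import AngleSeries, JointTriple, angle_series
from .preprocessing import (
    DEFAULT_CUTOFF_HZ,
    DEFAULT_FILTER_ORDER,
    Series,
    butterworth_lowpass,
    filter_positions,
    group_delay_frames,
)
from .skeleton import SkeletonSequence

DEFAULT_THRESHOLD_PCT = 5.0
MIN_TEMPLATE_SAMPLES = 8


@dataclass
class GestureTemplate:
    """Reference trajectories for one exercise.

    Attributes
    ----------
    exercise_id : str
        Catalog id of the exercise this template encodes.
    grid : (n,) array
        Normalized time grid on [0, 1], ``n >= 8``.
    trajectories : dict
        Scored-joint key -> (n,) reference angle trajectory in degrees.
    triples : dict
        Scored-joint key -> :class:`~msfit.kinematics.JointTriple`.
    weights : dict
        Scored-joint key -> nonnegative weight; normalized to sum to 1.
    duration_s : float
        Nominal duration of one repetition, seconds (used by segmentation).
    meta : dict
        Free-form provenance (e.g. generator parameters); not used in scoring.
    """

    exercise_id: str
    grid: np.ndarray
    trajectories: dict[str, np.ndarray]
    triples: dict[str, JointTriple]
    weights: dict[str, float]
    duration_s: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) < MIN_TEMPLATE_SAMPLES:
            raise TemplateError(
                f"template grid needs >= {MIN_TEMPLATE_SAMPLES} samples"
            )
        if not self.trajectories:
            raise TemplateError("template has no scored joints")
        for key, traj in self.trajectories.items():
            traj = np.asarray(traj, dtype=float)
            self.trajectories[key] = traj
            if traj.shape != self.grid.shape:
                raise TemplateError(f"trajectory {key!r} does not match the grid")
            if np.ptp(traj) <= 0:
                raise TemplateError(f"trajectory {key!r} has zero range of motion")
            if key not in self.triples:
                raise TemplateError(f"no joint triple for scored key {key!r}")
        total = float(sum(self.weights.get(k, 0.0) for k in self.trajectories))
        if total <= 0 or any(w < 0 for w in self.weights.values()):
            raise TemplateError("weights must be nonnegative with positive sum")
        self.weights = {k: self.weights.get(k, 0.0) / total for k in self.trajectories}
        if self.duration_s <= 0:
            raise TemplateError("duration_s must be > 0")

    @property
    def rom(self) -> dict[str, float]:
        """Per-joint range of motion (max - min of the reference), degrees."""
        return {k: float(np.ptp(v)) for k, v in self.trajectories.items()}

    @property
    def dominant_key(self) -> str:
        """Scored joint with the largest weight (ties broken by key order)."""
        return max(self.trajectories, key=lambda k: (self.weights[k], k))


@dataclass(frozen=True)
class GestureScore:
    error_pct: float
    per_joint_error: Mapping[str, float]
    correct: bool


@dataclass
class ScoringConfig:
    """Tunables for the scoring pipeline; defaults match the shipped behavior."""

    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    alignment: Literal["linear", "dtw"] = "linear"
    filter_order: int = DEFAULT_FILTER_ORDER
    filter_cutoff_hz: float = DEFAULT_CUTOFF_HZ
    zero_phase: bool = False
    #: Allow a circular time shift between a detected repetition and the
    #: template (compensates segmentation phase and causal-filter lag).
    phase_align: bool = True


def _resample_to_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear time normalization: map a series onto the template grid."""
    n = len(values)
    if n < 2:
        raise ScoringError("user series must have at least 2 samples")
    u = np.linspace(0.0, 1.0, n)
    lo, hi = grid[0], grid[-1]
    return np.interp(grid, lo + u * (hi - lo), values)


def _dtw_mean_abs(user: np.ndarray, ref: np.ndarray) -> float:
    """Mean absolute deviation along the optimal DTW path (|.| local cost)."""
    n, m = len(user), len(ref)
    cost = np.abs(user[:, None] - ref[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        prev = acc[i - 1]
        cur = acc[i]
        row = cost[i - 1]
        for j in range(1, m + 1):
            cur[j] = row[j - 1] + min(prev[j], cur[j - 1], prev[j - 1])
    # Backtrack to get the path length for a proper mean.
    i, j, steps = n, m, 0
    while i > 1 or j > 1:
        moves = [
            (acc[i - 1, j - 1], i - 1, j - 1),
            (acc[i - 1, j], i - 1, j),
            (acc[i, j - 1], i, j - 1),
        ]
        _, i, j = min(moves)
        steps += 1
    return float(acc[n, m] / (steps + 1))


def _clean(series: AngleSeries) -> np.ndarray:
    """Angle values with NaN (degenerate-frame) gaps linearly interpolated."""
    x = np.asarray(series.angles, dtype=float)
    bad = ~np.isfinite(x)
    if bad.all():
        raise ScoringError("angle series has no valid frames")
    if bad.any():
        idx = np.arange(len(x))
        x = x.copy()
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def _joint_errors_at_shift(
    user_on_grid: dict[str, np.ndarray], template: GestureTemplate, shift: float
) -> dict[str, float]:
    rom = template.rom
    errors = {}
    for key, user in user_on_grid.items():
        ref = template.trajectories[key]
        if shift:
            span = template.grid[-1] - template.grid[0]
            u = template.grid[0] + np.mod(template.grid - template.grid[0] + shift * span, span)
            ref = np.interp(u, template.grid, ref)
        errors[key] = float(np.mean(np.abs(user - ref)) / rom[key] * 100.0)
    return errors


def gesture_error(
    user: Mapping[str, AngleSeries] | AngleSeries,
    template: GestureTemplate,
    alignment: Literal["linear", "dtw"] = "linear",
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    phase_align: bool = False,
) -> GestureScore:
    """Score one execution of a gesture against its template.

    Parameters
    ----------
    user : mapping or AngleSeries
        One angle series per scored joint key; a bare series is accepted for
        single-joint templates.
    alignment : {"linear", "dtw"}
        Linear time normalization (default) or dynamic time warping.
    threshold_pct : float
        Correctness cut; the verdict is ``error_pct < threshold_pct``
        (strict inequality).
    phase_align : bool
        If True (linear alignment only), additionally search over a circular
        time shift of the template and keep the best-matching offset. Used by
        the session pipeline, where repetition boundaries carry phase slack.
    """
    if isinstance(user, AngleSeries):
        if len(template.trajectories) != 1:
            raise ScoringError(
                "a bare AngleSeries is only accepted for single-joint templates"
            )
        user = {next(iter(template.trajectories)): user}

    missing = [k for k in template.trajectories if k not in user]
    if missing:
        raise ScoringError(f"missing scored joint series: {missing}")

    if alignment == "dtw":
        rom = template.rom
        per_joint = {
            k: _dtw_mean_abs(_clean(user[k]), template.trajectories[k])
            / rom[k]
            * 100.0
            for k in template.trajectories
        }
    elif alignment == "linear":
        on_grid = {
            k: _resample_to_grid(_clean(user[k]), template.grid)
            for k in template.trajectories
        }
        if phase_align:
            per_joint = _phase_aligned_errors(on_grid, template)
        else:
            per_joint = _joint_errors_at_shift(on_grid, template, 0.0)
    else:
        raise ParameterError(f"unknown alignment {alignment!r}")

    error_pct = float(sum(template.weights[k] * per_joint[k] for k in per_joint))
    return GestureScore(
        error_pct=error_pct,
        per_joint_error=per_joint,
        correct=error_pct < threshold_pct,
    )


def _phase_aligned_errors(
    on_grid: dict[str, np.ndarray], template: GestureTemplate
) -> dict[str, float]:
    """Per-joint errors at the weighted-error-minimizing circular shift."""

    def objective(shift: float) -> float:
        errs = _joint_errors_at_shift(on_grid, template, float(shift))
        return sum(template.weights[k] * errs[k] for k in errs)

    n = len(template.grid)
    shifts = np.arange(n) / n
    coarse = [objective(s) for s in shifts]
    best = int(np.argmin(coarse))
    lo = shifts[best] - 1.5 / n
    hi = shifts[best] + 1.5 / n
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    shift = float(res.x) if res.fun <= coarse[best] else float(shifts[best])
    return _joint_errors_at_shift(on_grid, template, np.mod(shift, 1.0))


def segment_repetitions(
    series: AngleSeries,
    template: GestureTemplate,
    boundary_shift_frames: int = 0,
) -> list[tuple[int, int]]:
    """Delimit repetitions at successive minima of the dominant joint's angle.

    The series is low-pass smoothed (zero-phase, so detected minima are not
    lagged), minima are found with a minimum separation of half the template
    duration, and segments — including the leading and trailing partials —
    are kept when their length lies between half and double the template
    duration. ``boundary_shift_frames`` moves interior boundaries left to
    undo a known upstream causal-filter delay.

    Returns an empty list when no repetition is found (e.g. constant input).
    """
    from scipy.signal import find_peaks

    x = np.asarray(series.angles, dtype=float)
    finite = np.isfinite(x)
    if len(x) < 4 or not finite.any():
        return []
    if not finite.all():
        idx = np.arange(len(x))
        x = x.copy()
        x[~finite] = np.interp(idx[~finite], idx[finite], x[finite])

    fs = series.fs
    rep_frames = max(2, int(round(template.duration_s * fs)))
    min_len = max(2, rep_frames // 2)
    max_len = 2 * rep_frames

    cutoff = min(DEFAULT_CUTOFF_HZ, 0.45 * fs)
    if len(x) >= 3 * DEFAULT_FILTER_ORDER:
        smooth = butterworth_lowpass(
            Series(values=x, fs=fs), cutoff=cutoff, zero_phase=True
        ).values
    else:
        smooth = x

    # Activity gate: a flat series has no repetitions to find.
    dominant_rom = template.rom[template.dominant_key]
    if np.ptp(smooth) < 0.1 * dominant_rom:
        return []

    minima, _ = find_peaks(
        -smooth, distance=min_len, prominence=0.25 * np.ptp(smooth)
    )
    boundaries = [int(m) - boundary_shift_frames for m in minima]
    boundaries = [b for b in boundaries if 0 < b < len(x) - 1]

    edges = [0] + boundaries + [len(x) - 1]
    segments = [
        (a, b) for a, b in zip(edges, edges[1:]) if min_len <= b - a <= max_len
    ]
    return segments


def score_session_exercise(
    seq: SkeletonSequence,
    template: GestureTemplate,
    config: ScoringConfig | None = None,
) -> list[GestureScore]:
    """Full pipeline: filter positions, compute angles, segment, score.

    Returns one :class:`GestureScore` per detected repetition; an empty
    sequence yields an empty list.
    """
    config = config or ScoringConfig()
    if len(seq) == 0:
        return []
    if len(seq) < 3 * config.filter_order:
        return []

    filtered = filter_positions(
        seq,
        order=config.filter_order,
        cutoff=config.filter_cutoff_hz,
        zero_phase=config.zero_phase,
    )
    all_series = {
        key: angle_series(filtered, triple) for key, triple in template.triples.items()
    }

    delay = (
        0
        if config.zero_phase
        else group_delay_frames(
            filtered.nominal_fs, config.filter_order, config.filter_cutoff_hz
        )
    )
    segments = segment_repetitions(
        all_series[template.dominant_key], template, boundary_shift_frames=delay
    )

    scores = []
    for start, end in segments:
        chunk = {
            key: replace(
                s,
                angles=s.angles[start : end + 1],
                timestamps=None,
            )
            for key, s in all_series.items()
        }
        scores.append(
            gesture_error(
                chunk,
                template,
                alignment=config.alignment,
                threshold_pct=config.threshold_pct,
                phase_align=config.phase_align and config.alignment == "linear",
            )
        )
    return scores


def session_mean_error(scores: list[GestureScore]) -> float:
    """Session-aggregate error: mean of per-repetition error percentages."""
    if not scores:
        return float("nan")
    return float(np.mean([s.error_pct for s in scores]))


def estimate_amplitude_scale(
    seq: SkeletonSequence,
    template: GestureTemplate,
    config: ScoringConfig | None = None,
    key: str | None = None,
    method: Literal["fit", "rom"] = "fit",
) -> float:
    """Estimate the execution amplitude scale of the dominant scored joint.

    Detected repetitions are resampled onto the template grid and averaged
    into one measured cycle. With ``method="fit"`` (default) the scale is the
    least-squares amplitude of the reference shape within the measured cycle —
    i.e. the ROM ratio of the best-fitting rescaled reference, which is robust
    to position noise. ``method="rom"`` uses the raw ratio of the measured
    cycle's range of motion to the template ROM.
    """
    config = config or ScoringConfig()
    key = key or template.dominant_key
    filtered = filter_positions(
        seq,
        order=config.filter_order,
        cutoff=config.filter_cutoff_hz,
        zero_phase=config.zero_phase,
    )
    series = angle_series(filtered, template.triples[key])
    delay = 0 if config.zero_phase else group_delay_frames(
        filtered.nominal_fs, config.filter_order, config.filter_cutoff_hz
    )
    segments = segment_repetitions(series, template, boundary_shift_frames=delay)
    if not segments:
        raise ScoringError("no repetitions detected; cannot estimate amplitude")
    cycles = [
        _resample_to_grid(_clean(replace(series, angles=series.angles[a : b + 1], timestamps=None)), template.grid)
        for a, b in segments
    ]
    mean_cycle = np.mean(cycles, axis=0)
    if method == "rom":
        return float(np.ptp(mean_cycle) / template.rom[key])
    # Phase-invariant least-squares amplitude: peak of the circular
    # cross-correlation with the reference shape, parabolically refined so a
    # sub-sample phase residual (e.g. causal-filter lag) does not bias it.
    # Both cycles are band-limited to their leading harmonics first: one
    # repetition of a smooth gesture has little energy above ~10 cycles/rep,
    # while measurement noise is broadband.
    ref = template.trajectories[key]
    c = mean_cycle[:-1] - mean_cycle[:-1].mean()  # drop duplicated endpoint
    r = ref[:-1] - ref[:-1].mean()
    m = len(r)
    keep = min(10, (m - 1) // 2)
    fc_, fr_ = np.fft.fft(c), np.fft.fft(r)
    mask = np.zeros(m)
    mask[: keep + 1] = 1.0
    mask[m - keep :] = 1.0
    fc_, fr_ = fc_ * mask, fr_ * mask
    r = np.real(np.fft.ifft(fr_))
    corr = np.real(np.fft.ifft(fc_ * np.conj(fr_)))
    k = int(np.argmax(corr))
    y0, y1, y2 = corr[k - 1], corr[k], corr[(k + 1) % len(corr)]
    denom = y0 - 2 * y1 + y2
    peak = y1 if denom == 0 else y1 - (y0 - y2) ** 2 / (8 * denom)
    return float(peak / np.dot(r, r))


# ---------------------------------------------------------------------------
# Template file I/O: CSV with a normalized-time column plus one angle column
# per scored key, and a small YAML sidecar for triples/weights/duration.
# ---------------------------------------------------------------------------


def write_template(template: GestureTemplate, csv_path: str) -> None:
    import pandas as pd
    import yaml

    data = {"u": template.grid}
    for key, traj in template.trajectories.items():
        data[key] = traj
    pd.DataFrame(data).to_csv(csv_path, index=False)
    sidecar = {
        "exercise_id": template.exercise_id,
        "duration_s": float(template.duration_s),
        "weights": {k: float(v) for k, v in template.weights.items()},
        "triples": {
            k: [t.proximal, t.center, t.distal] for k, t in template.triples.items()
        },
    }
    with open(csv_path + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_template(csv_path: str) -> GestureTemplate:
    import pandas as pd
    import yaml

    df = pd.read_csv(csv_path)
    if "u" not in df.columns:
        raise TemplateError("template CSV needs a normalized-time column 'u'")
    with open(csv_path + ".yaml") as fh:
        sidecar = yaml.safe_load(fh)
    keys = [c for c in df.columns if c != "u"]
    return GestureTemplate(
        exercise_id=sidecar["exercise_id"],
        grid=df["u"].to_numpy(),
        trajectories={k: df[k].to_numpy() for k in keys},
        triples={k: JointTriple(*sidecar["triples"][k]) for k in keys},
        weights={k: sidecar["weights"].get(k, 1.0) for k in keys},
        duration_s=sidecar.get("duration_s", 2.0),
    )
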