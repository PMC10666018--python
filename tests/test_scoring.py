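import numpy as np
import pytest

from msfit.errors import ScoringError, TemplateError
from msfit.kinematics import DEFAULT_TRIPLES, AngleSeries, angle_series
from msfit.preprocessing import filter_positions, group_delay_frames
from msfit.scoring import (
    GestureTemplate,
    ScoringConfig,
    gesture_error,
    read_template,
    score_session_exercise,
    segment_repetitions,
    session_mean_error,
    write_template,
)
from msfit.skeleton import SkeletonSequence
from msfit.synthetic import (
    GeneratorParams,
    generate_execution,
    generate_template,
    true_boundaries,
)

HIP = DEFAULT_TRIPLES["hip_left"]


def sin_template(theta0=100.0, amplitude=30.0, n=100):
    grid = np.linspace(0.0, 1.0, n)
    traj = theta0 - amplitude * np.cos(2 * np.pi * grid)
    return GestureTemplate(
        exercise_id="test",
        grid=grid,
        trajectories={"hip_left": traj},
        triples={"hip_left": HIP},
        weights={"hip_left": 1.0},
        duration_s=2.0,
    )


def as_series(values, fs=50.0):
    return AngleSeries(triple=HIP, angles=np.asarray(values), fs=fs)


class TestTemplateInvariants:
    def test_min_samples(self):
        with pytest.raises(TemplateError):
            sin_template(n=7)

    def test_zero_rom_rejected(self):
        grid = np.linspace(0, 1, 20)
        with pytest.raises(TemplateError):
            GestureTemplate(
                exercise_id="t",
                grid=grid,
                trajectories={"hip_left": np.full(20, 90.0)},
                triples={"hip_left": HIP},
                weights={"hip_left": 1.0},
            )

    def test_weights_normalized(self):
        t = sin_template()
        assert sum(t.weights.values()) == pytest.approx(1.0)

    def test_negative_weight_rejected(self):
        grid = np.linspace(0, 1, 20)
        with pytest.raises(TemplateError):
            GestureTemplate(
                exercise_id="t",
                grid=grid,
                trajectories={"hip_left": 100 - 30 * np.cos(2 * np.pi * grid)},
                triples={"hip_left": HIP},
                weights={"hip_left": -1.0},
            )

    def test_rom_is_max_minus_min(self):
        # odd sample count puts grid points exactly on the extrema
        assert sin_template(amplitude=30.0, n=101).rom["hip_left"] == pytest.approx(60.0)


class TestGestureError:
    def test_identity_is_exactly_zero(self):
        t = sin_template()
        score = gesture_error(as_series(t.trajectories["hip_left"]), t)
        assert score.error_pct == 0.0
        assert score.correct is True

    def test_error_exactly_five_is_incorrect(self):
        # Exact-arithmetic construction: trajectory values quantized to
        # 1/1024 make adding 2.0 exact, the grid includes mid-cycle so the
        # ROM is exactly 40, and 2.0/40*100 == 5.0 in IEEE doubles.
        grid = np.linspace(0.0, 1.0, 65)
        traj = np.round((100.0 - 20.0 * np.cos(2 * np.pi * grid)) * 1024) / 1024
        t = GestureTemplate(
            exercise_id="exact",
            grid=grid,
            trajectories={"hip_left": traj},
            triples={"hip_left": HIP},
            weights={"hip_left": 1.0},
        )
        assert t.rom["hip_left"] == 40.0
        score = gesture_error(as_series(traj + 2.0), t)
        assert score.error_pct == 5.0
        assert score.correct is False

    def test_threshold_strictness_generic(self):
        t = sin_template()
        user = t.trajectories["hip_left"] + 2.0
        err = gesture_error(as_series(user), t).error_pct
        at_threshold = gesture_error(as_series(user), t, threshold_pct=err)
        assert at_threshold.correct is False
        just_above = gesture_error(as_series(user), t, threshold_pct=err + 1e-9)
        assert just_above.correct is True

    def test_closed_form_amplitude_scaling(self):
        # Independent oracle: dense quadrature of |0.1*A*sin| / (2A) * 100
        # over one period, compared to the analytic (2/pi)*|s-1|/2*100.
        A, s = 30.0, 1.1
        x = np.linspace(0, 2 * np.pi, 200_001)
        quadrature = np.trapezoid(np.abs((s - 1) * A * np.sin(x)), x) / (
            2 * np.pi
        ) / (2 * A) * 100
        analytic = (2 / np.pi) * abs(s - 1) / 2 * 100
        assert quadrature == pytest.approx(analytic, abs=1e-6)

        t = sin_template(amplitude=A, n=2000)
        user = 100.0 - s * A * np.cos(2 * np.pi * np.linspace(0, 1, 2000))
        score = gesture_error(as_series(user), t)
        assert score.error_pct == pytest.approx(analytic, abs=0.05)
        assert score.correct is True  # ~3.18% < 5%

    def test_scale_1_5_incorrect(self):
        A, s = 30.0, 1.5
        t = sin_template(amplitude=A, n=2000)
        user = 100.0 - s * A * np.cos(2 * np.pi * np.linspace(0, 1, 2000))
        score = gesture_error(as_series(user), t)
        assert score.error_pct == pytest.approx(15.915, abs=0.1)
        assert score.correct is False

    def test_monotone_in_amplitude_scale(self):
        t = sin_template(n=500)
        grid = np.linspace(0, 1, 500)
        errors = []
        for s in np.arange(1.0, 1.501, 0.05):
            user = 100.0 - s * 30.0 * np.cos(2 * np.pi * grid)
            errors.append(gesture_error(as_series(user), t).error_pct)
        assert all(b >= a - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_weight_convexity_two_joints(self):
        grid = np.linspace(0, 1, 100)
        traj_a = 100 - 30 * np.cos(2 * np.pi * grid)
        traj_b = 90 - 20 * np.cos(2 * np.pi * grid)
        t = GestureTemplate(
            exercise_id="two",
            grid=grid,
            trajectories={"hip_left": traj_a, "knee_left": traj_b},
            triples={
                "hip_left": HIP,
                "knee_left": DEFAULT_TRIPLES["knee_left"],
            },
            weights={"hip_left": 0.7, "knee_left": 0.3},
        )
        user = {
            "hip_left": as_series(traj_a + 3.0),
            "knee_left": as_series(traj_b + 1.0),
        }
        score = gesture_error(user, t)
        per = score.per_joint_error
        lo, hi = sorted(per.values())
        assert lo <= score.error_pct <= hi
        expected = 0.7 * per["hip_left"] + 0.3 * per["knee_left"]
        assert score.error_pct == pytest.approx(expected)

    def test_missing_scored_joint_raises(self):
        grid = np.linspace(0, 1, 100)
        t = GestureTemplate(
            exercise_id="two",
            grid=grid,
            trajectories={
                "hip_left": 100 - 30 * np.cos(2 * np.pi * grid),
                "knee_left": 90 - 20 * np.cos(2 * np.pi * grid),
            },
            triples={
                "hip_left": HIP,
                "knee_left": DEFAULT_TRIPLES["knee_left"],
            },
            weights={"hip_left": 0.5, "knee_left": 0.5},
        )
        with pytest.raises(ScoringError):
            gesture_error({"hip_left": as_series(np.ones(50) * 100)}, t)

    def test_dtw_identity_zero(self):
        t = sin_template()
        score = gesture_error(
            as_series(t.trajectories["hip_left"]), t, alignment="dtw"
        )
        assert score.error_pct == pytest.approx(0.0, abs=1e-12)

    def test_dtw_tolerates_speed_variation(self):
        t = sin_template(n=100)
        # same gesture traced at non-uniform speed
        u = np.linspace(0, 1, 160) ** 1.3
        user = 100.0 - 30.0 * np.cos(2 * np.pi * u)
        dtw = gesture_error(as_series(user), t, alignment="dtw").error_pct
        linear = gesture_error(as_series(user), t, alignment="linear").error_pct
        assert dtw < linear


class TestSegmentation:
    def test_three_reps_three_segments(self):
        params = GeneratorParams(exercise_id="one_leg_circle_1", n_reps=3)
        template, stream = generate_template(params)
        series = angle_series(filter_positions(stream), HIP)
        delay = group_delay_frames(params.fs)
        segments = segment_repetitions(series, template, boundary_shift_frames=delay)
        truth = true_boundaries(params)
        assert len(segments) == 3
        for (a, b), ta, tb in zip(segments, truth, truth[1:]):
            assert abs(a - ta) <= 2
            assert abs(b - tb) <= 2

    def test_constant_series_no_segments(self):
        t = sin_template()
        series = as_series(np.full(120, 100.0), fs=30.0)
        assert segment_repetitions(series, t) == []

    def test_single_rep_single_segment(self):
        params = GeneratorParams(exercise_id="one_leg_circle_1", n_reps=1)
        template, stream = generate_template(params)
        series = angle_series(stream, HIP)
        assert len(segment_repetitions(series, template)) == 1


class TestSessionPipeline:
    def test_five_clean_reps_all_correct_under_1pct(self, hip_template_stream):
        template, stream = hip_template_stream
        scores = score_session_exercise(stream, template)
        assert len(scores) == 5
        assert all(s.correct for s in scores)
        assert all(s.error_pct < 1.0 for s in scores)

    def test_scaled_1_5_all_incorrect(self, hip_template_stream):
        template, _ = hip_template_stream
        stream = generate_execution(template, amplitude_scale=1.5)
        scores = score_session_exercise(stream, template)
        assert len(scores) == 5
        assert all(not s.correct for s in scores)
        assert all(s.error_pct > 5.0 for s in scores)
        # closed form predicts ~15.9%
        assert session_mean_error(scores) == pytest.approx(15.915, abs=0.5)

    def test_empty_sequence_empty_scores(self, hip_template_stream):
        template, _ = hip_template_stream
        empty = SkeletonSequence(frames=[], nominal_fs=30.0)
        assert score_session_exercise(empty, template) == []

    def test_determinism_bit_identical(self, hip_template_stream):
        template, _ = hip_template_stream
        stream = generate_execution(template, amplitude_scale=1.2, noise_sd_m=0.003, seed=9)
        a = score_session_exercise(stream, template)
        b = score_session_exercise(stream, template)
        assert [s.error_pct for s in a] == [s.error_pct for s in b]
        assert [s.correct for s in a] == [s.correct for s in b]

    def test_multi_joint_exercise_pipeline(self):
        params = GeneratorParams(exercise_id="scapola_position_1", n_reps=4)
        template, stream = generate_template(params)
        scores = score_session_exercise(stream, template)
        assert len(scores) == 4
        assert all(s.error_pct < 1.0 for s in scores)
        assert set(scores[0].per_joint_error) == {"shoulder_left", "shoulder_right"}


class TestTemplateIO:
    def test_round_trip(self, tmp_path, hip_template_stream):
        template, _ = hip_template_stream
        path = str(tmp_path / "template.csv")
        write_template(template, path)
        back = read_template(path)
        assert back.exercise_id == template.exercise_id
        np.testing.assert_allclose(back.grid, template.grid)
        for key in template.trajectories:
            np.testing.assert_allclose(
                back.trajectories[key], template.trajectories[key]
            )
            assert back.triples[key] == template.triples[key]
            assert back.weights[key] == pytest.approx(template.weights[key])
        assert back.duration_s == template.duration_s
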