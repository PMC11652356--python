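"""Barycentric iris coordinates, misalignment drift and diplopia reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgce import (
    AlignmentSpec,
    SyntheticSpec,
    TranscriptWords,
    Word,
    alignment_drift,
    barycentric_coordinate,
    detect_diplopia_report,
    gen_alignment_session,
    misalignment_series,
)
from mgce.errors import InsufficientDataError, LowResolutionError

from conftest import make_frame, make_series


def _eye_frame(inner=100.0, outer=140.0, iris=120.0, eye="L"):
    return make_frame(0.0, {
        f"eye_inner_{eye}": (inner, 220.0, 1.0),
        f"eye_outer_{eye}": (outer, 220.0, 1.0),
        f"iris_center_{eye}": (iris, 220.0, 1.0),
    })


class TestBarycentric:
    def test_midpoint_is_half(self):
        assert barycentric_coordinate(_eye_frame(), "L") == pytest.approx(0.5)

    def test_three_quarters(self):
        assert barycentric_coordinate(_eye_frame(iris=130.0), "L") == pytest.approx(0.75)

    def test_translation_and_scale_invariance_example(self):
        b0 = barycentric_coordinate(_eye_frame(), "L")
        b1 = barycentric_coordinate(
            _eye_frame(inner=(100 + 57) * 2, outer=(140 + 57) * 2, iris=(120 + 57) * 2), "L"
        )
        assert b1 == pytest.approx(b0)

    @settings(deadline=None, max_examples=100)
    @given(
        inner=st.floats(-500, 500),
        width=st.floats(10, 300),
        frac=st.floats(0, 1),
        shift=st.floats(-1000, 1000),
        scale=st.floats(0.5, 20),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_invariance_on_random_geometries(self, inner, width, frac, shift, scale, sign):
        outer = inner + sign * width
        iris = inner + sign * width * frac
        b0 = barycentric_coordinate(_eye_frame(inner, outer, iris), "L")
        b1 = barycentric_coordinate(
            _eye_frame(inner * scale + shift, outer * scale + shift, iris * scale + shift), "L"
        )
        assert b0 == pytest.approx(frac, abs=1e-6)
        assert b1 == pytest.approx(b0, abs=1e-6)

    def test_narrow_eye_unresolvable(self):
        with pytest.raises(LowResolutionError):
            barycentric_coordinate(_eye_frame(outer=102.0, iris=101.0), "L")

    def test_missing_iris_raises(self):
        f = make_frame(0.0, {"eye_inner_L": (0.0, 0.0, 1.0), "eye_outer_L": (40.0, 0.0, 1.0)})
        with pytest.raises(InsufficientDataError):
            barycentric_coordinate(f, "L")


def _binocular_series(iris_L_x, iris_R_x, n=None, fps=25.0):
    n = n or len(iris_L_x)
    t = np.arange(n) / fps
    pts = {
        # left eye on image right: inner 320, outer 360
        "eye_inner_L": (np.full(n, 320.0), np.full(n, 220.0)),
        "eye_outer_L": (np.full(n, 360.0), np.full(n, 220.0)),
        "iris_center_L": (np.asarray(iris_L_x, float), np.full(n, 220.0)),
        # right eye on image left: inner 280, outer 240
        "eye_inner_R": (np.full(n, 280.0), np.full(n, 220.0)),
        "eye_outer_R": (np.full(n, 240.0), np.full(n, 220.0)),
        "iris_center_R": (np.asarray(iris_R_x, float), np.full(n, 220.0)),
    }
    return make_series(t, pts, fps=fps, exercise="diplopia")


class TestMisalignment:
    def test_centered_irises_give_zero(self):
        s = _binocular_series(np.full(100, 340.0), np.full(100, 260.0))
        m = misalignment_series(s)
        assert all(abs(x.misalignment) < 1e-12 for x in m)

    def test_conjugate_gaze_cancels(self):
        # both irises co-move +8 px in image space (yoked rightward gaze)
        g = 8.0 * np.sin(np.linspace(0, 6, 200))
        s = _binocular_series(340.0 + g, 260.0 + g)
        m = misalignment_series(s)
        assert max(abs(x.misalignment) for x in m) < 1e-12

    def test_one_eye_drifting_ramps(self):
        n = 200
        drift = np.linspace(0, 0.1, n)  # barycentric units
        s = _binocular_series(340.0 - 40.0 * drift, np.full(n, 260.0))
        m = misalignment_series(s)
        assert m[0].misalignment == pytest.approx(0.0, abs=1e-9)
        assert m[-1].misalignment == pytest.approx(0.1, abs=1e-9)

    def test_unusable_eye_named_in_error(self):
        t = np.arange(100) / 25.0
        pts = {
            "eye_inner_L": (np.full(100, 320.0), np.full(100, 220.0)),
            "eye_outer_L": (np.full(100, 360.0), np.full(100, 220.0)),
            "iris_center_L": (np.full(100, 340.0), np.full(100, 220.0)),
        }
        with pytest.raises(InsufficientDataError, match="eye R"):
            misalignment_series(make_series(t, pts, exercise="diplopia"))


class TestAlignmentDrift:
    def test_constant_zero_has_zero_drift(self):
        s = _binocular_series(np.full(200, 340.0), np.full(200, 260.0))
        res = alignment_drift(misalignment_series(s))
        assert res.drift_total == pytest.approx(0.0, abs=1e-12)
        assert res.flag == "indeterminate"  # below the 0.05 floor

    def test_linear_ramp_recovers_total(self):
        n = 1500
        drift = np.linspace(0, 0.10, n)
        s = _binocular_series(340.0 - 40.0 * drift, np.full(n, 260.0))
        res = alignment_drift(misalignment_series(s))
        assert res.drift_total == pytest.approx(0.10, abs=0.005)
        assert res.flag == "normal"

    def test_below_floor_is_indeterminate(self):
        n = 1500
        drift = np.linspace(0, 0.03, n)
        s = _binocular_series(340.0 - 40.0 * drift, np.full(n, 260.0))
        assert alignment_drift(misalignment_series(s)).flag == "indeterminate"

    def test_slope_equals_ols_oracle(self):
        rng = np.random.default_rng(5)
        n = 500
        m = rng.normal(0, 0.02, n)
        s = _binocular_series(340.0 - 40.0 * m, np.full(n, 260.0))
        samples = misalignment_series(s)
        res = alignment_drift(samples)
        t = np.array([x.t for x in samples])
        vals = np.array([x.misalignment for x in samples])
        A = np.vstack([t, np.ones(n)]).T
        slope = np.linalg.lstsq(A, vals, rcond=None)[0][0]
        assert res.drift_total == pytest.approx(slope * (t[-1] - t[0]), rel=1e-6, abs=1e-9)


class TestGeneratorRoundTrip:
    def test_true_drift_recovered(self):
        s, _ = gen_alignment_session(SyntheticSpec(
            seed=4, alignment=AlignmentSpec(true_drift=0.10)))
        res = alignment_drift(misalignment_series(s))
        assert res.drift_total == pytest.approx(0.10, abs=0.01)

    def test_conjugate_sessions_near_zero(self):
        worst = 0.0
        for seed in range(20):
            s, _ = gen_alignment_session(SyntheticSpec(
                seed=seed, alignment=AlignmentSpec(conjugate_gaze=True)))
            worst = max(worst, abs(alignment_drift(misalignment_series(s)).drift_total))
        assert worst < 0.01

    def test_determinism(self):
        a, _ = gen_alignment_session(SyntheticSpec(seed=9))
        b, _ = gen_alignment_session(SyntheticSpec(seed=9))
        assert a == b


class TestDiplopiaReport:
    def _tr(self, items):
        return TranscriptWords(words=tuple(Word(text=w, start=s, end=e) for w, s, e in items))

    def test_single_keyword_match(self):
        tr = self._tr([("I", 40.0, 40.2), ("see", 40.2, 40.5),
                       ("double", 41.2, 41.5), ("vision", 41.5, 41.9)])
        assert detect_diplopia_report(tr) == [41.2]

    def test_no_keyword_empty(self):
        tr = self._tr([("all", 0.0, 0.2), ("clear", 0.3, 0.5)])
        assert detect_diplopia_report(tr) == []

    def test_phrase_over_adjacent_words(self):
        tr = self._tr([("I", 0.0, 0.1), ("see", 0.2, 0.3), ("two", 0.4, 0.5),
                       ("of", 0.6, 0.7), ("everything", 0.8, 1.2)])
        assert detect_diplopia_report(tr) == [0.4]

    def test_case_and_punctuation_insensitive(self):
        tr = self._tr([("Double!", 5.0, 5.3)])
        assert detect_diplopia_report(tr) == [5.0]
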