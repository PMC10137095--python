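import numpy as np
import pytest

from ststp.eyes import (DegenerateGeometryError, compute_ear,
                        confidence_matrix, detect_blinks, ear_series,
                        eyebrow_offsets, landmark_error, locate_iris,
                        r_squared)


def ear_oracle(pts):
    """Literal restatement of the aspect-ratio formula."""
    l1, l2, l3, l4, l5, l6 = [np.asarray(p, float) for p in pts]
    return (np.linalg.norm(l2 - l6) + np.linalg.norm(l3 - l5)) \
        / (2 * np.linalg.norm(l1 - l4))


def _random_eye(rng):
    pts = rng.normal(0, 3, (6, 2))
    while np.linalg.norm(pts[0] - pts[3]) < 0.5:
        pts = rng.normal(0, 3, (6, 2))
    return pts


class TestEAR:
    def test_symmetric_landmarks_give_half(self):
        pts = [(0, 0), (1, 1), (3, 1), (4, 0), (3, -1), (1, -1)]
        assert compute_ear(np.array(pts, float)) == pytest.approx(0.5)

    def test_closed_eye_collapses_to_zero(self):
        pts = np.array([(0, 0), (1, 0), (3, 0), (4, 0), (3, 0), (1, 0)], float)
        assert compute_ear(pts) == 0.0

    def test_matches_formula_oracle_on_random_landmarks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pts = _random_eye(rng)
            assert compute_ear(pts) == pytest.approx(ear_oracle(pts),
                                                     abs=1e-12)

    def test_invariant_to_rigid_motion_and_scale(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pts = _random_eye(rng)
            ref = compute_ear(pts)
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            s = rng.uniform(0.2, 5.0)
            moved = s * pts @ R.T + rng.normal(0, 10, 2)
            assert compute_ear(moved) == pytest.approx(ref, rel=1e-9)

    def test_zero_width_eye_is_degenerate(self):
        pts = np.zeros((6, 2))
        with pytest.raises(DegenerateGeometryError):
            compute_ear(pts)

    def test_series_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        stack = np.stack([_random_eye(rng) for _ in range(8)])
        series = ear_series(stack)
        for t in range(8):
            assert series[t] == pytest.approx(compute_ear(stack[t]))


class TestBlinks:
    def test_constant_open_series_has_no_blinks(self):
        assert detect_blinks(np.full(20, 0.35)) == []

    def test_single_two_frame_blink_detected(self):
        events = detect_blinks(np.array([0.35, 0.1, 0.1, 0.35]),
                               threshold=0.2, min_frames=2)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (1, 2)
        assert events[0].duration == 2

    def test_ground_truth_blinks_recovered_from_landmarks(self, small_subject):
        series = ear_series(small_subject.landmarks.left_eye)
        events = detect_blinks(series, threshold=0.2, min_frames=2)
        assert len(events) == small_subject.truth["blink_count"]

    def test_count_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        series = np.clip(rng.normal(0.3, 0.12, 200), 0, None)
        counts = [len(detect_blinks(series, threshold=t, min_frames=2))
                  for t in (0.1, 0.2, 0.3, 0.4)]
        # higher threshold can merge runs but never yields fewer below-
        # threshold frames; counts of maximal runs may merge, so compare
        # total below-threshold coverage instead of raw event counts
        coverage = [sum(e.duration for e in
                        detect_blinks(series, threshold=t, min_frames=2))
                    for t in (0.1, 0.2, 0.3, 0.4)]
        assert coverage == sorted(coverage)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_blinks(np.array([0.3]), min_frames=2)


class TestIris:
    def _disc_patch(self, cy=15, cx=15, r=6, size=30):
        rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        patch = np.full((size, size), 220.0)
        patch[(rr - cy) ** 2 + (cc - cx) ** 2 <= r ** 2] = 40.0
        return patch

    def test_dark_disc_located_within_two_px(self):
        res = locate_iris(self._disc_patch(), radius_range=(3, 10))
        assert res is not None
        cy, cx, r = res
        assert abs(cy - 15) <= 2 and abs(cx - 15) <= 2 and abs(r - 6) <= 2

    def test_blank_patch_yields_null(self):
        assert locate_iris(np.full((20, 20), 128.0)) is None

    def test_closed_eye_rendering_yields_null(self):
        # a closed eye shows only the lid line, no circular iris boundary
        patch = np.full((30, 30), 220.0)
        patch[14:16, 6:24] = 40.0
        assert locate_iris(patch, radius_range=(3, 10)) is None

    def test_tiny_patch_rejected(self):
        with pytest.raises(ValueError):
            locate_iris(np.zeros((4, 4)))


class TestErrorMetrics:
    def test_perfect_detection_gives_zero(self):
        pts = np.arange(12.0).reshape(6, 2)
        assert landmark_error(pts, pts, inter_ocular=3.0) == 0.0

    def test_uniform_displacement_by_u_gives_hundred(self):
        rng = np.random.default_rng(4)
        tpl = rng.normal(size=(9, 2))
        U = 2.5
        pred = tpl + [U, 0.0]
        assert landmark_error(pred, tpl, U) == pytest.approx(100.0)

    def test_matches_hand_computed_sum(self):
        rng = np.random.default_rng(5)
        tpl = rng.normal(size=(7, 2))
        pred = tpl + rng.normal(0, 0.5, (7, 2))
        U = 1.7
        expected = 100.0 / (7 * U) * sum(
            np.linalg.norm(pred[i] - tpl[i]) for i in range(7))
        assert landmark_error(pred, tpl, U) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_non_positive_interocular_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError):
            landmark_error(pts, pts, 0.0)

    @pytest.mark.parametrize("fitted_kind, expected", [
        ("observed", 1.0), ("mean", 0.0)])
    def test_r_squared_closed_forms(self, fitted_kind, expected):
        obs = np.array([1.0, 2.0, 4.0, 3.0])
        fitted = obs if fitted_kind == "observed" else np.full(4, obs.mean())
        assert r_squared(obs, fitted) == pytest.approx(expected)

    def test_r_squared_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        obs = rng.normal(size=50)
        fit = obs + rng.normal(0, 0.3, 50)
        expected = 1 - np.sum((obs - fit) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert r_squared(obs, fit) == pytest.approx(expected, abs=1e-12)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared(np.ones(5), np.zeros(5))


class TestConfidenceMatrix:
    def test_self_fit_is_one(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        table = confidence_matrix({"a": x, "b": rng.normal(size=100)})
        assert table.loc["a", "a"] == pytest.approx(1.0)

    def test_exact_linear_relation_scores_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        table = confidence_matrix({"x": x, "y": 3.0 * x - 2.0})
        assert table.loc["y", "x"] == pytest.approx(1.0)

    def test_independent_series_score_near_zero(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table = confidence_matrix({"a": rng.normal(size=1000),
                                       "b": rng.normal(size=1000)})
            assert table.loc["b", "a"] < 0.05

    def test_symmetry_for_linearly_related_pairs(self):
        # a straight-line fit of y on x and of x on y share the same R^2
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = 2 * x + rng.normal(0, 0.4, 200)
        t = confidence_matrix({"x": x, "y": y})
        t_swapped = confidence_matrix({"y": y, "x": x})
        assert t.loc["y", "x"] == pytest.approx(t_swapped.loc["x", "y"],
                                                abs=1e-9)

    def test_constant_series_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            confidence_matrix({"ok": np.arange(5.0), "flat": np.ones(5)})


class TestEyebrow:
    def test_offsets_invariant_to_global_translation(self, small_subject):
        lm = small_subject.landmarks
        base = eyebrow_offsets(lm.brows, lm.left_eye, lm.right_eye)
        shift = np.array([7.0, -3.0])
        moved = eyebrow_offsets(lm.brows + shift, lm.left_eye + shift,
                                lm.right_eye + shift)
        assert np.allclose(base, moved, atol=1e-9)
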