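"""Worm detection, the dead-or-alive criterion, tracking and rectification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormvib import (
    BehaviourConfig,
    PlateConfig,
    StimulusSchedule,
    alive_call,
    build_automatic_curve,
    build_reference_curve,
    detect_worms,
    rectify_curve,
    render_frame,
    simulate_condition,
)
from wormvib.detect import DetectParams, ImageSequence
from wormvib.lifespan import SurvivalCurve, WormDetection
from wormvib.pipeline import analyze_condition, default_detect_params


def _straight_worm(row, col0, n=10, length=16.0):
    return np.stack([np.full(n, float(row)), np.linspace(col0, col0 + length, n)], axis=1)


def _seq(frames, **kw):
    return ImageSequence(np.stack(frames), **kw)


PARAMS = default_detect_params()


class TestDetectWorms:
    def test_separated_worms_all_detected(self, clean_plate):
        lines = [_straight_worm(40 + 20 * i, 60) for i in range(5)]
        frame = render_frame(lines, clean_plate)
        dets = detect_worms([_seq([frame, frame])], PARAMS)
        assert len(dets) == 5
        assert all(not d.moved_in_sequence for d in dets)

    def test_worm_touching_shadow_zone_hidden(self, small_plate):
        # a body merged with a dark wall arc is not a worm-sized blob
        from wormvib.simulate import shadow_mask

        sh = shadow_mask(small_plate)
        rr, cc = np.nonzero(sh)
        pts = _straight_worm(rr[len(rr) // 2], cc[len(cc) // 2] - 8)
        frame = render_frame([pts], small_plate)
        dets = detect_worms([_seq([frame, frame])], PARAMS, max_area=200)
        assert dets == []

    def test_overlapping_worms_merge_into_one_blob(self, clean_plate):
        a = _straight_worm(90, 80)
        b = np.stack([np.linspace(82, 98, 10), np.full(10, 88.0)], axis=1)
        frame = render_frame([a, b], clean_plate)
        dets = detect_worms([_seq([frame, frame])], PARAMS, max_area=400)
        assert len(dets) == 1  # documented limitation

    def test_empty_plate_empty_list(self, clean_plate):
        frame = render_frame([], clean_plate)
        assert detect_worms([_seq([frame, frame])], PARAMS) == []

    def test_mover_flagged_by_motion_pixels(self, clean_plate):
        f0 = render_frame([_straight_worm(90, 60)], clean_plate)
        f1 = render_frame([_straight_worm(90, 66)], clean_plate)
        dets = detect_worms([_seq([f0, f1])], PARAMS)
        assert len(dets) == 1 and dets[0].moved_in_sequence


class TestAliveCall:
    def _det(self, centroid=(50.0, 50.0), moved=False, offsets=None):
        if offsets is None:
            offsets = np.array([[0, -1], [0, 0], [0, 1]])
        return WormDetection(0, 2, 0, centroid, len(offsets), offsets, moved)

    def test_sequence_movement_is_alive(self):
        det = self._det(moved=True)
        assert alive_call(det, (50.0, 50.0), det.mask_offsets, True)

    def test_unchanged_position_and_shape_is_dead(self):
        det = self._det()
        assert not alive_call(det, (50.0, 50.0), det.mask_offsets.copy(), False)

    def test_position_change_is_alive(self):
        det = self._det(centroid=(50.0, 58.0))
        assert alive_call(det, (50.0, 50.0), det.mask_offsets, False)

    def test_shape_change_is_alive(self):
        det = self._det()
        prev = np.array([[0, -1], [0, 0], [1, 1], [1, 2]])
        assert alive_call(det, (50.0, 50.0), prev, False)

    def test_hidden_worm_is_dead_and_no_history_falls_back(self):
        assert not alive_call(None, (0.0, 0.0), None, True)
        det = self._det(moved=True)
        assert alive_call(det, None, None, True)
        assert not alive_call(self._det(), None, None, False)

    def test_vibrotaxis_responder_counts_via_after_phase(self):
        # still in "before", movement evidence comes from the after sequence
        det = self._det()
        assert alive_call(det, (50.0, 50.0), det.mask_offsets, moved_any_phase=True)


def _day_dets(day, specs):
    """specs: list of (centroid, moved) -> {'before': [WormDetection...]}"""
    offsets = np.array([[0, -1], [0, 0], [0, 1]])
    dets = [
        WormDetection(0, day, i, c, 3, offsets, m) for i, (c, m) in enumerate(specs)
    ]
    return {"before": dets}


class TestCurves:
    def test_automatic_curve_dips_then_rises(self):
        # one worm motionless on days 10-11, moving again on day 12
        pos = (40.0, 40.0)
        per_day = {
            9: _day_dets(9, [(pos, True)]),
            10: _day_dets(10, [(pos, False)]),
            11: _day_dets(11, [(pos, False)]),
            12: _day_dets(12, [((40.0, 52.0), True)]),
        }
        curve = build_automatic_curve(per_day, n0=1)
        assert list(curve.counts) == [1, 0, 0, 1]
        assert not curve.rectified

    def test_reference_curve_recovers_the_dip(self):
        pos = (40.0, 40.0)
        per_day = {
            9: _day_dets(9, [(pos, True)]),
            10: _day_dets(10, [(pos, False)]),
            11: _day_dets(11, [(pos, False)]),
            12: _day_dets(12, [((40.0, 52.0), True)]),
        }
        ref = build_reference_curve(per_day, n0=1)
        assert list(ref.counts) == [1, 1, 1, 1]
        assert ref.rectified

    def test_empty_plate_all_zero(self):
        per_day = {1: {"before": []}, 2: {"before": []}}
        curve = build_automatic_curve(per_day, n0=0)
        assert list(curve.counts) == [0, 0]

    def test_triple_inspection_recovers_hidden_worm(self):
        pos = (40.0, 40.0)
        day1 = {
            "before1": _day_dets(1, [(pos, True)])["before"],
            "before2": _day_dets(1, [(pos, True)])["before"],
            "before3": _day_dets(1, [(pos, True)])["before"],
        }
        # hidden at the first inspection, seen moving at the second
        day2 = {
            "before1": [],
            "before2": _day_dets(2, [((44.0, 40.0), True)])["before"],
            "before3": [],
        }
        triple = build_reference_curve({1: day1, 2: day2}, n0=1, mode="triple_inspection")
        single = build_reference_curve({1: day1, 2: day2}, n0=1, mode="single_inspection")
        assert list(triple.counts) == [1, 1]
        assert list(single.counts) == [1, 0]

    def test_triple_mode_requires_three_inspections(self):
        per_day = {1: _day_dets(1, [((4.0, 4.0), True)])}
        with pytest.raises(ValueError):
            build_reference_curve(per_day, n0=1, mode="triple_inspection")


class TestRectify:
    def oracle(self, counts):
        return [max(counts[i:]) for i in range(len(counts))]

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([15, 13, 14, 12], [15, 14, 14, 12]),
            ([15, 14, 14, 12], [15, 14, 14, 12]),
            ([0, 5], [5, 5]),
        ],
    )
    def test_reverse_running_max_examples(self, counts, expected):
        curve = SurvivalCurve("x", list(range(len(counts))), counts, n0=15)
        assert list(rectify_curve(curve).counts) == expected

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_idempotent(self, counts):
        curve = SurvivalCurve("x", list(range(len(counts))), counts, n0=15)
        rect = rectify_curve(curve)
        assert list(rect.counts) == self.oracle(counts)
        assert (np.diff(rect.counts) <= 0).all()
        assert list(rectify_curve(rect).counts) == list(rect.counts)


class TestPipelineProperties:
    def test_zero_error_limit_matches_truth(self, clean_nv_simulation):
        res = analyze_condition(clean_nv_simulation)
        truth = res.true_counts()
        assert np.array_equal(res.auto_curve.counts, truth)
        assert np.array_equal(res.reference_curve.counts, truth)
        assert res.report.eT_percent == 0.0

    def test_reference_dominates_automatic_and_tracks_bounded(self):
        plate = PlateConfig(n_worms=8, image_size=(224, 224))
        sim = simulate_condition(
            plate, BehaviourConfig(), StimulusSchedule.none(), 2,
            [1, 2, 5, 6, 7, 8, 9, 12, 13, 14, 15, 16], seed=21,
        )
        res = analyze_condition(sim)
        for sa, sm in zip(res.auto_plates, res.ref_plates):
            assert (sm.counts >= sa.counts).all()
            assert (np.diff(sm.counts) <= 0).all()
            assert sa.counts.max() <= plate.n_worms
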