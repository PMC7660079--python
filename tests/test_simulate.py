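"""Behaviour model and plate-image rendering."""
import numpy as np
import pytest

from wormvib import (
    BehaviourConfig,
    PlateConfig,
    StimulusSchedule,
    WormAgent,
    render_frame,
    sample_lifespans,
    simulate_condition,
    step_behaviour,
)
from wormvib.config import GREY_THRESHOLD
from wormvib.simulate import shadow_mask


class TestLifespans:
    def test_point_mass_distribution(self):
        beh = BehaviourConfig(lifespan_distribution="point", lifespan_median=14)
        assert list(sample_lifespans(beh, 5, seed=0)) == [14] * 5

    def test_gompertz_median_recovered(self):
        # Monte-Carlo against the calibrated analytic median of 14 days
        draws = sample_lifespans(BehaviourConfig(), 10_000, seed=1)
        assert abs(np.median(draws) - 14) <= 1
        assert draws.min() >= 2

    def test_same_seed_identical(self):
        beh = BehaviourConfig()
        assert np.array_equal(sample_lifespans(beh, 50, 3), sample_lifespans(beh, 50, 3))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BehaviourConfig(lifespan_shape=-1.0)
        with pytest.raises(ValueError):
            sample_lifespans(BehaviourConfig(), 0, seed=0)


class TestStepBehaviour:
    def _worm(self, death_day=30):
        return WormAgent(id=0, death_day=death_day, position=np.array([50.0, 50.0]))

    def test_dead_worm_never_moves(self, rng):
        worm = self._worm(death_day=5)
        sched = StimulusSchedule.constant(5, 3.0, range(5, 30))
        out = step_behaviour(worm, 10, sched, BehaviourConfig(), rng)
        assert out.moved_before is False and out.moved_after is False
        assert not np.any(out.displacement)

    def test_certain_response_moves(self, rng):
        beh = BehaviourConfig(stimulated_response_weekly=(1.0, 1.0, 1.0))
        sched = StimulusSchedule.constant(5, 3.0, range(5, 30))
        out = step_behaviour(self._worm(), 10, sched, beh, rng)
        assert out.moved_after is True

    def test_response_rate_binomial_recovery(self, rng):
        # empirical response over many draws near the configured 0.93
        beh = BehaviourConfig(habituation_rate=0.0)
        sched = StimulusSchedule.constant(5, 3.0, range(5, 30))
        n = 10_000
        hits = sum(
            step_behaviour(self._worm(), 16, sched, beh, rng).moved_after
            for _ in range(n)
        )
        se = np.sqrt(0.93 * 0.07 / n)
        assert abs(hits / n - 0.93) <= 3 * se

    def test_habituation_resets_on_duration_change(self, rng):
        beh = BehaviourConfig()
        worm = self._worm()
        worm.habituation_count = 200
        worm.last_stim_duration = 1.0
        sched = StimulusSchedule.constant(5, 3.0, range(5, 30))
        step_behaviour(worm, 10, sched, beh, rng)
        # counter restarted from zero and then counted this stimulus
        assert worm.habituation_count == 1
        assert worm.last_stim_duration == 3.0

    def test_no_move_probability_curve(self):
        beh = BehaviourConfig()
        assert beh.no_move_prob(5) == pytest.approx(0.02)
        assert beh.no_move_prob(9) == pytest.approx(0.15)
        assert beh.no_move_prob(21) == pytest.approx(0.29)
        assert beh.no_move_prob(30) == pytest.approx(0.29)
        assert 0.02 < beh.no_move_prob(7) < 0.15


class TestRendering:
    def test_empty_plate_is_uniform_background(self, clean_plate):
        img = render_frame([], clean_plate)
        assert img.dtype == np.uint8
        assert (img == clean_plate.background_grey).all()

    def test_shadow_zone_area_fraction(self, small_plate):
        mask = shadow_mask(small_plate)
        plate_area = np.pi * small_plate.plate_radius_px**2
        assert mask.sum() == pytest.approx(0.05 * plate_area, rel=0.15)

    def test_worm_rendered_dark_with_3px_width(self, clean_plate):
        pts = np.stack([np.full(10, 96.0), np.linspace(80, 96, 10)], axis=1)
        img = render_frame([pts], clean_plate)
        assert set(np.unique(img)) == {clean_plate.worm_grey, clean_plate.background_grey}
        # cross-section through the straight horizontal body is 3 px wide
        col = img[:, 88]
        assert (col == clean_plate.worm_grey).sum() == 3

    def test_segmentation_is_exact_on_clean_frames(self, clean_plate):
        pts = np.stack([np.full(10, 96.0), np.linspace(80, 96, 10)], axis=1)
        img = render_frame([pts], clean_plate)
        dark = img <= GREY_THRESHOLD
        assert dark.sum() == (img == clean_plate.worm_grey).sum()

    def test_worm_outside_bounds_raises(self, clean_plate):
        pts = np.stack([np.full(10, 5000.0), np.linspace(0, 9, 10)], axis=1)
        with pytest.raises(ValueError, match="outside"):
            render_frame([pts], clean_plate)


class TestConditionSimulation:
    def test_nv_schedule_has_no_after_sequences(self, clean_plate, clean_behaviour):
        sim = simulate_condition(
            clean_plate, clean_behaviour, StimulusSchedule.none(), 1, [1, 2, 3], seed=0
        )
        assert all(sim.phases(d) == ["before"] for d in sim.days)

    def test_first_after_sequence_on_start_day(self, clean_plate, clean_behaviour):
        sched = StimulusSchedule.constant(5, 3.0, [5, 6, 7])
        sim = simulate_condition(
            clean_plate, clean_behaviour, sched, 1, [1, 2, 5, 6, 7], seed=0
        )
        with_after = [d for d in sim.days if "after" in sim.phases(d)]
        assert with_after == [5, 6, 7]
        stack = sim.render_sequence(0, 5, "after")
        assert stack.shape == (clean_plate.frame_count, *clean_plate.image_size)

    def test_fixed_seed_bit_identical(self, small_plate):
        beh = BehaviourConfig()
        sims = [
            simulate_condition(
                small_plate, beh, StimulusSchedule.none(), 1, [1, 2, 3], seed=9
            )
            for _ in range(2)
        ]
        assert sims[0].truth.equals(sims[1].truth)
        for day in (1, 3):
            a = sims[0].render_sequence(0, day, "before")
            b = sims[1].render_sequence(0, day, "before")
            assert np.array_equal(a, b)

    def test_true_live_counts_non_increasing(self, small_plate):
        sim = simulate_condition(
            small_plate, BehaviourConfig(), StimulusSchedule.none(), 3,
            list(range(1, 20)), seed=2,
        )
        for p in range(3):
            counts = sim.true_live_counts(p)
            assert (np.diff(counts) <= 0).all()

    def test_non_mover_renders_identically_and_mover_changes(
        self, clean_plate, clean_behaviour
    ):
        # clean limit: every live worm changes pixels within every sequence
        sim = simulate_condition(
            clean_plate, clean_behaviour, StimulusSchedule.none(), 1,
            list(range(1, 10)), seed=3,
        )
        for day in sim.days:
            stack = sim.render_sequence(0, day, "before")
            alive = (sim.death_days(0) > day).sum()
            if alive:
                assert (stack[0] != stack[-1]).any()
        # after every worm is dead the scene must be frozen
        horizon_day = int(sim.death_days(0).max())
        sim2 = simulate_condition(
            clean_plate, clean_behaviour, StimulusSchedule.none(), 1,
            [horizon_day, horizon_day + 1], seed=3, horizon=horizon_day + 1,
        )
        stack = sim2.render_sequence(0, horizon_day + 1, "before")
        assert (stack[0] == stack[-1]).all()

    def test_schedule_before_first_acquisition_rejected(self, clean_plate):
        sched = StimulusSchedule.constant(1, 3.0, [1, 2])
        with pytest.raises(ValueError):
            simulate_condition(
                clean_plate, BehaviourConfig(), sched, 1, [2, 3], seed=0
            )

    def test_noise_pixels_alternate(self):
        plate = PlateConfig(
            n_worms=1, image_size=(128, 128), shadow_zone_fraction=0.0,
            noise_pixel_rate=0.01,
        )
        beh = BehaviourConfig(lifespan_distribution="point", lifespan_median=3)
        sim = simulate_condition(plate, beh, StimulusSchedule.none(), 1, [4], seed=1,
                                 horizon=4)
        stack = sim.render_sequence(0, 4, "before")  # worm dead: only noise moves
        changed = (stack[0] != stack[1]).sum()
        assert changed == int(round(0.01 * 128 * 128))
        assert np.array_equal(stack[0], stack[2])  # period-2 alternation
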