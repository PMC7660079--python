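"""Synthetic plate-image simulator with ground truth.

Generates seeded 30-frame greyscale sequences that emulate the lifespan
machine's optics (uniform grey-48 background, worms darker than the grey-33
threshold, dark wall-shadow arcs covering ~5% of plate area, optional
alternating sensor-noise pixels) driven by an ageing/vibrotaxis/habituation
behaviour model, together with a per-worm ground-truth table.

Timing conventions (these make the dead-or-alive criterion exact in the
clean limit):

* all stochastic behaviour is drawn per calendar day;
* a worm's movement on day ``k`` consists of in-sequence displacement during
  the inspection(s) plus one overnight step after the inspection;
* the overnight step after day ``k`` happens only if the worm moved on day
  ``k`` *and* is still alive on day ``k+1`` — a moribund worm makes no
  movement between its last inspection alive and the next (terminal
  quiescence), so a worm found unchanged at inspection is genuinely dead
  under daily acquisition.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line

from .config import BehaviourConfig, PlateConfig, StimulusSchedule

__all__ = [
    "WormAgent",
    "ConditionSimulation",
    "sample_lifespans",
    "step_behaviour",
    "render_frame",
    "simulate_condition",
    "shadow_mask",
]

N_POSE_POINTS = 10


# ---------------------------------------------------------------------------
# lifespans


def sample_lifespans(
    behaviour: BehaviourConfig, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` integer death days from the configured lifespan distribution.

    For the Gompertz family the continuous survival time is
    ``S(t) = exp(-(b/a) (e^{a t} - 1))`` with shape ``a`` and scale ``b``
    calibrated so the continuous median equals ``lifespan_median``; death days
    are the ceiling of the continuous draw (a worm dying during day ``d`` is
    alive on days ``< d``). Death days are clamped to be >= 2 so every worm is
    alive on the first assay day.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if behaviour.lifespan_distribution == "point":
        return np.full(n, int(round(behaviour.lifespan_median)), dtype=int)
    a = behaviour.lifespan_shape
    b = behaviour.gompertz_scale
    u = rng.random(n)
    t = np.log1p(-(a / b) * np.log(u)) / a
    return np.maximum(2, np.ceil(t).astype(int))


# ---------------------------------------------------------------------------
# per-worm behaviour


@dataclass
class WormAgent:
    """State of one simulated animal (current day)."""

    id: int
    death_day: int
    position: np.ndarray  # (2,) float px, row/col
    heading: float = 0.0
    pose: np.ndarray | None = None  # current centreline; frozen while not moving
    moved_before: bool = False
    moved_after: bool | None = None
    occluded: bool = False
    habituation_count: int = 0
    last_stim_duration: float = 0.0
    n_stim_days: int = 0
    displacement: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def alive_on(self, day: int) -> bool:
        return day < self.death_day


def _habituation_factor(behaviour: BehaviourConfig, count: int) -> float:
    return (1.0 - behaviour.habituation_rate) ** count


def step_behaviour(
    worm: WormAgent,
    day: int,
    schedule: StimulusSchedule,
    behaviour: BehaviourConfig,
    rng: np.random.Generator,
    *,
    motility_px2: float | None = None,
) -> WormAgent:
    """Advance one worm by one day, drawing its movement flags in place.

    ``moved_before ~ Bernoulli(1 - no_move_prob(day))`` for a live worm; on a
    stimulation day ``moved_after ~ Bernoulli(response(day) * habituation)``.
    Habituation counts every stimulus experienced and (by default) resets when
    the stimulus duration changes. ``displacement`` is the proposed overnight
    step, scaled by age-decayed motility and shrunk by the post-stimulus
    motility decrement; the caller applies it subject to plate geometry. Dead
    worms never move but keep their position (the corpse stays on the plate).
    """
    t = schedule.duration_on(day)
    alive = worm.alive_on(day)
    if not alive:
        worm.moved_before = False
        worm.moved_after = False if t > 0 else None
        worm.displacement = np.zeros(2)
        return worm

    worm.moved_before = rng.random() >= behaviour.no_move_prob(day)
    if t > 0:
        if (
            behaviour.habituation_reset_on_duration_change
            and worm.last_stim_duration not in (0.0, t)
        ):
            worm.habituation_count = 0
        p = behaviour.response_prob(day) * _habituation_factor(
            behaviour, worm.habituation_count
        )
        worm.moved_after = rng.random() < p
        worm.habituation_count += 1
        worm.last_stim_duration = t
        worm.n_stim_days += 1
    else:
        worm.moved_after = None

    moved = worm.moved_before or bool(worm.moved_after)
    if moved and worm.alive_on(day + 1):
        if motility_px2 is None:
            motility_px2 = behaviour.motility(day, worm.death_day, worm.n_stim_days)
        step = max(4.0, 4.0 * np.sqrt(max(motility_px2, 0.0)))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        worm.displacement = step * np.array([np.cos(theta), np.sin(theta)])
    else:
        worm.displacement = np.zeros(2)
    return worm


# ---------------------------------------------------------------------------
# geometry helpers


def _make_pose(
    centroid: np.ndarray, heading: float, length_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Random smooth centreline (N_POSE_POINTS x 2) centred on ``centroid``."""
    n_seg = N_POSE_POINTS - 1
    seg = length_px / n_seg
    angles = heading + np.cumsum(rng.normal(0.0, 0.25, n_seg))
    steps = seg * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    pts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return pts - pts.mean(axis=0) + centroid


def shadow_mask(config: PlateConfig) -> np.ndarray:
    """Boolean mask of the wall-shadow arcs (dark occlusion zones).

    Fixed arcs in the outer annulus of the plate whose total area equals
    ``shadow_zone_fraction`` of the plate area.
    """
    h, w = config.image_size
    out = np.zeros((h, w), dtype=bool)
    frac = config.shadow_zone_fraction
    if frac <= 0:
        return out
    r = config.plate_radius_px
    r_in = 0.92 * r
    ann_frac = 1.0 - (r_in / r) ** 2  # annulus share of plate area
    phi_total = min(2.0 * np.pi, 2.0 * np.pi * frac / ann_frac)
    centres = np.array([0.5, 2.5, 4.5])  # radians, fixed arc positions
    half = phi_total / (2 * len(centres))
    cy, cx = config.centre
    yy, xx = np.ogrid[:h, :w]
    rad = np.hypot(yy - cy, xx - cx)
    ang = np.mod(np.arctan2(xx - cx, yy - cy), 2.0 * np.pi)
    in_ann = (rad >= r_in) & (rad <= r)
    for c in centres:
        d = np.abs(np.mod(ang - c + np.pi, 2.0 * np.pi) - np.pi)
        out |= in_ann & (d <= half)
    return out


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Distance from point ``p`` to the segment ``a``-``b``."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(p - a)))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.hypot(*(p - (a + t * ab))))


def _point_in_shadow(pos: np.ndarray, config: PlateConfig) -> bool:
    if config.shadow_zone_fraction <= 0:
        return False
    r = config.plate_radius_px
    r_in = 0.92 * r
    cy, cx = config.centre
    dy, dx = pos[0] - cy, pos[1] - cx
    rad = float(np.hypot(dy, dx))
    if not (r_in <= rad <= r):
        return False
    ann_frac = 1.0 - (r_in / r) ** 2
    phi_total = min(2.0 * np.pi, 2.0 * np.pi * config.shadow_zone_fraction / ann_frac)
    half = phi_total / 6.0
    ang = np.mod(np.arctan2(dx, dy), 2.0 * np.pi)
    for c in (0.5, 2.5, 4.5):
        if abs(np.mod(ang - c + np.pi, 2.0 * np.pi) - np.pi) <= half:
            return True
    return False


# ---------------------------------------------------------------------------
# rendering


def render_frame(
    polylines: Sequence[np.ndarray],
    config: PlateConfig,
    frame_index: int = 0,
    *,
    shadow: np.ndarray | None = None,
    noise_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Render one 8-bit frame from worm centrelines.

    Background is uniform ``background_grey``; shadow arcs are drawn at
    ``shadow_grey`` (below the segmentation threshold); each centreline is
    rasterised and dilated to the 3 px worm width at ``worm_grey``. Noise
    pixels alternate between dark and background grey with the frame parity.
    Raises if any worm point falls outside the image.
    """
    h, w = config.image_size
    img = np.full((h, w), config.background_grey, dtype=np.uint8)
    if shadow is None:
        shadow = shadow_mask(config)
    img[shadow] = config.shadow_grey
    if polylines:
        canvas = np.zeros((h, w), dtype=bool)
        for pts in polylines:
            ipts = np.rint(pts).astype(int)
            if (ipts < 0).any() or (ipts[:, 0] >= h).any() or (ipts[:, 1] >= w).any():
                raise ValueError("worm outside image bounds")
            for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
                rr, cc = line(r0, c0, r1, c1)
                canvas[rr, cc] = True
        body = ndimage.binary_dilation(canvas, structure=np.ones((3, 3), bool))
        img[body] = config.worm_grey
    if noise_coords is not None and len(noise_coords):
        val = config.shadow_grey if frame_index % 2 == 0 else config.background_grey
        alt = config.background_grey if frame_index % 2 == 0 else config.shadow_grey
        half = len(noise_coords) // 2
        img[noise_coords[:half, 0], noise_coords[:half, 1]] = val
        img[noise_coords[half:, 0], noise_coords[half:, 1]] = alt
    return img


# ---------------------------------------------------------------------------
# full condition simulation


def _lerp_poses(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    return a + f * (b - a)


class ConditionSimulation:
    """Seeded realisation of one condition: behaviour truth + lazy rendering.

    The behaviour pass runs eagerly (cheap per-worm arrays); image sequences
    are rendered on demand so a whole multi-plate assay never has to sit in
    memory at once. Identical ``(configs, schedule, seed)`` give bit-identical
    images and ground truth.
    """

    def __init__(
        self,
        plate_config: PlateConfig,
        behaviour: BehaviourConfig,
        schedule: StimulusSchedule,
        n_plates: int,
        days: Sequence[int],
        seed: int,
        inspections: int = 1,
        horizon: int | None = None,
    ) -> None:
        self.plate_config = plate_config
        self.behaviour = behaviour
        self.schedule = schedule
        self.n_plates = int(n_plates)
        self.days = sorted(int(d) for d in days)
        self.inspections = int(inspections)
        self.seed = int(seed)
        self.horizon = int(horizon or max(self.days))
        if schedule.durations and min(schedule.durations) < min(self.days):
            raise ValueError("schedule starts before the first acquisition day")
        self._shadow = shadow_mask(plate_config)
        # a worm whose rendered body would touch a shadow arc is hidden from
        # view (it merges with the dark zone); test pose points against the
        # shadow dilated by the rendering footprint
        self._shadow_occ = (
            ndimage.binary_dilation(self._shadow, iterations=3)
            if self._shadow.any()
            else self._shadow
        )
        self._run()

    # -- behaviour pass ----------------------------------------------------

    def _plate_rng(self, plate: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, plate]))

    def _run(self) -> None:
        cfg = self.plate_config
        beh = self.behaviour
        n = cfg.n_worms
        H = self.horizon
        acq = set(self.days)
        self._death: dict[int, np.ndarray] = {}
        # per plate: poses[day][insp] arrays and end-of-day state
        self._poses: dict[int, dict] = {}
        self._noise: dict[int, np.ndarray] = {}
        rows = []
        sep = 1.5 * cfg.worm_length_px + 2.0
        for p in range(self.n_plates):
            rng = self._plate_rng(p)
            death = sample_lifespans(beh, n, rng)
            self._death[p] = death
            worms = []
            positions = self._init_positions(rng, sep)
            for w in range(n):
                worms.append(
                    WormAgent(
                        id=w,
                        death_day=int(death[w]),
                        position=positions[w],
                        heading=rng.uniform(0, 2 * np.pi),
                    )
                )
            n_noise = int(round(cfg.noise_pixel_rate * cfg.image_size[0] * cfg.image_size[1]))
            self._noise[p] = self._draw_noise_coords(rng, n_noise)
            plate_days: dict[int, dict] = {}
            for day in range(1, H + 1):
                is_acq = day in acq
                t = self.schedule.duration_on(day) if is_acq else 0.0
                day_sched = (
                    self.schedule if is_acq else StimulusSchedule.none(self.schedule.label)
                )
                day_rec: dict = {"t": t, "inspections": []}
                px_factor = (0.03 / cfg.mm_per_px) ** 2  # machine px^2 -> render px^2
                for worm in worms:
                    mot = beh.motility(day, worm.death_day, worm.n_stim_days)
                    step_behaviour(
                        worm, day, day_sched, beh, rng, motility_px2=mot * px_factor
                    )
                if is_acq:
                    day_rec["inspections"] = self._realise_inspections(worms, day, t, rng, sep)
                    for worm in worms:
                        rows.append(
                            {
                                "plate": p,
                                "day": day,
                                "worm_id": worm.id,
                                "alive": worm.alive_on(day),
                                "moved_before": bool(worm.moved_before)
                                and worm.alive_on(day),
                                "moved_after": (
                                    bool(worm.moved_after) if t > 0 else None
                                ),
                                "occluded": worm.occluded,
                            }
                        )
                # overnight step (only drawn non-zero for movers surviving day+1)
                for worm in worms:
                    if np.any(worm.displacement):
                        new = self._apply_step(
                            worm.position, worm.displacement, worms, worm.id, rng, sep
                        )
                        if worm.pose is not None:
                            worm.pose = worm.pose + (new - worm.position)
                        worm.position = new
                        worm.heading = float(
                            np.arctan2(worm.displacement[1], worm.displacement[0])
                        )
                plate_days[day] = day_rec
            self._poses[p] = plate_days
        self.truth = pd.DataFrame(rows)

    def _init_positions(self, rng: np.random.Generator, sep: float) -> list[np.ndarray]:
        cfg = self.plate_config
        cy, cx = cfg.centre
        rmax = 0.95 * cfg.plate_radius_px - cfg.worm_length_px
        out: list[np.ndarray] = []
        while len(out) < cfg.n_worms:
            rad = rmax * np.sqrt(rng.random())
            ang = rng.uniform(0, 2 * np.pi)
            pos = np.array([cy + rad * np.cos(ang), cx + rad * np.sin(ang)])
            if all(np.hypot(*(pos - q)) >= sep for q in out):
                out.append(pos)
        return out

    def _draw_noise_coords(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n <= 0:
            return np.zeros((0, 2), dtype=int)
        h, w = self.plate_config.image_size
        idx = rng.choice(h * w, size=n, replace=False)
        return np.stack(np.unravel_index(idx, (h, w)), axis=1)

    def _apply_step(
        self,
        pos: np.ndarray,
        disp: np.ndarray,
        worms: list[WormAgent],
        self_id: int,
        rng: np.random.Generator,
        sep: float,
    ) -> np.ndarray:
        """Apply a movement step with lawn-centred drift, wall reflection and
        worm-worm avoidance (rejection sampling with step shrinking)."""
        cfg = self.plate_config
        cy, cx = cfg.centre
        rmax = 0.95 * cfg.plate_radius_px
        lawn = 0.45 * cfg.plate_radius_px
        margin = cfg.worm_length_px / 2.0 + 2.0
        step_len = float(np.hypot(*disp))
        others = [w.position for w in worms if w.id != self_id]
        cur = pos.copy()
        for attempt in range(12):
            theta = rng.uniform(0, 2 * np.pi) if attempt else np.arctan2(disp[1], disp[0])
            vec = step_len * np.array([np.cos(theta), np.sin(theta)])
            # drift back toward the bacterial lawn when outside it
            d_c = np.array([cy, cx]) - cur
            rad = float(np.hypot(*d_c))
            if rad > lawn and rad > 0:
                vec = vec + 0.8 * step_len * d_c / rad
            cand = cur + vec
            crad = float(np.hypot(cand[0] - cy, cand[1] - cx))
            if crad > rmax - margin:
                cand = np.array([cy, cx]) + (cand - np.array([cy, cx])) * (
                    (rmax - margin) / crad
                )
            # keep the whole straight-line path clear of other worms so swept
            # motion pixels never touch a neighbour's body
            if all(_segment_distance(q, cur, cand) >= sep for q in others):
                return cand
            step_len *= 0.7
        return pos

    def _realise_inspections(
        self,
        worms: list[WormAgent],
        day: int,
        t: float,
        rng: np.random.Generator,
        sep: float,
    ) -> list[dict]:
        """Fix start/end centrelines for each inspection of the day.

        Each inspection is a 30 s before-sequence (plus an after-sequence when
        ``t > 0``); a moving worm crawls by half its swept length per 30 s
        (tortuosity) with a 2 px floor so movement is always resolvable at the
        rendered pixel pitch.
        """
        cfg = self.plate_config
        beh = self.behaviour
        recs = []
        for _ in range(self.inspections):
            insp: dict = {"worms": []}
            for worm in worms:
                alive = worm.alive_on(day)
                mot = beh.motility(day, worm.death_day, worm.n_stim_days)
                mot_px2 = mot * (0.03 / cfg.mm_per_px) ** 2  # machine px^2 -> render px^2
                crawl = max(2.0, 0.5 * mot_px2 / cfg.worm_width_px)
                if worm.pose is None:
                    worm.pose = _make_pose(
                        worm.position, worm.heading, cfg.worm_length_px, rng
                    )
                start_pose = worm.pose
                rec = {
                    "id": worm.id,
                    "occluded": False,
                    "poses": {"before": (start_pose, start_pose)},
                }
                if alive and worm.moved_before:
                    end = self._apply_step(
                        worm.position,
                        crawl * np.array([np.cos(worm.heading), np.sin(worm.heading)]),
                        worms,
                        worm.id,
                        rng,
                        sep,
                    )
                    end_pose = _make_pose(end, worm.heading, cfg.worm_length_px, rng)
                    rec["poses"]["before"] = (start_pose, end_pose)
                    worm.position = end
                    worm.pose = end_pose
                if t > 0:
                    cur_pose = rec["poses"]["before"][1]
                    rec["poses"]["after"] = (cur_pose, cur_pose)
                    if alive and worm.moved_after:
                        end = self._apply_step(
                            worm.position,
                            crawl
                            * np.array([np.cos(worm.heading), np.sin(worm.heading)]),
                            worms,
                            worm.id,
                            rng,
                            sep,
                        )
                        end_pose = _make_pose(end, worm.heading, cfg.worm_length_px, rng)
                        rec["poses"]["after"] = (cur_pose, end_pose)
                        worm.position = end
                        worm.pose = end_pose
                rec["occluded"] = any(
                    self._pose_in_shadow(p)
                    for pair in rec["poses"].values()
                    for p in pair
                )
                worm.occluded = rec["occluded"]
                insp["worms"].append(rec)
            recs.append(insp)
        return recs

    def _pose_in_shadow(self, pose: np.ndarray) -> bool:
        if not self._shadow_occ.any():
            return False
        h, w = self.plate_config.image_size
        ipts = np.clip(np.rint(pose).astype(int), 0, [h - 1, w - 1])
        return bool(self._shadow_occ[ipts[:, 0], ipts[:, 1]].any())

    # -- rendering ---------------------------------------------------------

    def phases(self, day: int) -> list[str]:
        base = ["before"] if self.inspections == 1 else [
            f"before{i+1}" for i in range(self.inspections)
        ]
        if self.schedule.duration_on(day) > 0:
            base.append("after")
        return base

    def _phase_key(self, phase: str) -> tuple[int, str]:
        if phase == "after":
            return self.inspections - 1, "after"
        if phase == "before":
            return 0, "before"
        if phase.startswith("before"):
            return int(phase[len("before"):]) - 1, "before"
        raise KeyError(phase)

    def render_sequence(self, plate: int, day: int, phase: str = "before") -> np.ndarray:
        """Render the (frame_count, H, W) uint8 stack for one plate/day/phase."""
        if day not in self._poses[plate] or not self._poses[plate][day]["inspections"]:
            raise KeyError(f"day {day} is not an acquisition day")
        insp_idx, sub = self._phase_key(phase)
        if sub == "after" and self._poses[plate][day]["t"] <= 0:
            raise KeyError("no after-phase on an unstimulated day")
        rec = self._poses[plate][day]["inspections"][insp_idx]
        cfg = self.plate_config
        T = cfg.frame_count
        noise = self._noise[plate]
        frames = np.empty((T, *cfg.image_size), dtype=np.uint8)
        movers, static = [], []
        for wrec in rec["worms"]:
            if wrec["occluded"]:
                continue
            a, b = wrec["poses"][sub]
            (movers if np.any(a != b) else static).append((a, b))
        static_lines = [a for a, _ in static]
        if not movers and not len(noise):
            frame = render_frame(static_lines, cfg, 0, shadow=self._shadow)
            frames[:] = frame
            return frames
        for f in range(T):
            frac = f / (T - 1)
            lines = static_lines + [_lerp_poses(a, b, frac) for a, b in movers]
            frames[f] = render_frame(
                lines, cfg, f, shadow=self._shadow, noise_coords=noise
            )
        return frames

    def iter_sequences(self) -> Iterator[tuple[int, int, str, np.ndarray]]:
        """Yield (plate, day, phase, stack) over the whole condition."""
        for p in range(self.n_plates):
            for day in self.days:
                for phase in self.phases(day):
                    yield p, day, phase, self.render_sequence(p, day, phase)

    # -- truth accessors ----------------------------------------------------

    def death_days(self, plate: int) -> np.ndarray:
        """Ground-truth death day of every worm on one plate."""
        return self._death[plate].copy()

    def true_live_counts(self, plate: int) -> np.ndarray:
        """True number of live worms on each acquisition day for one plate."""
        death = self._death[plate]
        return np.array([(death > d).sum() for d in self.days], dtype=int)


def simulate_condition(
    plate_config: PlateConfig,
    behaviour: BehaviourConfig,
    schedule: StimulusSchedule,
    n_plates: int,
    days: Sequence[int],
    seed: int,
    inspections: int = 1,
    horizon: int | None = None,
) -> ConditionSimulation:
    """Build the seeded simulation for one condition (images rendered lazily)."""
    return ConditionSimulation(
        plate_config, behaviour, schedule, n_plates, days, seed, inspections, horizon
    )
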