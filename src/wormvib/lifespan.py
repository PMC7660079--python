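"""Daily detections -> survival curves (dead-or-alive criterion).

A worm is scored alive on an inspection day if it moved during the 30 s
sequence (either phase, when a post-vibration sequence exists), or if its
position or shape changed since the previous inspection; otherwise it is
scored dead. The automatic curve applies this criterion causally day by day
(it may dip and rise when a live worm is briefly motionless or hidden). The
reference curve emulates expert manual counting: the same criterion, but a
worm seen to change at a later inspection is regressively rectified back to
alive on the earlier days.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .detect import DetectParams, ImageSequence, classify_pixels, motion_area, segment_frame

__all__ = [
    "WormDetection",
    "SurvivalCurve",
    "PlateTracker",
    "detect_worms",
    "alive_call",
    "build_automatic_curve",
    "build_reference_curve",
    "rectify_curve",
]

POSITION_TOLERANCE_PX = 3.0  # one worm width
SHAPE_TOLERANCE = 0.05  # relative mask-overlap distance


@dataclass
class WormDetection:
    """One dark blob of plausible worm size in a day's sequence."""

    plate: int
    day: int
    blob_id: int
    centroid: tuple[float, float]
    area: int
    mask_offsets: np.ndarray  # (N, 2) pixel offsets relative to rounded centroid
    moved_in_sequence: bool
    phase: str = "before"


@dataclass
class SurvivalCurve:
    """Per-day alive counts for one condition (or one plate)."""

    label: str
    days: list[int]
    counts: np.ndarray
    n0: int
    rectified: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.days):
            raise ValueError("counts and days must have equal length")
        if (self.counts < 0).any() or (self.counts > self.n0).any():
            raise ValueError("counts must lie in [0, n0]")


def _shape_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Relative symmetric-difference distance between two blob masks,
    compared in centroid-anchored offset coordinates (0 iff identical)."""
    sa = {tuple(p) for p in a}
    sb = {tuple(p) for p in b}
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa ^ sb) / union


def detect_worms(
    sequences: list[ImageSequence],
    params: DetectParams | None = None,
    *,
    min_area: int = 6,
    max_area: int = 400,
) -> list[WormDetection]:
    """Extract worm-sized dark blobs from each of a day's sequences.

    The blob support is the black mask of the *last* frame (the position a
    worm is left in at the end of the inspection) with noisy-class pixels
    removed; connected components outside ``[min_area, max_area]`` px^2 (sensor
    noise, wall shadows) are discarded. ``moved_in_sequence`` is true when
    motion-class pixels touch the blob's neighbourhood.
    """
    params = params or DetectParams()
    out: list[WormDetection] = []
    for seq in sequences:
        stack = np.stack([segment_frame(f, params) for f in seq.frames])
        sig = classify_pixels(stack, params)
        mask = stack[-1] & ~sig.noisy_mask
        labels = measure.label(mask, connectivity=2)
        for region in measure.regionprops(labels):
            if not min_area <= region.area <= max_area:
                continue
            cy, cx = region.centroid
            coords = region.coords
            offsets = coords - np.rint([cy, cx]).astype(int)
            # the worm's own swept path is contiguous with its final body, so
            # a tight 2 px neighbourhood suffices and avoids crediting a
            # passing neighbour's motion to a still worm
            minr, minc, maxr, maxc = region.bbox
            neigh = np.zeros_like(mask)
            neigh[
                max(minr - 2, 0) : maxr + 2, max(minc - 2, 0) : maxc + 2
            ] = True
            moved = motion_area(sig, neigh) > 0
            out.append(
                WormDetection(
                    plate=seq.plate,
                    day=seq.day,
                    blob_id=len(out),
                    centroid=(cy, cx),
                    area=int(region.area),
                    mask_offsets=offsets,
                    moved_in_sequence=moved,
                    phase=seq.phase,
                )
            )
    return out


def alive_call(
    detection: WormDetection | None,
    previous_centroid: tuple[float, float] | None,
    previous_offsets: np.ndarray | None,
    moved_any_phase: bool,
    *,
    position_tol: float = POSITION_TOLERANCE_PX,
    shape_tol: float = SHAPE_TOLERANCE,
) -> bool:
    """Dead-or-alive criterion for one worm on one inspection day.

    Alive iff it moved within any of the day's sequences, or its centroid
    displaced more than one worm width since the previous inspection, or its
    blob shape changed by more than the tolerance. An undetected (hidden)
    worm is scored dead. Without a previous-day record the call falls back to
    within-sequence motion only.
    """
    if detection is None:
        return False
    if moved_any_phase:
        return True
    if previous_centroid is None:
        return False
    dy = detection.centroid[0] - previous_centroid[0]
    dx = detection.centroid[1] - previous_centroid[1]
    if np.hypot(dy, dx) > position_tol:
        return True
    if previous_offsets is not None:
        if _shape_distance(detection.mask_offsets, previous_offsets) > shape_tol:
            return True
    return False


@dataclass
class _Track:
    id: int
    centroid: tuple[float, float]
    offsets: np.ndarray
    calls: dict[int, bool] = field(default_factory=dict)
    seen: bool = True


class PlateTracker:
    """Greedy nearest-neighbour day-to-day track linking for one plate.

    Tracks are seeded from the first acquisition day (all ``n0`` worms are
    assumed alive then — the assay starts with young adults). Unmatched tracks
    persist at their last position (candidate dead); detections that match no
    track found a new track (a worm emerging from a shadow zone).
    """

    def __init__(self, n0: int, gate_px: float) -> None:
        self.n0 = n0
        self.gate = gate_px
        self.tracks: list[_Track] = []
        self.days: list[int] = []

    @staticmethod
    def _greedy_assign(
        tracks: list[tuple[int, tuple[float, float]]],
        dets: list[WormDetection],
        gate: float,
    ) -> dict[int, int]:
        pairs = sorted(
            (
                (_dist(pos, det.centroid), ti, di)
                for ti, pos in tracks
                for di, det in enumerate(dets)
            ),
            key=lambda x: x[0],
        )
        used_t: set[int] = set()
        used_d: set[int] = set()
        assign: dict[int, int] = {}
        for d, ti, di in pairs:
            if d > gate or ti in used_t or di in used_d:
                continue
            assign[ti] = di
            used_t.add(ti)
            used_d.add(di)
        return assign

    def update(self, day: int, detections_by_phase: dict[str, list[WormDetection]]) -> None:
        """Fold one day's phases (inspections, then after-vibration) into the
        tracks. Phases are matched sequentially so each track's position record
        ends at the last frame of the day's final phase; movement evidence from
        any phase counts."""
        first_day = not self.days
        self.days.append(day)
        prev_state = {tr.id: (tr.centroid, tr.offsets) for tr in self.tracks}
        moved: dict[int, bool] = {tr.id: False for tr in self.tracks}
        matched: set[int] = set()
        for phase, dets in detections_by_phase.items():
            cand = [(tr.id, tr.centroid) for tr in self.tracks]
            assign = self._greedy_assign(cand, dets, self.gate)
            # population is fixed at n0: before inventing a new track, force
            # leftover detections onto leftover tracks (global NN, no birth)
            rest_t = [c for c in cand if c[0] not in assign]
            rest_d = [d for d in enumerate(dets) if d[0] not in set(assign.values())]
            if rest_t and rest_d:
                sub = self._greedy_assign(
                    rest_t, [d for _, d in rest_d], float("inf")
                )
                for ti, dj in sub.items():
                    assign[ti] = rest_d[dj][0]
            by_id = {tr.id: tr for tr in self.tracks}
            for ti, di in assign.items():
                det = dets[di]
                tr = by_id[ti]
                tr.centroid = det.centroid
                tr.offsets = det.mask_offsets
                moved[ti] = moved[ti] or det.moved_in_sequence
                matched.add(ti)
            for di, det in enumerate(dets):
                if di in set(assign.values()):
                    continue
                tr = _Track(len(self.tracks), det.centroid, det.mask_offsets)
                moved[tr.id] = det.moved_in_sequence
                matched.add(tr.id)
                prev_state[tr.id] = (None, None)
                self.tracks.append(tr)
        for tr in self.tracks:
            if tr.id not in prev_state:
                continue
            if first_day:
                tr.calls[day] = tr.id in matched
                continue
            if tr.id not in matched:
                tr.calls[day] = False  # hidden or gone: candidate dead
                tr.seen = False
                continue
            tr.seen = True
            prev_c, prev_o = prev_state[tr.id]
            if prev_c is None:
                tr.calls[day] = True  # newly appeared: it got here somehow
                continue
            det = WormDetection(
                plate=0,
                day=day,
                blob_id=tr.id,
                centroid=tr.centroid,
                area=len(tr.offsets),
                mask_offsets=tr.offsets,
                moved_in_sequence=moved[tr.id],
            )
            tr.calls[day] = alive_call(det, prev_c, prev_o, moved[tr.id])

    # -- curves -------------------------------------------------------------

    def automatic_counts(self) -> np.ndarray:
        """Causal per-day alive counts (unrectified, clamped to [0, n0])."""
        out = []
        for i, day in enumerate(self.days):
            if i == 0:
                out.append(self.n0)
                continue
            out.append(min(self.n0, sum(tr.calls.get(day, False) for tr in self.tracks)))
        return np.asarray(out, dtype=int)

    def reference_counts(self) -> np.ndarray:
        """Per-worm regressively rectified counts (expert emulation).

        Each track is alive through its last day with an observed change; a
        track first seen late (hidden worm) is recovered back to day 1.
        """
        alive = np.zeros((len(self.tracks), len(self.days)), dtype=bool)
        for ti, tr in enumerate(self.tracks):
            idx = [i for i, d in enumerate(self.days) if tr.calls.get(d, False)]
            if idx:
                alive[ti, : idx[-1] + 1] = True
        counts = alive.sum(axis=0)
        counts[0] = self.n0
        return np.minimum(self.n0, counts)


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def build_automatic_curve(
    per_day_detections: dict[int, dict[str, list[WormDetection]]],
    n0: int,
    *,
    label: str = "",
    gate_px: float = 50.0,
) -> SurvivalCurve:
    """Run the tracker over a plate's daily detections -> automatic curve SA."""
    tracker = PlateTracker(n0, gate_px)
    for day in sorted(per_day_detections):
        tracker.update(day, per_day_detections[day])
    return SurvivalCurve(
        label=label, days=tracker.days, counts=tracker.automatic_counts(), n0=n0
    )


def build_reference_curve(
    per_day_detections: dict[int, dict[str, list[WormDetection]]],
    n0: int,
    *,
    mode: str = "single_inspection",
    label: str = "",
    gate_px: float = 50.0,
) -> SurvivalCurve:
    """Expert-emulating reference curve SM with regressive rectification.

    ``single_inspection`` uses the first daily inspection only (plus the
    post-vibration phase when present); ``triple_inspection`` requires three
    inspections per day and takes the most favourable evidence across them
    (hidden-worm recovery), as in triple manual counting.
    """
    if mode not in ("single_inspection", "triple_inspection"):
        raise ValueError(f"unknown mode {mode!r}")
    tracker = PlateTracker(n0, gate_px)
    for day in sorted(per_day_detections):
        phases = per_day_detections[day]
        insp = [p for p in phases if p.startswith("before")]
        if mode == "triple_inspection":
            if len(insp) < 3:
                raise ValueError("triple_inspection needs three inspections per day")
            selected = dict(phases)
        else:
            keep = [insp[0]] + [p for p in phases if p == "after"]
            selected = {p: phases[p] for p in keep}
        tracker.update(day, selected)
    counts = tracker.reference_counts()
    return SurvivalCurve(
        label=label, days=tracker.days, counts=counts, n0=n0, rectified=True
    )


def rectify_curve(curve: SurvivalCurve) -> SurvivalCurve:
    """Regressive rectification of a count curve: reverse running maximum.

    If more worms are seen on a later day, the earlier counts are raised (the
    missing worms had been hidden). The result is non-increasing and the
    operation is idempotent.
    """
    rect = np.maximum.accumulate(curve.counts[::-1])[::-1]
    return SurvivalCurve(
        label=curve.label, days=list(curve.days), counts=rect, n0=curve.n0, rectified=True
    )
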