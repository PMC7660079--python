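"""Configuration types for the plate simulator, behaviour model and experiments.

All three config objects are plain dataclasses with YAML round-trip support so
experiment presets can be shipped and edited as text.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

GREY_THRESHOLD = 33  # fixed segmentation threshold of the imaging pipeline

__all__ = [
    "GREY_THRESHOLD",
    "PlateConfig",
    "BehaviourConfig",
    "StimulusSchedule",
    "ConditionConfig",
    "ExperimentConfig",
    "load_experiment",
    "dump_experiment",
]


@dataclass
class PlateConfig:
    """Optical/geometric description of one imaged Petri plate.

    The machine images a 55 mm plate at roughly 30 um/pxl with the background
    held near grey level 48 by active lighting; worms are much darker than the
    fixed segmentation threshold (33). Rendering works in image pixels: the
    plate is scaled to fit ``image_size`` and the *effective* pixel pitch is
    derived from ``plate_diameter_mm`` and the rendered plate radius, while
    ``pixel_scale_um`` keeps the nominal machine pitch for unit conversions.
    """

    n_worms: int = 15
    plate_diameter_mm: float = 55.0
    pixel_scale_um: float = 30.0
    background_grey: int = 48
    worm_grey: int = 15
    shadow_grey: int = 20
    frame_count: int = 30
    frame_rate: float = 1.0
    image_size: tuple[int, int] = (512, 512)
    shadow_zone_fraction: float = 0.05
    noise_pixel_rate: float = 0.001
    seed: int | None = None
    worm_length_mm: float = 1.0
    worm_width_px: int = 3

    def __post_init__(self) -> None:
        self.image_size = tuple(int(v) for v in self.image_size)  # type: ignore[assignment]
        if not (self.worm_grey <= GREY_THRESHOLD < self.background_grey):
            raise ValueError(
                "require worm_grey <= 33 < background_grey for fixed-threshold "
                f"segmentation, got {self.worm_grey} / {self.background_grey}"
            )
        if not (self.shadow_grey <= GREY_THRESHOLD):
            raise ValueError("shadow zones must segment dark (shadow_grey <= 33)")
        if not 0.0 <= self.shadow_zone_fraction < 1.0:
            raise ValueError("shadow_zone_fraction must be in [0, 1)")
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        if self.frame_count < 2:
            raise ValueError("need at least 2 frames per sequence")

    @property
    def plate_radius_px(self) -> float:
        return 0.47 * min(self.image_size)

    @property
    def mm_per_px(self) -> float:
        """Effective rendered pixel pitch in mm/pxl."""
        return self.plate_diameter_mm / (2.0 * self.plate_radius_px)

    @property
    def worm_length_px(self) -> float:
        return max(6.0, self.worm_length_mm / self.mm_per_px)

    @property
    def centre(self) -> tuple[float, float]:
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)


@dataclass
class BehaviourConfig:
    """Ageing / vibrotaxis / habituation behaviour model of a worm cohort.

    Defaults encode the study conditions: a Gompertz lifespan with median 14
    days; a piecewise-linear probability that a live worm shows no detectable
    movement during a 30 s inspection (2% up to day 5, 15% at day 9, 29% at
    day 21 and beyond); a weekly post-stimulus response probability
    (99/98/93%); a small multiplicative habituation decrement per stimulus that
    resets when the stimulus duration changes; and a 1%/stimulation-day loss of
    movement amount.

    ``baseline_motility`` is the swept area (px^2 per 30 s) of a young adult at
    the machine's nominal 30 um/pxl; it is converted through mm when rendering
    at other pixel pitches. Motility decays linearly with the fraction of the
    worm's life already lived.
    """

    lifespan_distribution: str = "gompertz"  # or "point"
    lifespan_median: float = 14.0
    lifespan_shape: float = 0.25  # Gompertz shape, 1/day
    baseline_motility: float = 1200.0  # px^2 / 30 s at 30 um/pxl
    no_move_days: tuple[float, ...] = (0.0, 5.0, 9.0, 21.0)
    no_move_probs: tuple[float, ...] = (0.02, 0.02, 0.15, 0.29)
    stimulated_response_weekly: tuple[float, ...] = (0.99, 0.98, 0.93)
    habituation_rate: float = 0.005  # per stimulus, multiplicative
    habituation_reset_on_duration_change: bool = True
    post_stimulus_motility_decrement: float = 0.01  # per prior stimulation day

    def __post_init__(self) -> None:
        probs = list(self.no_move_probs) + list(self.stimulated_response_weekly)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.baseline_motility < 0:
            raise ValueError("motility must be >= 0")
        if self.lifespan_distribution not in ("gompertz", "point"):
            raise ValueError(f"unknown lifespan distribution {self.lifespan_distribution!r}")
        if self.lifespan_distribution == "gompertz" and self.lifespan_shape <= 0:
            raise ValueError("Gompertz shape must be positive")

    @property
    def gompertz_scale(self) -> float:
        """Baseline hazard ``b`` such that the continuous median is the target."""
        a = self.lifespan_shape
        return a * np.log(2.0) / (np.exp(a * self.lifespan_median) - 1.0)

    def no_move_prob(self, day: float) -> float:
        """P(live worm shows no detectable movement in 30 s) on a given day."""
        return float(np.interp(day, self.no_move_days, self.no_move_probs))

    def response_prob(self, day: float) -> float:
        """Unhabituated post-stimulus response probability on a given day."""
        week = min(int((day - 1) // 7), len(self.stimulated_response_weekly) - 1)
        return float(self.stimulated_response_weekly[max(week, 0)])

    def motility(self, day: float, death_day: float, n_prior_stim_days: int = 0) -> float:
        """Swept area (px^2/30 s at 30 um/pxl) of a live worm on ``day``."""
        age_factor = max(0.0, 1.0 - day / float(death_day))
        stim_factor = (1.0 - self.post_stimulus_motility_decrement) ** n_prior_stim_days
        return self.baseline_motility * age_factor * stim_factor


@dataclass
class StimulusSchedule:
    """Per-day vibration durations for one condition.

    Conditions are named ``V_d<start>-t<duration>`` (vibration from assay day
    ``d`` for ``t`` seconds before the 30 s capture) or ``NV`` (never
    stimulated). ``durations`` maps assay day -> seconds; absent days are 0.
    """

    label: str
    durations: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.durations = {int(k): float(v) for k, v in self.durations.items() if v > 0}

    @classmethod
    def none(cls, label: str = "NV") -> "StimulusSchedule":
        return cls(label=label)

    @classmethod
    def constant(
        cls, start_day: int, duration: float, days: Sequence[int], label: str | None = None
    ) -> "StimulusSchedule":
        sel = {int(d): float(duration) for d in days if d >= start_day}
        if label is None:
            label = f"V_d{start_day}-t{duration:g}"
        return cls(label=label, durations=sel)

    @property
    def start_day(self) -> int | None:
        return min(self.durations) if self.durations else None

    def duration_on(self, day: int) -> float:
        return self.durations.get(int(day), 0.0)

    @property
    def is_stimulated(self) -> bool:
        return bool(self.durations)


@dataclass
class ConditionConfig:
    """One experimental condition: schedule + cohort sizing."""

    schedule: StimulusSchedule
    n_plates: int = 2
    plate: PlateConfig = field(default_factory=PlateConfig)
    behaviour: BehaviourConfig = field(default_factory=BehaviourConfig)
    inspections: int = 1  # daily inspections (3 emulates triple manual counting)

    @property
    def label(self) -> str:
        return self.schedule.label


@dataclass
class ExperimentConfig:
    """A named set of conditions sharing an acquisition-day calendar."""

    name: str
    conditions: list[ConditionConfig]
    acquisition_days: list[int]
    horizon: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"condition labels must be unique, got {labels}")
        self.acquisition_days = sorted(int(d) for d in self.acquisition_days)
        if self.horizon is None:
            self.horizon = max(self.acquisition_days)


# ---------------------------------------------------------------------------
# YAML round trip


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def dump_experiment(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def _build_condition(d: dict) -> ConditionConfig:
    sched = StimulusSchedule(**d["schedule"])
    plate = PlateConfig(**d.get("plate", {}))
    behaviour = BehaviourConfig(**d.get("behaviour", {}))
    return ConditionConfig(
        schedule=sched,
        n_plates=int(d.get("n_plates", 2)),
        plate=plate,
        behaviour=behaviour,
        inspections=int(d.get("inspections", 1)),
    )


def load_experiment(path: str | Path) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text())
    return ExperimentConfig(
        name=d["name"],
        conditions=[_build_condition(c) for c in d["conditions"]],
        acquisition_days=list(d["acquisition_days"]),
        horizon=d.get("horizon"),
        seed=int(d.get("seed", 0)),
    )
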