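"""End-to-end analysis: simulate -> detect -> curves -> error statistics.

This is the layer the CLI, the tests and the acceptance script drive. Images
are rendered and consumed plate-day by plate-day so memory stays flat.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BehaviourConfig, ConditionConfig, ExperimentConfig, PlateConfig
from .detect import DetectParams, ImageSequence
from .lifespan import SurvivalCurve, detect_worms, PlateTracker
from .simulate import ConditionSimulation, simulate_condition
from .stats import ErrorReport, error_report
from .stimulus import ResponseRecord, build_response_records

__all__ = [
    "ConditionResult",
    "default_detect_params",
    "tracking_gate_px",
    "analyze_condition",
    "run_condition",
    "run_experiment",
    "experiment3_config",
]


def default_detect_params() -> DetectParams:
    # simulated camera is rigidly fixed, so alignment is a no-op we skip
    return DetectParams(alignment="none")


def tracking_gate_px(plate: PlateConfig, behaviour: BehaviourConfig) -> float:
    """Day-to-day linking gate: the largest plausible daily displacement.

    Overnight step plus two in-sequence crawls of a young adult, with a
    5-worm-length floor.
    """
    mot_px2 = behaviour.baseline_motility * (0.03 / plate.mm_per_px) ** 2
    step = max(4.0, 4.0 * np.sqrt(mot_px2))
    crawl = max(2.0, 0.5 * mot_px2 / plate.worm_width_px)
    # 1.8x: the overnight step plus its lawn-drift component
    return max(5.0 * plate.worm_length_px, 1.8 * step + 2.0 * crawl + plate.worm_length_px)


def _worm_area_bounds(plate: PlateConfig) -> tuple[int, int]:
    body = (plate.worm_length_px + 2) * plate.worm_width_px
    return max(4, int(0.2 * body)), int(6 * body)


@dataclass
class ConditionResult:
    """Curves, detections summary and error statistics for one condition."""

    label: str
    days: list[int]
    auto_plates: list[SurvivalCurve]
    ref_plates: list[SurvivalCurve]
    truth: pd.DataFrame
    report: ErrorReport
    response_records: list[ResponseRecord] = field(default_factory=list)

    @property
    def auto_curve(self) -> SurvivalCurve:
        counts = np.sum([c.counts for c in self.auto_plates], axis=0)
        n0 = sum(c.n0 for c in self.auto_plates)
        return SurvivalCurve(self.label, list(self.days), counts, n0)

    @property
    def reference_curve(self) -> SurvivalCurve:
        counts = np.sum([c.counts for c in self.ref_plates], axis=0)
        n0 = sum(c.n0 for c in self.ref_plates)
        return SurvivalCurve(self.label, list(self.days), counts, n0, rectified=True)

    def true_counts(self) -> np.ndarray:
        alive = self.truth.groupby(["day"])["alive"].sum()
        return np.asarray([int(alive.get(d, 0)) for d in self.days])


def analyze_plate(
    sim: ConditionSimulation,
    plate: int,
    params: DetectParams | None = None,
    *,
    reference_mode: str | None = None,
) -> tuple[SurvivalCurve, SurvivalCurve]:
    """Detect + track one plate; return (automatic SA, reference SM) curves."""
    params = params or default_detect_params()
    cfg = sim.plate_config
    min_a, max_a = _worm_area_bounds(cfg)
    gate = tracking_gate_px(cfg, sim.behaviour)
    if reference_mode is None:
        reference_mode = "triple_inspection" if sim.inspections >= 3 else "single_inspection"
    auto = PlateTracker(cfg.n_worms, gate)
    ref = PlateTracker(cfg.n_worms, gate)
    for day in sim.days:
        dets_by_phase: dict[str, list] = {}
        for phase in sim.phases(day):
            stack = sim.render_sequence(plate, day, phase)
            seq = ImageSequence(stack, plate=plate, day=day, phase=phase)
            dets_by_phase[phase] = detect_worms(
                [seq], params, min_area=min_a, max_area=max_a
            )
        insp = [p for p in dets_by_phase if p.startswith("before")]
        auto_sel = {insp[0]: dets_by_phase[insp[0]]}
        if "after" in dets_by_phase:
            auto_sel["after"] = dets_by_phase["after"]
        auto.update(day, auto_sel)
        ref_sel = dets_by_phase if reference_mode == "triple_inspection" else auto_sel
        ref.update(day, ref_sel)
    sa = SurvivalCurve(sim.schedule.label, list(sim.days), auto.automatic_counts(), cfg.n_worms)
    sm = SurvivalCurve(
        sim.schedule.label,
        list(sim.days),
        ref.reference_counts(),
        cfg.n_worms,
        rectified=True,
    )
    return sa, sm


def analyze_condition(
    sim: ConditionSimulation, params: DetectParams | None = None
) -> ConditionResult:
    """Run the full detection/curve/error pipeline over a simulated condition."""
    auto_plates, ref_plates = [], []
    for p in range(sim.n_plates):
        sa, sm = analyze_plate(sim, p, params)
        auto_plates.append(sa)
        ref_plates.append(sm)
    rep = error_report(ref_plates, auto_plates, condition=sim.schedule.label)
    records = build_response_records(sim.truth, sim.schedule)
    return ConditionResult(
        label=sim.schedule.label,
        days=list(sim.days),
        auto_plates=auto_plates,
        ref_plates=ref_plates,
        truth=sim.truth,
        report=rep,
        response_records=records,
    )


def run_condition(cond: ConditionConfig, days: list[int], seed: int) -> ConditionResult:
    """Simulate and analyze one condition end to end."""
    sim = simulate_condition(
        cond.plate,
        cond.behaviour,
        cond.schedule,
        cond.n_plates,
        days,
        seed,
        inspections=cond.inspections,
    )
    return analyze_condition(sim)


def run_experiment(cfg: ExperimentConfig, seed: int | None = None) -> dict[str, ConditionResult]:
    """Run every condition of an experiment; seeds derive per condition."""
    base = cfg.seed if seed is None else seed
    out = {}
    for i, cond in enumerate(cfg.conditions):
        out[cond.label] = run_condition(cond, cfg.acquisition_days, int(base) + 1000 * i)
    return out


# ---------------------------------------------------------------------------
# the lifespan-error experiment (two conditions, weekday acquisition)

WEEKEND_DAYS = frozenset({3, 4, 10, 11, 17, 18})
EXPERIMENT3_DAYS = tuple(d for d in range(1, 22) if d not in WEEKEND_DAYS)
EXPERIMENT3_V_DAYS = (5, 6, 7, 8, 9, 12, 13, 14, 15, 16, 19, 20, 21)


def experiment3_config(
    *,
    n_plates: int = 8,
    nv_replications: int = 2,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> ExperimentConfig:
    """The lifespan-error experiment: NV replications vs V_d5-t3.

    Daily weekday acquisition over a 21-day horizon; the stimulated condition
    receives a 3 s vibration immediately before the 30 s capture on every
    acquisition day from day 5 on.
    """
    from .config import StimulusSchedule

    plate = PlateConfig(image_size=image_size)
    behaviour = BehaviourConfig()
    conds = []
    for r in range(nv_replications):
        conds.append(
            ConditionConfig(
                schedule=StimulusSchedule.none(
                    "NV" if nv_replications == 1 else f"NV_rep{r+1}"
                ),
                n_plates=n_plates,
                plate=plate,
                behaviour=behaviour,
            )
        )
    conds.append(
        ConditionConfig(
            schedule=StimulusSchedule.constant(5, 3.0, EXPERIMENT3_V_DAYS),
            n_plates=n_plates,
            plate=plate,
            behaviour=behaviour,
        )
    )
    return ExperimentConfig(
        name="experiment3",
        conditions=conds,
        acquisition_days=list(EXPERIMENT3_DAYS),
        seed=seed,
    )


def error_experiment_summary(
    seeds: list[int],
    *,
    n_plates: int = 8,
    image_size: tuple[int, int] = (256, 256),
) -> pd.DataFrame:
    """Replicate the lifespan-error experiment over seeds.

    For every seed the NV replications and the stimulated V_d5-t3 cohort are
    simulated and pushed through the full pipeline; returns one row per seed
    with eT (percent, NV averaged over its replications), the pooled
    plate-error sigma and mean, and the NV-vs-V error-variance F test p-value.
    """
    from .stats import variance_difference_test

    rows = []
    for seed in seeds:
        cfg = experiment3_config(n_plates=n_plates, image_size=image_size, seed=int(seed))
        res = run_experiment(cfg)
        nv = [res["NV_rep1"], res["NV_rep2"]]
        v = res["V_d5-t3"]
        nv_ep = np.concatenate([r.report.plate_day_errors for r in nv])
        v_ep = v.report.plate_day_errors
        _, p = variance_difference_test(nv_ep, v_ep)
        rows.append(
            {
                "seed": int(seed),
                "eT_NV": float(np.mean([r.report.eT_percent for r in nv])),
                "eT_V": float(v.report.eT_percent),
                "sigma_NV": float(
                    np.sqrt((nv_ep**2).sum() / (nv_ep.size - 1))
                ),
                "sigma_V": float(v.report.sigma),
                "mean_eP_NV": float(nv_ep.mean()),
                "mean_eP_V": float(v_ep.mean()),
                "var_test_p": float(p),
                "n_worms_NV": int(sum(r.report.n0 for r in nv)),
                "n_worms_V": int(v.report.n0),
            }
        )
    return pd.DataFrame(rows)
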