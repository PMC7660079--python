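"""Lifespan-curve error statistics, variance comparison and survival tests.

The error of an automated survival curve SA against the manual reference SM
is summarised by

* per-day error            e(k)   = |SM(k) - SA(k)|                  (individuals)
* total error              eT     = mean_k e(k) over acquisition days, reported
                                    as a percentage of the initial cohort n0
* signed per-plate errors  eP(p)  = x(p) - X(p)   (measured minus reference)
* mean plate error         eP     = mean_p eP(p)
* plate-error deviation    sigma  = sqrt( sum_p eP(p)^2 / (Np - 1) )

sigma is, literally, the uncentred root mean square with an Np-1 denominator;
a conventional centred sample SD is available behind a flag. Kaplan-Meier and
the log-rank test are delegated to lifelines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .lifespan import SurvivalCurve

__all__ = [
    "ErrorReport",
    "per_day_error",
    "total_error",
    "plate_errors",
    "plate_error_sd",
    "variance_difference_test",
    "km_estimator",
    "logrank_test",
    "error_report",
]


def _common_days(sm: SurvivalCurve, sa: SurvivalCurve) -> list[int]:
    days = [d for d in sm.days if d in set(sa.days)]
    if not days:
        raise ValueError("curves share no acquisition days")
    return days


def per_day_error(sm: SurvivalCurve, sa: SurvivalCurve, k: int) -> int:
    """e(k) = |SM(k) - SA(k)| on acquisition day ``k`` (individuals)."""
    if k not in sm.days or k not in sa.days:
        raise ValueError(f"day {k} is not covered by both curves")
    return int(abs(int(sm.counts[sm.days.index(k)]) - int(sa.counts[sa.days.index(k)])))


def total_error(
    sm: SurvivalCurve, sa: SurvivalCurve, *, normalise_by_n0: bool = True
) -> float:
    """eT: mean of e(k) over the shared acquisition days.

    With ``normalise_by_n0`` (the default) the result is a percentage of the
    initial cohort size; otherwise it is in individuals.
    """
    days = _common_days(sm, sa)
    mean_e = float(np.mean([per_day_error(sm, sa, k) for k in days]))
    if not normalise_by_n0:
        return mean_e
    if sm.n0 <= 0:
        raise ValueError("n0 must be positive to normalise")
    return 100.0 * mean_e / sm.n0


def plate_errors(x: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Signed per-plate errors eP(p) = x(p) - X(p) (measured minus reference)."""
    x = np.asarray(x, dtype=float)
    X = np.asarray(X, dtype=float)
    if x.shape != X.shape:
        raise ValueError(f"mismatched plate sets: {x.shape} vs {X.shape}")
    return x - X


def plate_error_sd(ep: np.ndarray, *, centred: bool = False) -> float:
    """sigma = sqrt( sum eP(p)^2 / (Np - 1) ), the uncentred form.

    ``centred=True`` gives the conventional sample standard deviation instead.
    """
    ep = np.asarray(ep, dtype=float)
    n = ep.size
    if n < 2:
        raise ValueError("need at least two plates")
    if centred:
        return float(np.std(ep, ddof=1))
    return float(np.sqrt(np.sum(ep**2) / (n - 1)))


def variance_difference_test(
    ep_a: np.ndarray, ep_b: np.ndarray, *, method: str = "f"
) -> tuple[float, float]:
    """Two-sided test for unequal error variances between two conditions.

    ``method='f'`` is the variance-ratio F test (statistic = s_a^2 / s_b^2 with
    (n_a-1, n_b-1) dof); ``method='levene'`` is the robust alternative. Two
    degenerate zero-variance samples are equal by convention (p = 1).
    Returns (statistic, p).
    """
    a = np.asarray(ep_a, dtype=float)
    b = np.asarray(ep_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two plates per condition")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0, 1.0
    if method == "f":
        if vb == 0.0 or va == 0.0:
            return float("inf"), 0.0
        f = va / vb
        dist = sps.f(a.size - 1, b.size - 1)
        p = 2.0 * min(dist.cdf(f), dist.sf(f))
        return float(f), float(min(p, 1.0))
    if method == "levene":
        stat, p = sps.levene(a, b, center="median")
        return float(stat), float(p)
    raise ValueError(f"unknown method {method!r}")


def km_estimator(
    durations: np.ndarray, event_observed: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate.

    Returns (times, S(t)) including t=0, S=1; ``event_observed`` marks deaths
    (1) versus right-censored observations (0), defaulting to all deaths.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 1:
        raise ValueError("need at least one observation")
    if event_observed is None:
        event_observed = np.ones_like(durations)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=np.asarray(event_observed))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(
    durations_a: np.ndarray,
    durations_b: np.ndarray,
    event_a: np.ndarray | None = None,
    event_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """Standard two-group log-rank test: (chi-square statistic on 1 dof, p)."""
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)) and event_a is None and event_b is None:
        return 0.0, 1.0  # identical samples carry no evidence
    res = _ll_logrank(
        a,
        b,
        event_observed_A=None if event_a is None else np.asarray(event_a),
        event_observed_B=None if event_b is None else np.asarray(event_b),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class ErrorReport:
    """Error statistics of one condition's automatic curve against reference."""

    condition: str
    days: list[int]
    e_per_day: np.ndarray  # e(k), individuals
    eT_percent: float
    plate_day_errors: np.ndarray  # signed eP observations (per plate per day)
    mean_plate_error: float
    sigma: float
    n0: int
    n_plates: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "days": list(map(int, self.days)),
            "e_per_day": [int(v) for v in self.e_per_day],
            "eT_percent": float(self.eT_percent),
            "mean_plate_error": float(self.mean_plate_error),
            "sigma": float(self.sigma),
            "n0": int(self.n0),
            "n_plates": int(self.n_plates),
            **self.extra,
        }


def error_report(
    sm_plates: list[SurvivalCurve],
    sa_plates: list[SurvivalCurve],
    *,
    condition: str = "",
) -> ErrorReport:
    """Full error report for one condition from per-plate SM and SA curves.

    e(k) and eT follow the summed-plates definition; the signed per-plate
    errors are taken per plate per acquisition day (measured minus reference),
    the observation unit behind the per-plate error histograms.
    """
    if len(sm_plates) != len(sa_plates) or not sm_plates:
        raise ValueError("need matching non-empty per-plate curve lists")
    days = list(sm_plates[0].days)
    for c in sm_plates + sa_plates:
        if list(c.days) != days:
            raise ValueError("all plates must share the acquisition days")
    sm_sum = np.sum([c.counts for c in sm_plates], axis=0)
    sa_sum = np.sum([c.counts for c in sa_plates], axis=0)
    n0 = int(sum(c.n0 for c in sm_plates))
    e = np.abs(sm_sum - sa_sum).astype(int)
    eT = 100.0 * float(e.mean()) / n0
    ep = np.concatenate(
        [
            plate_errors(sa.counts, sm.counts)
            for sm, sa in zip(sm_plates, sa_plates)
        ]
    )
    return ErrorReport(
        condition=condition,
        days=days,
        e_per_day=e,
        eT_percent=eT,
        plate_day_errors=ep,
        mean_plate_error=float(ep.mean()),
        sigma=plate_error_sd(ep),
        n0=n0,
        n_plates=len(sm_plates),
    )
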