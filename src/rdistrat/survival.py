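"""Product-limit (Kaplan–Meier) estimation of event-free survival.

Event-free survival times are measured from a common origin — by default
the 180-day landmark, so curves are comparable across strata; measuring
from each patient's end of therapy is available as an option. The
product-limit estimator is

    S(t) = prod_{t_i <= t} (1 - d_i / n_i),

the product running over distinct event times, with d_i events among n_i
subjects at risk. Subjects censored at an event time are counted at risk
at that time (events before censorings, the standard tie convention). The
estimator is computed as the literal sequential product over event times
so it agrees bit-for-bit with an explicit risk-set recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .selection import DEFAULT_LANDMARK_DAY
from .stratify import StratumAssignment


@dataclass
class KMCurve:
    """A product-limit survival estimate with at-risk bookkeeping.

    ``times`` are the sorted distinct event times; ``survival`` the value
    of S just after each; ``at_risk``/``n_events`` the risk-set sizes and
    event counts at those times. ``max_time`` is the largest observed time
    (event or censoring); evaluation beyond it is extrapolation.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_subjects: int
    max_time: float
    origin: str = "landmark"
    greenwood_se: np.ndarray = field(default=None, repr=False)


def efs_times(
    cohort: Cohort,
    origin_rule: str = "landmark",
    landmark_day: int = DEFAULT_LANDMARK_DAY,
) -> list[tuple[float, bool]]:
    """Per-patient (time, event) pairs from the chosen origin.

    ``origin_rule`` is ``"landmark"`` (a common origin at the landmark
    day) or ``"end_of_therapy"`` (each patient's own end of therapy). A
    non-positive time signals that selection was not applied and raises.
    """
    if origin_rule not in ("landmark", "end_of_therapy"):
        raise ValueError(f"unknown origin_rule {origin_rule!r}")
    out: list[tuple[float, bool]] = []
    for course in cohort:
        origin = landmark_day if origin_rule == "landmark" else course.end_of_therapy_day
        endpoint = course.event_day if course.event_observed else course.censor_day
        t = endpoint - origin
        if t <= 0:
            raise ValueError(
                f"patient {course.patient_id}: non-positive survival time {t}; "
                "apply landmark selection before estimating survival"
            )
        out.append((float(t), course.event_observed))
    return out


def km_estimate(times_events: list[tuple[float, bool]], origin: str = "landmark") -> KMCurve:
    """Product-limit estimate from (time, event-indicator) pairs."""
    if not times_events:
        raise ValueError("cannot estimate survival from an empty sample")
    times = np.array([t for t, _ in times_events], dtype=float)
    events = np.array([bool(e) for _, e in times_events])
    if np.any(times <= 0):
        raise ValueError("all survival times must be positive")

    event_times = np.unique(times[events])
    surv_vals = []
    at_risk = []
    n_events = []
    greenwood = []
    s = 1.0
    gw = 0.0
    for t in event_times:
        n_i = int(np.sum(times >= t))  # censored ties remain at risk
        d_i = int(np.sum(events & (times == t)))
        s = s * (1.0 - d_i / n_i)
        at_risk.append(n_i)
        n_events.append(d_i)
        surv_vals.append(s)
        if n_i > d_i:
            gw += d_i / (n_i * (n_i - d_i))
            greenwood.append(s * np.sqrt(gw))
        else:
            greenwood.append(0.0)

    return KMCurve(
        times=event_times,
        survival=np.array(surv_vals, dtype=float),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_events, dtype=int),
        n_subjects=len(times),
        max_time=float(times.max()),
        origin=origin,
        greenwood_se=np.array(greenwood, dtype=float),
    )


def survival_at(curve: KMCurve, t: float, with_flag: bool = False):
    """Right-continuous step-function evaluation of S(t).

    With ``with_flag=True`` returns ``(value, extrapolated)`` where the
    flag marks evaluation beyond the last observed time.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    idx = int(np.searchsorted(curve.times, t, side="right"))
    value = 1.0 if idx == 0 else float(curve.survival[idx - 1])
    if with_flag:
        return value, t > curve.max_time
    return value


def greenwood_se_at(curve: KMCurve, t: float) -> float:
    """Greenwood standard error of S(t) (0 before the first event)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    idx = int(np.searchsorted(curve.times, t, side="right"))
    return 0.0 if idx == 0 else float(curve.greenwood_se[idx - 1])


def km_by_stratum(
    cohort: Cohort,
    assignment: StratumAssignment,
    origin_rule: str = "landmark",
    landmark_day: int = DEFAULT_LANDMARK_DAY,
) -> dict[int, KMCurve]:
    """One KM curve per stratum of an assignment."""
    curves: dict[int, KMCurve] = {}
    for stratum in assignment.strata():
        sub = Cohort(
            courses=[c for c in cohort if assignment.labels[c.patient_id] == stratum],
            provenance=dict(cohort.provenance),
        )
        curves[stratum] = km_estimate(
            efs_times(sub, origin_rule, landmark_day), origin=origin_rule
        )
    return curves


def curve_frame(curve: KMCurve):
    """Curve export table: time, at_risk, n_events, survival."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.times,
            "at_risk": curve.at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival,
        }
    )
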