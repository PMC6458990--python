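"""Figure builders: tau-delta plane views, KM panels, adaptation bars.

Figures are run artifacts; the numbers behind them live in the exported
CSVs. All functions save to a file and close the figure.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import ADAPTATION_CAUSES, Arm, Cohort
from .metrics import RDITrajectory
from .regimen import TEMPLATES, intended_schedule, target_rdi
from .stratify import StratumAssignment
from .survival import KMCurve

_STRATUM_CMAP = plt.get_cmap("tab10")


def _target_polyline(arm: Arm) -> tuple[np.ndarray, np.ndarray]:
    template = TEMPLATES[arm]
    days = np.array(intended_schedule(template), dtype=float)
    taus = days / template.time_normalizer_days
    deltas = np.arange(1, template.n_cycles + 1) / template.n_cycles
    return taus, deltas


def plot_tau_delta(
    cohort: Cohort,
    trajectories: dict[str, RDITrajectory],
    assignment: StratumAssignment | None,
    mode: str,
    path: str | Path,
) -> Path:
    """Draw the tau-delta plane: rRDI polylines, aRDI points, or both.

    Colouring follows the stratum assignment when given, otherwise the
    randomized arm. Target trajectories/markers for both arms are drawn in
    black.
    """
    if len(cohort) == 0:
        raise ValueError("cannot plot an empty cohort")
    if mode not in ("lines", "points", "both"):
        raise ValueError(f"unknown mode {mode!r}")

    fig, ax = plt.subplots(figsize=(7, 5))

    def colour_of(course) -> tuple:
        if assignment is not None:
            return _STRATUM_CMAP((assignment.labels[course.patient_id] - 1) % 10)
        return {"reg-c": "purple", "reg-di": "pink"}[course.arm.value]

    for course in cohort:
        traj = trajectories[course.patient_id]
        taus = [p.tau for p in traj.points]
        deltas = [p.delta for p in traj.points]
        c = colour_of(course)
        if mode in ("lines", "both"):
            ax.plot(taus, deltas, color=c, alpha=0.35, linewidth=0.8)
        if mode in ("points", "both"):
            marker = "s" if course.arm is Arm.REG_C else "o"
            ax.scatter([taus[-1]], [deltas[-1]], color=c, marker=marker, s=14, alpha=0.7)

    for arm, style, marker in ((Arm.REG_DI, ":", "o"), (Arm.REG_C, "-", "s")):
        taus, deltas = _target_polyline(arm)
        if mode in ("lines", "both"):
            ax.plot(taus, deltas, color="black", linestyle=style, linewidth=2.0)
        tau_t, delta_t = target_rdi(TEMPLATES[arm])
        ax.scatter([tau_t], [delta_t], color="black", marker=marker, s=60, zorder=5)

    ax.set_xlabel(r"standardised time on treatment $\tau$")
    ax.set_ylabel(r"standardised cumulative dose $\delta$")
    ax.set_title("Dose-intensity trajectories in the time-dose plane")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_km(curves: dict[int, KMCurve], path: str | Path, title: str = "Event-free survival") -> Path:
    """Step plot of one KM curve per stratum."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for stratum, curve in sorted(curves.items()):
        times = np.concatenate([[0.0], curve.times])
        surv = np.concatenate([[1.0], curve.survival])
        ax.step(
            times,
            surv,
            where="post",
            color=_STRATUM_CMAP((stratum - 1) % 10),
            label=f"stratum {stratum} (n={curve.n_subjects})",
        )
    ax.set_xlabel(f"days since {next(iter(curves.values())).origin.replace('_', ' ')}")
    ax.set_ylabel("event-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_adaptations(table, path: str | Path) -> Path:
    """Grouped bars of adaptation proportions per stratum across cycles,
    coloured by recorded cause."""
    strata = sorted(table["stratum"].unique())
    causes = [c.value for c in ADAPTATION_CAUSES]
    fig, axes = plt.subplots(
        1, len(strata), figsize=(3.2 * len(strata), 3.4), sharey=True, squeeze=False
    )
    width = 0.8 / len(causes)
    for ax, stratum in zip(axes[0], strata):
        sub = table[table["stratum"] == stratum]
        for ci, cause in enumerate(causes):
            rows = sub[sub["cause"] == cause].sort_values("cycle_index")
            ax.bar(
                rows["cycle_index"] + (ci - len(causes) / 2 + 0.5) * width,
                rows["proportion"],
                width=width,
                label=cause,
            )
        ax.set_title(f"stratum {stratum}", fontsize=9)
        ax.set_xlabel("cycle")
        ax.set_xticks(range(1, 7))
    axes[0][0].set_ylabel("proportion adapted")
    axes[0][-1].legend(fontsize=7)
    fig.suptitle("Treatment adaptations per cycle and cause")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
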