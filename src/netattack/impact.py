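"""Outcome measures reduced from attack trajectories.

Five outcomes summarize each attack on each network:

* **impact magnitude** for components and average path length — the peak
  value reached anywhere along the trajectory minus the initial value;
* **attack extent** for components and average path length — the proportion
  of the network's original symptoms removed when the peak is first reached;
* **connectivity extent** — the proportion removed when connectivity first
  drops to half its initial value.

Peak ties resolve to the first attainment; extents use the initial node
count N as denominator; trajectory steps where a metric is undefined (NaN
path length on an edgeless remnant) are skipped by the peak search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .attack import AttackTrajectory

__all__ = [
    "ConditionOutcome",
    "DescriptiveSummary",
    "impact_magnitude",
    "attack_extent",
    "connectivity_extent",
    "outcome_from_trajectory",
    "aggregate_random",
    "summarize",
    "OUTCOME_FIELDS",
]

MetricName = Literal["components", "path_length"]

OUTCOME_FIELDS = (
    "components_magnitude",
    "components_extent",
    "pathlength_magnitude",
    "pathlength_extent",
    "connectivity_extent",
)


@dataclass(frozen=True)
class ConditionOutcome:
    """The five outcomes for one network under one attack condition."""

    network_id: str
    condition: str
    components_magnitude: float
    components_extent: float
    pathlength_magnitude: float
    pathlength_extent: float
    connectivity_extent: float


@dataclass(frozen=True)
class DescriptiveSummary:
    """Mean (SD), 20%-trimmed mean (SE), and range of a set of outcomes."""

    mean: float
    sd: float
    trimmed_mean: float
    trimmed_se: float
    minimum: float
    maximum: float


def _metric_array(traj: AttackTrajectory, metric: MetricName) -> np.ndarray:
    if metric == "components":
        return traj.components.astype(float)
    if metric == "path_length":
        return traj.path_length
    raise ValueError(f"unknown metric {metric!r}")


def impact_magnitude(traj: AttackTrajectory, metric: MetricName) -> float:
    """Peak metric value along the trajectory minus the initial value."""
    arr = _metric_array(traj, metric)
    if np.isnan(arr).all():
        raise ValueError(f"{metric} undefined at every step of the trajectory")
    if np.isnan(arr[0]):
        raise ValueError(f"{metric} undefined at step 0 (initial network has no edges)")
    return float(np.nanmax(arr) - arr[0])


def attack_extent(traj: AttackTrajectory, metric: MetricName) -> float:
    """Proportion of original symptoms removed when the peak is first reached."""
    arr = _metric_array(traj, metric)
    if np.isnan(arr[0]):
        raise ValueError(f"{metric} undefined at step 0")
    peak = np.nanmax(arr)
    with np.errstate(invalid="ignore"):
        hit = arr >= peak - 1e-12  # NaN compares False, so undefined steps are skipped
    first = int(np.argmax(hit))
    return first / traj.n_initial


def connectivity_extent(traj: AttackTrajectory) -> float:
    """Proportion removed when connectivity first drops to <= 50% of initial."""
    conn = traj.connectivity
    if conn[0] <= 0:
        raise ValueError("initial connectivity is zero")
    hit = np.flatnonzero(conn <= 0.5 * conn[0])
    first = int(hit[0])  # guaranteed: the final single-node state has no edges
    return first / traj.n_initial


def outcome_from_trajectory(traj: AttackTrajectory, network_id: str) -> ConditionOutcome:
    return ConditionOutcome(
        network_id=network_id,
        condition=traj.condition,
        components_magnitude=impact_magnitude(traj, "components"),
        components_extent=attack_extent(traj, "components"),
        pathlength_magnitude=impact_magnitude(traj, "path_length"),
        pathlength_extent=attack_extent(traj, "path_length"),
        connectivity_extent=connectivity_extent(traj),
    )


def aggregate_random(
    trajectories: Sequence[AttackTrajectory],
    network_id: str,
    method: Literal["per_replicate", "mean_trajectory"] = "per_replicate",
) -> ConditionOutcome:
    """Collapse random-attack replicates into one outcome row.

    ``per_replicate`` (default) computes the five outcomes on every replicate
    and averages them.  ``mean_trajectory`` first averages the state-metric
    trajectories pointwise across replicates and reduces that mean
    trajectory; it is kept for sensitivity analysis.
    """
    if not trajectories:
        raise ValueError("need at least one replicate")
    if method == "per_replicate":
        rows = [outcome_from_trajectory(t, network_id) for t in trajectories]
        return ConditionOutcome(
            network_id=network_id,
            condition="random",
            **{
                f: float(np.mean([getattr(r, f) for r in rows]))
                for f in OUTCOME_FIELDS
            },
        )
    if method == "mean_trajectory":
        t0 = trajectories[0]
        with np.errstate(invalid="ignore"):
            mean_traj = AttackTrajectory(
                condition="random",
                removal_order=t0.removal_order,
                connectivity=np.mean([t.connectivity for t in trajectories], axis=0),
                components=np.mean([t.components for t in trajectories], axis=0),
                path_length=np.nanmean(
                    np.array([t.path_length for t in trajectories]), axis=0
                ),
                mode=t0.mode,
            )
        return outcome_from_trajectory(mean_traj, network_id)
    raise ValueError(f"unknown aggregation method {method!r}")


def summarize(values: Sequence[float], trim: float = 0.2) -> DescriptiveSummary:
    """Descriptives in the study's reporting format.

    SD uses the n-1 divisor; the trimmed SE is the Winsorized SD divided by
    (1 - 2*trim) * sqrt(n), the standard error estimate that goes with a
    trimmed mean.
    """
    from .robust import trimmed_mean, winsorize

    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values for trimmed descriptives")
    n = len(x)
    wins = winsorize(x, trim)
    wins_sd = float(np.std(wins, ddof=1))
    return DescriptiveSummary(
        mean=float(x.mean()),
        sd=float(np.std(x, ddof=1)),
        trimmed_mean=trimmed_mean(x, trim),
        trimmed_se=wins_sd / ((1 - 2 * trim) * np.sqrt(n)),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )
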