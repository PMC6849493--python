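"""End-to-end study orchestration.

For every input network: compute the four ranking measures, run the four
targeted attacks plus the random-attack campaign, reduce each trajectory to
the five outcome measures, then compare the attack conditions per outcome
with descriptives, an omnibus robust trimmed-means bootstrap-t test, and
familywise post hoc comparisons.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .attack import AttackConfig, random_attack, targeted_attack
from .impact import (
    OUTCOME_FIELDS,
    ConditionOutcome,
    aggregate_random,
    outcome_from_trajectory,
    summarize,
)
from .measures import detect_modules, rank_nodes
from .network import SymptomNetwork
from .robust import RobustConfig, OmnibusResult, omnibus_bootstrap_t, posthoc_bootstrap_t
from .synthetic import EnsembleSpec, gen_network_ensemble

__all__ = ["StudyConfig", "StudyReport", "run_study", "write_report"]

log = logging.getLogger(__name__)

ALL_CONDITIONS = ("random", "degree", "strength", "bridgeness", "overlap")


@dataclass(frozen=True)
class StudyConfig:
    """Complete recipe for one study run."""

    networks: Sequence[SymptomNetwork] | None = None
    ensemble: EnsembleSpec | None = None
    conditions: tuple[str, ...] = ALL_CONDITIONS
    mode: Literal["initial", "recalculated"] = "initial"
    n_sims: int = 2000
    attack: AttackConfig = AttackConfig()
    robust: RobustConfig = RobustConfig()
    random_aggregation: Literal["per_replicate", "mean_trajectory"] = "per_replicate"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 attack conditions")
        unknown = set(self.conditions) - set(ALL_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if (self.networks is None) == (self.ensemble is None):
            raise ValueError("provide exactly one of networks or ensemble")


@dataclass(frozen=True)
class StudyReport:
    outcomes: pd.DataFrame = field(repr=False)  # one row per network x condition
    descriptives: pd.DataFrame = field(repr=False)  # per outcome x condition
    omnibus: dict[str, OmnibusResult] = field(repr=False)
    posthoc: dict[str, pd.DataFrame] = field(repr=False)
    manifest: dict = field(repr=False)


def _network_outcomes(
    net: SymptomNetwork,
    network_id: str,
    config: StudyConfig,
    seed: int,
) -> list[ConditionOutcome]:
    module_measures = {"bridgeness", "overlap"} & set(config.conditions)
    assignment = None
    if module_measures and config.mode == "initial":
        assignment = detect_modules(net)
    rows = []
    for cond in config.conditions:
        if cond == "random":
            trajs = random_attack(net, n_sims=config.n_sims, seed=seed, config=config.attack)
            rows.append(aggregate_random(trajs, network_id, config.random_aggregation))
        elif config.mode == "initial":
            order = rank_nodes(net, cond, assignment)
            traj = targeted_attack(net, order=order, config=config.attack)
            rows.append(outcome_from_trajectory(traj, network_id))
        else:
            traj = targeted_attack(
                net, mode="recalculated", measure=cond, config=config.attack
            )
            rows.append(outcome_from_trajectory(traj, network_id))
    return rows


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full attack study; see module docstring.

    Networks that fail a stage are skipped with a logged reason and listed
    in the manifest; the study aborts only if fewer than 5 networks survive.
    """
    if config.ensemble is not None:
        networks = gen_network_ensemble(config.ensemble)
        ids = [f"net_{i:03d}" for i in range(len(networks))]
    else:
        networks = list(config.networks)
        ids = [f"net_{i:03d}" for i in range(len(networks))]

    net_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 np.random.SeedSequence(config.seed).spawn(len(networks))]

    all_rows: list[ConditionOutcome] = []
    skipped: list[dict] = []
    for net, nid, nseed in zip(networks, ids, net_seeds):
        try:
            all_rows.extend(_network_outcomes(net, nid, config, nseed))
        except Exception as exc:  # noqa: BLE001 - any stage failure skips the network
            log.warning("skipping %s: %s", nid, exc)
            skipped.append({"network": nid, "reason": str(exc)})
    n_ok = len({r.network_id for r in all_rows})
    if n_ok < 5:
        raise RuntimeError(f"only {n_ok} networks survived; need at least 5")

    outcomes = pd.DataFrame(
        [
            {"network": r.network_id, "condition": r.condition,
             **{f: getattr(r, f) for f in OUTCOME_FIELDS}}
            for r in all_rows
        ]
    )

    desc_rows = []
    omnibus: dict[str, OmnibusResult] = {}
    posthoc: dict[str, pd.DataFrame] = {}
    for outcome in OUTCOME_FIELDS:
        wide = outcomes.pivot(index="network", columns="condition", values=outcome)
        wide = wide[[c for c in config.conditions]]
        for cond in config.conditions:
            s = summarize(wide[cond].dropna().to_numpy(), trim=config.robust.trim)
            desc_rows.append(
                {"outcome": outcome, "condition": cond, "mean": s.mean, "sd": s.sd,
                 "trimmed_mean": s.trimmed_mean, "trimmed_se": s.trimmed_se,
                 "minimum": s.minimum, "maximum": s.maximum}
            )
        X = wide.to_numpy()
        omnibus[outcome] = omnibus_bootstrap_t(X, config.robust)
        comps = posthoc_bootstrap_t(X, config.robust, labels=list(config.conditions))
        posthoc[outcome] = pd.DataFrame(
            [
                {"pair": f"{c.pair[0]} vs. {c.pair[1]}", "psihat": c.psihat,
                 "ci_low": c.ci_low, "ci_high": c.ci_high,
                 "test_statistic": c.test_statistic,
                 "critical_value": c.critical_value, "significant": c.significant}
                for c in comps
            ]
        )

    manifest = {
        "netattack_version": __version__,
        "seed": config.seed,
        "n_networks": len(networks),
        "n_analyzed": n_ok,
        "skipped": skipped,
        "conditions": list(config.conditions),
        "mode": config.mode,
        "n_sims": config.n_sims,
        "weighted_connectivity": config.attack.weighted_connectivity,
        "distance_mode": config.attack.distance_mode,
        "random_aggregation": config.random_aggregation,
        "robust": {"trim": config.robust.trim, "n_boot": config.robust.n_boot,
                   "alpha": config.robust.alpha, "seed": config.robust.seed},
        "ensemble": None
        if config.ensemble is None
        else {"k": config.ensemble.k, "node_range": list(config.ensemble.node_range),
              "density_range": list(config.ensemble.density_range),
              "positive_fraction": config.ensemble.positive_fraction,
              "seed": config.ensemble.seed},
    }
    return StudyReport(outcomes, pd.DataFrame(desc_rows), omnibus, posthoc, manifest)


def write_report(report: StudyReport, out_dir: str) -> None:
    """Write outcome, descriptive and comparison tables plus the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    report.outcomes.to_csv(os.path.join(out_dir, "outcomes.csv"), index=False)
    report.descriptives.to_csv(os.path.join(out_dir, "descriptives.csv"), index=False)
    omni = {
        k: {"F_t": v.statistic, "F_crit": v.critical_value,
            "significant": v.significant, "n": v.n}
        for k, v in report.omnibus.items()
    }
    with open(os.path.join(out_dir, "omnibus.json"), "w") as fh:
        json.dump(omni, fh, indent=2)
    for outcome, table in report.posthoc.items():
        table.to_csv(os.path.join(out_dir, f"posthoc_{outcome}.csv"), index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(report.manifest, fh, indent=2)
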