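"""Monte-Carlo engine: replicate, estimate, and score against the true MPC.

One replication runs the full pipeline — latent trajectories, recalled
baseline, perceived change, observed scores, PGRC discretization, all
configured estimators — from a single seeded stream. A scenario is R
replications with spawned seeds; its summary reports, per estimator and
direction, the bias, empirical SD, RMSE and Monte-Carlo SE against the true
MPC mapped onto the observed score scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .config import ScenarioConfig, true_mpc
from .estimators import EstimateResult, run_all
from .latent_model import simulate_subjects
from .measurement import ObservedPanel, mpc_on_score_scale, observe_ctt, simulate_responses
from .pgrc import simulate_pgrc

__all__ = ["ReplicationRecord", "run_replication", "run_scenario", "summarize_grid"]

SUMMARY_METRICS = [
    "n_estimable",
    "mean_estimate",
    "bias",
    "relative_bias",
    "empirical_sd",
    "rmse",
    "mc_se_bias",
]


@dataclass
class ReplicationRecord:
    """Everything one replication produced, with its seed for replay."""

    scenario_id: str
    replication: int
    seed: int
    results: list[EstimateResult]
    anchor_group_sizes: dict[int, int]
    change_pc_corr: float


def _observe(config: ScenarioConfig, subjects: pd.DataFrame, rng: np.random.Generator) -> ObservedPanel:
    meas = config.measurement
    if meas.mode == "ctt":
        return observe_ctt(subjects, meas.reliability, rng, config.latent)
    return simulate_responses(subjects, meas.item_bank, rng, meas.rescale_0_100)


def run_replication(config: ScenarioConfig, seed: int, replication: int = 0) -> ReplicationRecord:
    """One seeded pass: simulate -> observe -> anchor -> estimate.

    All randomness comes from the one generator seeded here; the pipeline
    consumes it in a fixed order (latent, recall, measurement, thresholds)
    so that scenarios differing only in later stages share earlier draws.
    """
    rng = np.random.default_rng(seed)
    try:
        subjects = simulate_subjects(config.latent, config.recall, config.n_subjects, rng)
        panel = _observe(config, subjects, rng)
        anchor = simulate_pgrc(subjects, config.pgrc, rng)
        reliability = config.measurement.reliability if config.measurement.mode == "ctt" else None
        results = run_all(panel.scores, anchor, config.estimators, reliability)
    except Exception as exc:
        raise RuntimeError(
            f"scenario {config.scenario_id!r} replication {replication} (seed {seed}) failed"
        ) from exc

    change = panel.scores["change"].to_numpy()
    pc = subjects["pc"].to_numpy()
    if np.ptp(change) == 0.0 or np.ptp(pc) == 0.0:
        corr = float("nan")
    else:
        corr = float(pearsonr(change, pc).statistic)
    sizes = anchor["pgrc_category"].value_counts().to_dict()
    return ReplicationRecord(
        scenario_id=config.scenario_id,
        replication=replication,
        seed=seed,
        results=results,
        anchor_group_sizes={int(k): int(v) for k, v in sizes.items()},
        change_pc_corr=corr,
    )


def _summarize(config: ScenarioConfig, records: list[ReplicationRecord]) -> pd.DataFrame:
    mpc_plus_latent, mpc_minus_latent = true_mpc(config)
    truth = {
        "improvement": mpc_on_score_scale(config, mpc_plus_latent),
        "deterioration": mpc_on_score_scale(config, mpc_minus_latent),
    }
    corrs = np.array([r.change_pc_corr for r in records], dtype=float)
    mean_corr = float(np.nanmean(corrs)) if np.any(~np.isnan(corrs)) else float("nan")

    keys: list[tuple[str, str]] = []
    for r in records[0].results:
        keys.append((r.estimator_id, r.direction))

    rows = []
    n_rep = len(records)
    for est_id, direction in keys:
        per_rep = [
            res
            for rec in records
            for res in rec.results
            if res.estimator_id == est_id and res.direction == direction
        ]
        values = np.array([r.value for r in per_rep if r.estimable], dtype=float)
        n_est = values.size
        t = truth[direction]
        if n_est:
            mean = float(values.mean())
            bias = mean - t
            rel = bias / t if t != 0 else float("nan")
            sd = float(values.std(ddof=1)) if n_est > 1 else float("nan")
            rmse = float(np.sqrt(np.mean((values - t) ** 2)))
            mcse = sd / np.sqrt(n_est) if n_est > 1 else float("nan")
        else:
            mean = bias = rel = sd = rmse = mcse = float("nan")
        guards = [r.guard_pass for r in per_rep if r.guard_pass is not None]
        guard_rate = float(np.mean(guards)) if guards else float("nan")
        rows.append(
            {
                "scenario_id": config.scenario_id,
                "estimator_id": est_id,
                "direction": direction,
                "truth": t,
                "n_replications": n_rep,
                "n_estimable": n_est,
                "mean_estimate": mean,
                "bias": bias,
                "relative_bias": rel,
                "empirical_sd": sd,
                "rmse": rmse,
                "mc_se_bias": mcse,
                "guard_pass_rate": guard_rate,
                "mean_change_pc_corr": mean_corr,
            }
        )
    return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig) -> tuple[list[ReplicationRecord], pd.DataFrame]:
    """Run all replications of one scenario and summarize against the truth.

    Replication seeds are an integer stream derived from the scenario's
    base_seed, so scenarios and replications are independently reproducible.
    """
    seeds = np.random.SeedSequence(config.base_seed).generate_state(config.n_replications)
    records = [
        run_replication(config, int(seed), replication=i) for i, seed in enumerate(seeds)
    ]
    return records, _summarize(config, records)


def records_to_frame(records: list[ReplicationRecord]) -> pd.DataFrame:
    """Flatten replication records into one row per estimator result."""
    rows = []
    for rec in records:
        for res in rec.results:
            rows.append(
                {
                    "scenario_id": rec.scenario_id,
                    "replication": rec.replication,
                    "seed": rec.seed,
                    "estimator_id": res.estimator_id,
                    "direction": res.direction,
                    "value": res.value,
                    "status": res.status,
                    "n_anchor_group": res.n_anchor_group,
                    "guard_correlation": res.guard_correlation,
                    "guard_pass": res.guard_pass,
                    "change_pc_corr": rec.change_pc_corr,
                }
            )
    return pd.DataFrame(rows)


def summarize_grid(summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack scenario summaries into a tidy long table (one metric per row)."""
    if not summaries or all(len(s) == 0 for s in summaries):
        return pd.DataFrame(
            columns=["scenario_id", "estimator_id", "direction", "truth", "metric", "value"]
        )
    wide = pd.concat([s for s in summaries if len(s)], ignore_index=True)
    long = wide.melt(
        id_vars=["scenario_id", "estimator_id", "direction", "truth"],
        value_vars=SUMMARY_METRICS,
        var_name="metric",
        value_name="value",
    )
    return long.sort_values(
        ["metric", "scenario_id", "estimator_id", "direction"], kind="stable"
    ).reset_index(drop=True)
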