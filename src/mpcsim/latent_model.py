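"""Latent trajectories: construct levels, recalled baseline, perceived change.

Each subject carries an antecedent (stable disposition), a catalyst (0/1
health event), a coping mechanism, and the latent construct at the two
measurement times. The recalled baseline sc_t1mem mixes the true baseline
with the current state and other contingencies; the perceived change is
pc = sc_t2 - sc_t1mem. All structural paths are linear-Gaussian with
coefficients exposed in :class:`mpcsim.config.LatentParams` and
:class:`mpcsim.config.RecallParams`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import LatentParams, RecallParams

__all__ = ["sample_latent", "recall_baseline", "perceived_change", "simulate_subjects"]

SUBJECT_COLUMNS = [
    "subject_id",
    "antecedent",
    "catalyst",
    "mechanism",
    "sc_t1",
    "sc_t2",
    "sc_t1mem",
    "pc",
]


def sample_latent(latent: LatentParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n subjects' latent trajectories up to sc_t2.

    antecedent ~ N(0,1) (its effect on baseline is folded into the marginal
    sc_t1 distribution); catalyst ~ Bernoulli with log-odds
    logit(catalyst_prob) + beta_sc1_on_catalyst * (sc_t1 - mean); mechanism
    is fed by centered sc_t1 and a catalyst-triggered N(0,1) shock; sc_t2 is
    the linear combination of its structural parents plus residual noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    antecedent = rng.standard_normal(n)
    sc_t1 = rng.normal(latent.mean_sc_t1, latent.sd_sc_t1, n)
    centered = sc_t1 - latent.mean_sc_t1

    if latent.catalyst_prob in (0.0, 1.0):
        # degenerate Bernoulli; the log-odds shift cannot move it
        p = np.full(n, latent.catalyst_prob)
    else:
        p = expit(logit(latent.catalyst_prob) + latent.beta_sc1_on_catalyst * centered)
    catalyst = (rng.random(n) < p).astype(float)

    mechanism = latent.beta_sc1_on_mechanism * centered + catalyst * rng.standard_normal(n)
    sc_t2 = (
        latent.rho_auto * sc_t1
        + latent.beta_catalyst_on_sc2 * catalyst
        + latent.beta_antecedent_on_sc2 * antecedent
        + latent.beta_mechanism_on_sc2 * mechanism
        + rng.normal(0.0, latent.sd_resid_sc2, n)
    )
    return pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "antecedent": antecedent,
            "catalyst": catalyst,
            "mechanism": mechanism,
            "sc_t1": sc_t1,
            "sc_t2": sc_t2,
        }
    )


def recall_baseline(
    subjects: pd.DataFrame, recall: RecallParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill sc_t1mem: the remembered baseline the subject reconstructs.

    sc_t1mem = lam*sc_t1 + psi*sc_t2 + gamma_a*antecedent + gamma_c*catalyst
    + gamma_m*mechanism + N(0, sd_mem^2). lam = 1, psi = 0 with zero gammas
    and noise is perfect recall; lam = 0, psi = 1 is pure reconstruction from
    the present state.
    """
    out = subjects.copy()
    out["sc_t1mem"] = (
        recall.lam * out["sc_t1"].to_numpy()
        + recall.psi * out["sc_t2"].to_numpy()
        + recall.gamma_antecedent * out["antecedent"].to_numpy()
        + recall.gamma_catalyst * out["catalyst"].to_numpy()
        + recall.gamma_mechanism * out["mechanism"].to_numpy()
        + rng.normal(0.0, recall.sd_mem, len(out))
    )
    return out


def perceived_change(subjects: pd.DataFrame) -> pd.DataFrame:
    """Fill pc = sc_t2 - sc_t1mem (exact)."""
    out = subjects.copy()
    out["pc"] = out["sc_t2"].to_numpy() - out["sc_t1mem"].to_numpy()
    return out


def simulate_subjects(
    latent: LatentParams, recall: RecallParams, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Full latent pipeline: sample, recall, perceived change."""
    return perceived_change(recall_baseline(sample_latent(latent, n, rng), recall, rng))
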