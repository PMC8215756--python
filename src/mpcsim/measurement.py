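"""Observed PRO scores from latent construct levels.

Two psychometric modes are supported:

* **CTT** (classical test theory): observed score = latent level + normal
  error, with the error variance chosen so that the true-score share of the
  observed variance equals the configured reliability ``rho``.
* **IRT**: item responses drawn from Samejima's graded response model (GRM,
  logistic cumulative response functions) and summed into a raw score.

The module also maps the latent-scale MPC truth onto the observed score
scale: an identity in CTT mode, and the test-characteristic-curve difference
``tcc(theta_ref + mpc) - tcc(theta_ref)`` in IRT mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

if TYPE_CHECKING:  # pragma: no cover
    from .config import LatentParams, ScenarioConfig

__all__ = [
    "ItemBank",
    "ObservedPanel",
    "observe_ctt",
    "grm_category_probs",
    "simulate_responses",
    "tcc",
    "mpc_on_score_scale",
    "sem_of_scores",
    "sc_t2_variance",
]


class ItemBank(BaseModel):
    """A bank of polytomous items for the graded response model.

    ``discriminations[j]`` is the slope a_j > 0 of item j; ``thresholds[j]``
    are its m-1 strictly increasing category locations b_{j,c} on the latent
    scale. All items share the same number of response categories m.
    """

    discriminations: list[float]
    thresholds: list[list[float]]

    @model_validator(mode="after")
    def _check(self) -> "ItemBank":
        if len(self.discriminations) != len(self.thresholds):
            raise ValueError("discriminations and thresholds must have one entry per item")
        if not self.discriminations:
            raise ValueError("item bank must contain at least one item")
        if any(a <= 0 for a in self.discriminations):
            raise ValueError("item discriminations must be > 0")
        m_minus_1 = len(self.thresholds[0])
        for j, b in enumerate(self.thresholds):
            if len(b) != m_minus_1:
                raise ValueError("all items must have the same number of categories")
            if any(b[c] >= b[c + 1] for c in range(len(b) - 1)):
                raise ValueError(f"item {j}: category thresholds must be strictly increasing")
        return self

    @property
    def n_items(self) -> int:
        return len(self.discriminations)

    @property
    def n_categories(self) -> int:
        """Categories per item, m (responses coded 0..m-1)."""
        return len(self.thresholds[0]) + 1

    @property
    def max_score(self) -> int:
        return self.n_items * (self.n_categories - 1)


@dataclass
class ObservedPanel:
    """Two-wave observed scores, one row per subject.

    ``scores`` has columns subject_id, score_t1, score_t2, change with
    change = score_t2 - score_t1 exactly. ``item_responses`` (IRT mode only)
    is a wide frame item_1_t1 ... item_J_t2.
    """

    scores: pd.DataFrame
    item_responses: pd.DataFrame | None = None


def sc_t2_variance(latent: "LatentParams") -> float | None:
    """Population variance of sc_t2 implied by the structural equations.

    Closed form exists when the catalyst is independent of sc_t1
    (beta_sc1_on_catalyst = 0); otherwise returns None and callers fall back
    to a sample estimate.
    """
    if latent.beta_sc1_on_catalyst != 0.0:
        return None
    p = latent.catalyst_prob
    v1 = latent.sd_sc_t1**2
    slope = latent.rho_auto + latent.beta_mechanism_on_sc2 * latent.beta_sc1_on_mechanism
    return (
        slope**2 * v1
        + latent.beta_catalyst_on_sc2**2 * p * (1.0 - p)
        + latent.beta_antecedent_on_sc2**2
        + latent.beta_mechanism_on_sc2**2 * p
        + latent.sd_resid_sc2**2
    )


def observe_ctt(
    subjects: pd.DataFrame,
    reliability: float,
    rng: np.random.Generator,
    latent: "LatentParams | None" = None,
) -> ObservedPanel:
    """Add classical measurement error to the latent levels of both waves.

    The error SD per wave is sigma_T * sqrt((1 - rho) / rho), with sigma_T^2
    the true-score (latent) variance of that wave — from the structural
    parameters when available, otherwise the sample variance — so that
    Var(true) / Var(observed) = rho.
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError(f"reliability must be in (0, 1], got {reliability}")
    n = len(subjects)
    var_t1 = latent.sd_sc_t1**2 if latent is not None else float(np.var(subjects["sc_t1"], ddof=1))
    var_t2 = sc_t2_variance(latent) if latent is not None else None
    if var_t2 is None:
        var_t2 = float(np.var(subjects["sc_t2"], ddof=1))
    noise_factor = np.sqrt((1.0 - reliability) / reliability)
    score_t1 = subjects["sc_t1"].to_numpy() + rng.normal(0.0, np.sqrt(var_t1) * noise_factor, n)
    score_t2 = subjects["sc_t2"].to_numpy() + rng.normal(0.0, np.sqrt(var_t2) * noise_factor, n)
    scores = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "score_t1": score_t1,
            "score_t2": score_t2,
            "change": score_t2 - score_t1,
        }
    )
    return ObservedPanel(scores=scores)


def grm_category_probs(
    theta: float | np.ndarray, discrimination: float, thresholds: Sequence[float]
) -> np.ndarray:
    """GRM category probabilities at latent level(s) theta for one item.

    P(response >= c) = logistic(a * (theta - b_c)); category probabilities
    are adjacent differences with sentinels 1 and 0. Returns shape (m,) for
    scalar theta, (len(theta), m) for a vector.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(thresholds, dtype=float)
    cum = expit(discrimination * (theta_arr[:, None] - b[None, :]))  # P(>= c), c = 1..m-1
    ones = np.ones((theta_arr.shape[0], 1))
    zeros = np.zeros((theta_arr.shape[0], 1))
    bounded = np.hstack([ones, cum, zeros])
    probs = bounded[:, :-1] - bounded[:, 1:]
    probs = np.clip(probs, 0.0, None)
    if np.isscalar(theta) or np.asarray(theta).ndim == 0:
        return probs[0]
    return probs


def _draw_item_responses(
    theta: np.ndarray, bank: ItemBank, rng: np.random.Generator
) -> np.ndarray:
    """(n, J) integer response matrix, responses coded 0..m-1."""
    n = theta.shape[0]
    out = np.empty((n, bank.n_items), dtype=int)
    for j in range(bank.n_items):
        probs = grm_category_probs(theta, bank.discriminations[j], bank.thresholds[j])
        cdf = np.cumsum(probs, axis=1)
        u = rng.random(n)
        out[:, j] = (u[:, None] > cdf[:, :-1]).sum(axis=1)
    return out


def simulate_responses(
    subjects: pd.DataFrame,
    bank: ItemBank,
    rng: np.random.Generator,
    rescale_0_100: bool = False,
) -> ObservedPanel:
    """Simulate GRM item responses at both waves and build sum scores."""
    resp: dict[str, np.ndarray] = {}
    scores = {}
    for wave, col in (("t1", "sc_t1"), ("t2", "sc_t2")):
        theta = subjects[col].to_numpy(dtype=float)
        mat = _draw_item_responses(theta, bank, rng)
        for j in range(bank.n_items):
            resp[f"item_{j + 1}_{wave}"] = mat[:, j]
        scores[wave] = mat.sum(axis=1).astype(float)
    if rescale_0_100:
        factor = 100.0 / bank.max_score
        scores = {w: s * factor for w, s in scores.items()}
    frame = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "score_t1": scores["t1"],
            "score_t2": scores["t2"],
            "change": scores["t2"] - scores["t1"],
        }
    )
    items = pd.DataFrame(resp)
    items.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    return ObservedPanel(scores=frame, item_responses=items)


def tcc(theta: float | np.ndarray, bank: ItemBank) -> float | np.ndarray:
    """Test characteristic curve: expected sum score at latent level theta.

    The expected score of one GRM item is the sum of its cumulative response
    probabilities, so the TCC is strictly increasing in theta.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros_like(theta_arr)
    for a, b in zip(bank.discriminations, bank.thresholds):
        total += expit(a * (theta_arr[:, None] - np.asarray(b)[None, :])).sum(axis=1)
    if np.isscalar(theta) or np.asarray(theta).ndim == 0:
        return float(total[0])
    return total


def mpc_on_score_scale(config: "ScenarioConfig", mpc_latent: float) -> float:
    """Map a latent-scale MPC value onto the observed score scale.

    CTT mode treats the score scale as the latent scale (identity). IRT mode
    evaluates the TCC difference around the baseline population mean, with
    the optional 0-100 rescale applied consistently.
    """
    meas = config.measurement
    if meas.mode == "ctt":
        return float(mpc_latent)
    bank = meas.item_bank
    theta_ref = config.latent.mean_sc_t1
    delta = tcc(theta_ref + mpc_latent, bank) - tcc(theta_ref, bank)
    if meas.rescale_0_100:
        delta *= 100.0 / bank.max_score
    return float(delta)


def sem_of_scores(baseline_scores: Sequence[float], reliability: float) -> float:
    """Standard error of measurement: SD(baseline) * sqrt(1 - rho)."""
    scores = np.asarray(baseline_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("at least 2 baseline scores required")
    if not 0.0 < reliability <= 1.0:
        raise ValueError(f"reliability must be in (0, 1], got {reliability}")
    return float(np.std(scores, ddof=1) * np.sqrt(1.0 - reliability))
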