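"""Random thresholds and discretization of perceived change into a PGRC.

Each subject carries their own vector of k-1 strictly increasing thresholds
on the perceived-change continuum, drawn independently from normal
distributions whose locations are the population parameters — the two
middle-adjacent locations being the true MPC for deterioration and
improvement. Ordering violations are handled by whole-vector rejection
sampling (sorting would distort the marginal locations and silently bias
the MPC definition); the rejection rate is logged and capped.

Categories are coded as integers centered at 0 (0 = "the same"; positive =
improvement side). Boundary convention: a perceived change exactly equal to
a threshold falls in the upper category.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PgrcParams

__all__ = ["ThresholdSamplingError", "sample_thresholds", "discretize", "simulate_pgrc"]

logger = logging.getLogger("mpcsim")


class ThresholdSamplingError(RuntimeError):
    """Rejection sampling failed to produce ordered threshold vectors."""


def sample_thresholds(
    pgrc: PgrcParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n per-subject threshold vectors, shape (n, k-1).

    tau_s ~ N(mu_s, sigma_s^2) independently; vectors that are not strictly
    increasing are redrawn whole. Raises if any vector is still unordered
    after ``max_reject_iters`` rounds (advice: widen the mu spacing or
    shrink the sigmas).
    """
    mus = np.array([t.mu for t in pgrc.thresholds])
    sigmas = np.array([t.sigma for t in pgrc.thresholds])
    if np.all(sigmas == 0.0):
        return np.tile(mus, (n, 1))

    tau = rng.normal(mus, sigmas, size=(n, len(mus)))
    bad = ~np.all(np.diff(tau, axis=1) > 0.0, axis=1)
    n_rejected = 0
    iters = 0
    while bad.any():
        iters += 1
        if iters > pgrc.max_reject_iters:
            raise ThresholdSamplingError(
                f"threshold ordering rejection exceeded {pgrc.max_reject_iters} rounds "
                f"({int(bad.sum())} vectors still unordered); widen the mu spacing or "
                "reduce the sigmas"
            )
        n_rejected += int(bad.sum())
        tau[bad] = rng.normal(mus, sigmas, size=(int(bad.sum()), len(mus)))
        bad = ~np.all(np.diff(tau, axis=1) > 0.0, axis=1)
    rate = n_rejected / (n + n_rejected)
    if rate > 0.10:
        logger.warning(
            "threshold rejection rate %.1f%% — mu spacing is narrow relative to sigma "
            "and sampled locations may drift from the nominal MPC", 100 * rate
        )
    elif n_rejected:
        logger.debug("threshold rejection rate %.3f%%", 100 * rate)
    return tau


def discretize(
    pc_values: np.ndarray, threshold_vectors: np.ndarray, pgrc: PgrcParams
) -> pd.DataFrame:
    """Map each perceived change to its PGRC category given its thresholds.

    Left-closed/right-open intervals: category c is the unique c with
    tau_c <= pc < tau_{c+1} (sentinels at ±inf), so pc equal to a threshold
    takes the upper category. Category codes run -(k-1)/2 .. (k-1)/2.
    """
    pc = np.asarray(pc_values, dtype=float)
    tau = np.asarray(threshold_vectors, dtype=float)
    if pc.shape[0] != tau.shape[0]:
        raise ValueError(f"length mismatch: {pc.shape[0]} pc values, {tau.shape[0]} threshold vectors")
    if tau.shape[1] != pgrc.k - 1:
        raise ValueError(f"expected {pgrc.k - 1} thresholds per subject, got {tau.shape[1]}")
    idx = (pc[:, None] >= tau).sum(axis=1)  # 0..k-1
    category = idx - (pgrc.k - 1) // 2
    labels = np.asarray(pgrc.labels, dtype=object)[idx]
    out = pd.DataFrame(
        {
            "subject_id": np.arange(pc.shape[0]),
            "pgrc_category": category,
            "pgrc_label": labels,
        }
    )
    for s in range(tau.shape[1]):
        out[f"tau_{s + 1}"] = tau[:, s]
    return out


def simulate_pgrc(
    subjects: pd.DataFrame, pgrc: PgrcParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample per-subject thresholds and discretize the pc column.

    Returns one row per subject: subject_id, pgrc_category, pgrc_label and
    the sampled tau_1..tau_{k-1} (kept for diagnostics).
    """
    pc = subjects["pc"].to_numpy(dtype=float)
    tau = sample_thresholds(pgrc, len(pc), rng)
    out = discretize(pc, tau, pgrc)
    out["subject_id"] = subjects["subject_id"].to_numpy()
    return out
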