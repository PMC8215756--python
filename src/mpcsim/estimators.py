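"""MID/MPC estimators: anchor-based and distribution-based.

Anchor-based estimators link the two-wave change score to the PGRC answer:
the mean change of the minimally-changed group, the adjacent-group mean
difference (minimal vs "no change"), and the ROC cut-point that best
discriminates changed from unchanged subjects. Distribution-based rules
(0.5 effect size, 1 SEM) use only score variability and carry no anchor
guard — they are included for comparison because they cannot, by design,
target the perceived-change threshold.

All estimators return :class:`EstimateResult`; a group being empty yields a
first-class ``not_estimable`` result rather than an exception, so scenario
batches never abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import EstimatorSettings

__all__ = [
    "EstimateResult",
    "anchor_correlation",
    "mean_change_minimal_group",
    "mean_diff_adjacent",
    "roc_threshold",
    "es_based",
    "sem_based",
    "run_all",
    "results_to_frame",
]

Direction = Literal["improvement", "deterioration"]
_TIE_TOL = 1e-12


@dataclass
class EstimateResult:
    """One estimator's output for one direction of change.

    ``value`` is in score units (NaN when status is not "ok"). Anchor-based
    results carry the size of the defining anchor group and the guard
    correlation between change score and PGRC category; distribution-based
    results leave the guard fields as None.
    """

    estimator_id: str
    direction: str
    value: float
    status: str = "ok"
    n_anchor_group: int | None = None
    guard_correlation: float | None = None
    guard_pass: bool | None = None
    details: dict[str, Any] = field(default_factory=dict)

    @property
    def estimable(self) -> bool:
        return self.status == "ok"


def _not_estimable(estimator_id: str, direction: str, reason: str) -> EstimateResult:
    return EstimateResult(
        estimator_id=estimator_id,
        direction=direction,
        value=float("nan"),
        status="not_estimable",
        details={"reason": reason},
    )


def anchor_correlation(change: Sequence[float], pgrc: Sequence[int]) -> float:
    """Spearman rank correlation between change scores and PGRC categories.

    The standard prerequisite before any anchor-based estimation: the anchor
    must show at least a moderate monotone association with the change score.
    """
    change = np.asarray(change, dtype=float)
    cats = np.asarray(pgrc, dtype=float)
    if change.shape[0] != cats.shape[0]:
        raise ValueError("change and pgrc must have equal length")
    if change.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.all(cats == cats[0]) or np.all(change == change[0]):
        raise ValueError("correlation undefined: constant input")
    return float(spearmanr(change, cats).statistic)


def _side(direction: str) -> int:
    if direction == "improvement":
        return 1
    if direction == "deterioration":
        return -1
    raise ValueError(f"direction must be 'improvement' or 'deterioration', got {direction!r}")


def mean_change_minimal_group(
    change: Sequence[float], pgrc: Sequence[int], direction: Direction
) -> EstimateResult:
    """Mean change score among subjects reporting minimal change (category ±1)."""
    change = np.asarray(change, dtype=float)
    cats = np.asarray(pgrc)
    side = _side(direction)
    mask = cats == side
    if not mask.any():
        return _not_estimable("mean_change_minimal_group", direction, "minimal-change group empty")
    return EstimateResult(
        estimator_id="mean_change_minimal_group",
        direction=direction,
        value=float(change[mask].mean()),
        n_anchor_group=int(mask.sum()),
    )


def mean_diff_adjacent(
    change: Sequence[float], pgrc: Sequence[int], direction: Direction
) -> EstimateResult:
    """Mean change in the minimal-change group minus the "no change" group."""
    change = np.asarray(change, dtype=float)
    cats = np.asarray(pgrc)
    side = _side(direction)
    minimal = cats == side
    same = cats == 0
    if not minimal.any() or not same.any():
        which = "minimal-change" if not minimal.any() else "no-change"
        return _not_estimable("mean_diff_adjacent", direction, f"{which} group empty")
    return EstimateResult(
        estimator_id="mean_diff_adjacent",
        direction=direction,
        value=float(change[minimal].mean() - change[same].mean()),
        n_anchor_group=int(minimal.sum()),
    )


def _roc_candidates(pooled: np.ndarray) -> np.ndarray:
    v = np.unique(pooled)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])


def roc_threshold(
    change: Sequence[float],
    pgrc: Sequence[int],
    direction: Direction,
    criterion: str = "euclidean",
    weight: float = 0.5,
) -> EstimateResult:
    """Optimal ROC cut-point on the change score separating changed from unchanged.

    Positive class: all categories on the requested side (>= +1 for
    improvement); negative class: the middle category only; opposite-side
    subjects are excluded. Candidate thresholds are the midpoints between
    consecutive distinct pooled change values plus one candidate beyond each
    extreme; for improvement a subject is classified "changed" when
    change >= threshold (<= for deterioration). Criteria:

    * ``euclidean`` — minimize sqrt((1-sens)^2 + (1-spec)^2)
    * ``youden`` — maximize sens + spec - 1
    * ``weighted`` — minimize w*(1-sens)^2 + (1-w)*(1-spec)^2

    Ties are broken by smallest \\|threshold\\|, then smallest threshold.
    """
    change = np.asarray(change, dtype=float)
    cats = np.asarray(pgrc)
    side = _side(direction)
    pos = change[cats * side >= 1]
    neg = change[cats == 0]
    if pos.size == 0 or neg.size == 0:
        which = "changed" if pos.size == 0 else "no-change"
        return _not_estimable("roc_threshold", direction, f"{which} class empty")

    cand = _roc_candidates(np.concatenate([pos, neg]))
    sp = np.sort(pos)
    sn = np.sort(neg)
    if side == 1:  # changed iff change >= t
        sens = (pos.size - np.searchsorted(sp, cand, side="left")) / pos.size
        spec = np.searchsorted(sn, cand, side="left") / neg.size
    else:  # changed iff change <= t
        sens = np.searchsorted(sp, cand, side="right") / pos.size
        spec = (neg.size - np.searchsorted(sn, cand, side="right")) / neg.size

    if criterion == "euclidean":
        loss = np.hypot(1.0 - sens, 1.0 - spec)
    elif criterion == "youden":
        loss = -(sens + spec - 1.0)
    elif criterion == "weighted":
        loss = weight * (1.0 - sens) ** 2 + (1.0 - weight) * (1.0 - spec) ** 2
    else:
        raise ValueError(f"unknown ROC criterion {criterion!r}")

    tied = np.flatnonzero(loss <= loss.min() + _TIE_TOL)
    best = min(tied, key=lambda i: (abs(cand[i]), cand[i]))
    thr = float(cand[best])

    pooled = np.unique(np.concatenate([pos, neg]))
    below = pooled[pooled < thr]
    above = pooled[pooled >= thr]
    gap = float(above[0] - below[-1]) if below.size and above.size else math.inf
    return EstimateResult(
        estimator_id="roc_threshold",
        direction=direction,
        value=thr,
        n_anchor_group=int(pos.size),
        details={
            "criterion": criterion,
            "sensitivity": float(sens[best]),
            "specificity": float(spec[best]),
            "criterion_value": float(loss[best]),
            "obs_gap": gap,
        },
    )


def es_based(
    baseline_scores: Sequence[float],
    multiplier: float = 0.5,
    direction: Direction = "improvement",
) -> EstimateResult:
    """Effect-size rule: multiplier x SD(baseline) (Cohen's 0.5 by default).

    Signed by direction (negative for deterioration) so results tabulate
    uniformly with the anchor-based estimators.
    """
    scores = np.asarray(baseline_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("at least 2 baseline scores required")
    sign = _side(direction)
    return EstimateResult(
        estimator_id="es_based",
        direction=direction,
        value=float(sign * multiplier * np.std(scores, ddof=1)),
        details={"multiplier": multiplier},
    )


def sem_based(
    baseline_scores: Sequence[float],
    reliability: float,
    multiplier: float = 1.0,
    direction: Direction = "improvement",
) -> EstimateResult:
    """SEM rule: multiplier x SD(baseline) x sqrt(1 - reliability)."""
    scores = np.asarray(baseline_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("at least 2 baseline scores required")
    if not 0.0 < reliability <= 1.0:
        raise ValueError(f"reliability must be in (0, 1], got {reliability}")
    sign = _side(direction)
    return EstimateResult(
        estimator_id="sem_based",
        direction=direction,
        value=float(sign * multiplier * np.std(scores, ddof=1) * np.sqrt(1.0 - reliability)),
        details={"multiplier": multiplier, "reliability": reliability},
    )


def run_all(
    scores: pd.DataFrame,
    pgrc: pd.DataFrame,
    settings: EstimatorSettings | None = None,
    reliability: float | None = None,
) -> list[EstimateResult]:
    """Run every configured estimator for both directions on an aligned panel.

    ``scores`` needs columns subject_id, score_t1, change; ``pgrc`` needs
    subject_id, pgrc_category. The anchor guard (Spearman correlation vs the
    configured cut-off) is attached to every anchor-based result. Failures
    of individual estimators become not_estimable results; the batch never
    aborts. Result ordering is deterministic (configured id order x
    improvement-then-deterioration).
    """
    settings = settings or EstimatorSettings()
    merged = scores.merge(pgrc[["subject_id", "pgrc_category"]], on="subject_id", validate="1:1")
    change = merged["change"].to_numpy(dtype=float)
    cats = merged["pgrc_category"].to_numpy()
    baseline = merged["score_t1"].to_numpy(dtype=float)

    try:
        guard_r = anchor_correlation(change, cats)
        guard_pass = guard_r >= settings.guard_cutoff
    except ValueError:
        guard_r, guard_pass = float("nan"), False

    results: list[EstimateResult] = []
    directions: tuple[Direction, Direction] = ("improvement", "deterioration")
    for est_id in settings.ids:
        for direction in directions:
            if est_id == "mean_change_minimal_group":
                res = mean_change_minimal_group(change, cats, direction)
            elif est_id == "mean_diff_adjacent":
                res = mean_diff_adjacent(change, cats, direction)
            elif est_id == "roc_threshold":
                res = roc_threshold(
                    change, cats, direction,
                    criterion=settings.roc_criterion, weight=settings.roc_weight,
                )
            elif est_id == "es_based":
                res = es_based(baseline, settings.es_multiplier, direction)
            elif est_id == "sem_based":
                if reliability is None:
                    res = _not_estimable("sem_based", direction, "reliability not provided")
                else:
                    res = sem_based(baseline, reliability, settings.sem_multiplier, direction)
            else:  # pragma: no cover - settings validation forbids this
                raise ValueError(f"unknown estimator id {est_id!r}")
            if est_id in ("mean_change_minimal_group", "mean_diff_adjacent", "roc_threshold"):
                res.guard_correlation = guard_r
                res.guard_pass = bool(guard_pass)
            results.append(res)
    return results


def results_to_frame(results: list[EstimateResult]) -> pd.DataFrame:
    """Flatten results into the estimates table (stable column order)."""
    rows = []
    for r in results:
        rows.append(
            {
                "estimator_id": r.estimator_id,
                "direction": r.direction,
                "value": r.value,
                "n_anchor_group": r.n_anchor_group,
                "guard_correlation": r.guard_correlation,
                "guard_pass": r.guard_pass,
                "status": r.status,
                "roc_sensitivity": r.details.get("sensitivity"),
                "roc_specificity": r.details.get("specificity"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "estimator_id", "direction", "value", "n_anchor_group",
            "guard_correlation", "guard_pass", "status",
            "roc_sensitivity", "roc_specificity",
        ],
    )
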