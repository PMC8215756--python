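import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("suite")

MINIMAL_YAML = """
scenario_id: demo
n_subjects: 50
n_replications: 2
base_seed: 7
measurement:
  mode: ctt
  reliability: 0.9
pgrc:
  k: 3
  thresholds:
    - {mu: -1.0, sigma: 0.0}
    - {mu: 1.0, sigma: 0.0}
"""


@pytest.fixture
def minimal_yaml() -> str:
    return MINIMAL_YAML


def roc_oracle(pos, neg, direction, criterion, weight=0.5):
    """Brute-force ROC cut-point selection, independent of the package.

    Enumerates every candidate threshold (midpoints between consecutive
    distinct pooled values plus one beyond each extreme), computes
    sensitivity/specificity by direct counting, and applies the criterion
    with the tie-break smallest |threshold| then smallest threshold.
    """
    pos, neg = list(pos), list(neg)
    vals = sorted(set(pos + neg))
    cands = (
        [vals[0] - 1.0]
        + [(a + b) / 2.0 for a, b in zip(vals, vals[1:])]
        + [vals[-1] + 1.0]
    )
    entries = []
    for t in cands:
        if direction == "improvement":
            sens = sum(1 for x in pos if x >= t) / len(pos)
            spec = sum(1 for x in neg if x < t) / len(neg)
        else:
            sens = sum(1 for x in pos if x <= t) / len(pos)
            spec = sum(1 for x in neg if x > t) / len(neg)
        if criterion == "euclidean":
            loss = math.hypot(1.0 - sens, 1.0 - spec)
        elif criterion == "youden":
            loss = -(sens + spec - 1.0)
        elif criterion == "weighted":
            loss = weight * (1.0 - sens) ** 2 + (1.0 - weight) * (1.0 - spec) ** 2
        else:
            raise ValueError(criterion)
        entries.append((t, loss))
    best_loss = min(loss for _, loss in entries)
    tied = [t for t, loss in entries if loss <= best_loss + 1e-12]
    thr = min(tied, key=lambda t: (abs(t), t))
    return thr, best_loss


def random_roc_instance(rng: np.random.Generator):
    """A small random two-class instance (change scores + categories)."""
    n_pos = int(rng.integers(1, 16))
    n_neg = int(rng.integers(1, 16))
    # mix continuous values with ties on a coarse grid
    if rng.random() < 0.5:
        pos = rng.normal(1.0, 1.0, n_pos)
        neg = rng.normal(0.0, 1.0, n_neg)
    else:
        pos = rng.integers(-3, 6, n_pos).astype(float) / 2.0
        neg = rng.integers(-5, 4, n_neg).astype(float) / 2.0
    change = np.concatenate([pos, neg])
    cats = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return change, cats, pos, neg
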