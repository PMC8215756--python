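"""Scenario configuration: validation, ground-truth MPC, grid expansion.

A scenario fully parameterizes one simulated population and study design:
the latent structural model, the recall (remembered-baseline) model, the
psychometric measurement mode, the PGRC threshold distributions — which
carry the ground-truth MPC as the location parameters of the two thresholds
bounding the middle ("no change") category — and the estimators to run.

Files are YAML (JSON parses as a YAML subset). All models are pydantic, so
every invariant is enforced at load time and serialization round-trips.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .measurement import ItemBank

__all__ = [
    "ConfigError",
    "ThresholdSpec",
    "PgrcParams",
    "LatentParams",
    "RecallParams",
    "MeasurementParams",
    "EstimatorSettings",
    "ScenarioConfig",
    "load_config",
    "loads_config",
    "serialize_config",
    "save_config",
    "true_mpc",
    "expand_grid",
    "degenerate_scenario",
]

logger = logging.getLogger("mpcsim")

DEFAULT_LABELS: dict[int, list[str]] = {
    3: ["worse", "the same", "better"],
    5: ["a lot worse", "a little worse", "about the same", "a little better", "a lot better"],
    7: [
        "a great deal worse",
        "a lot worse",
        "a little worse",
        "about the same",
        "a little better",
        "a lot better",
        "a great deal better",
    ],
}


class ConfigError(ValueError):
    """A scenario file failed to parse or validate."""


class ThresholdSpec(BaseModel):
    """One PGRC threshold on the perceived-change continuum.

    ``mu`` is the population location (construct units); ``sigma`` the SD of
    the threshold across subjects. The threshold family is normal (recorded
    here so alternatives can be added without changing the schema).
    """

    mu: float
    sigma: float = Field(ge=0.0)
    family: Literal["normal"] = "normal"


class PgrcParams(BaseModel):
    """The global rating-of-change item: k ordered categories, k-1 thresholds.

    The middle category must span 0: the two middle-adjacent threshold
    locations are the ground-truth MPC for deterioration (negative) and
    improvement (positive).
    """

    k: int
    thresholds: list[ThresholdSpec]
    labels: list[str] | None = None
    max_reject_iters: int = Field(default=1000, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "PgrcParams":
        if self.k not in (3, 5, 7):
            raise ValueError(f"k must be odd and one of 3, 5, 7; got {self.k}")
        if len(self.thresholds) != self.k - 1:
            raise ValueError(
                f"a PGRC with {self.k} categories needs {self.k - 1} thresholds, "
                f"got {len(self.thresholds)}"
            )
        mus = [t.mu for t in self.thresholds]
        if any(mus[i] >= mus[i + 1] for i in range(len(mus) - 1)):
            raise ValueError(f"thresholds not increasing: mu = {mus}")
        mid = (self.k - 1) // 2
        if not (mus[mid - 1] < 0.0 < mus[mid]):
            raise ValueError(
                "middle category must span 0: need "
                f"mu[{mid - 1}] < 0 < mu[{mid}], got {mus[mid - 1]} and {mus[mid]}"
            )
        if self.labels is None:
            self.labels = list(DEFAULT_LABELS[self.k])
        elif len(self.labels) != self.k:
            raise ValueError(f"need {self.k} labels, got {len(self.labels)}")
        return self


class LatentParams(BaseModel):
    """Structural (linear-Gaussian) model of the latent construct.

    sc_t1 ~ N(mean_sc_t1, sd_sc_t1^2); the catalyst is a Bernoulli health
    event whose log-odds may depend on sc_t1; the mechanism is a coping
    process fed by sc_t1 and triggered by the catalyst; sc_t2 is a linear
    combination of sc_t1 (autoregression rho_auto), catalyst, antecedent and
    mechanism plus N(0, sd_resid_sc2^2) residual.
    """

    mean_sc_t1: float = 0.0
    sd_sc_t1: float = Field(default=1.0, gt=0.0)
    catalyst_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    beta_catalyst_on_sc2: float = 0.0
    beta_antecedent_on_sc2: float = 0.0
    beta_mechanism_on_sc2: float = 0.0
    beta_sc1_on_catalyst: float = 0.0
    beta_sc1_on_mechanism: float = 0.0
    rho_auto: float = 1.0
    sd_resid_sc2: float = Field(default=1.0, ge=0.0)


class RecallParams(BaseModel):
    """How the remembered baseline sc_t1mem is formed.

    ``lam`` weights the true baseline (accurate recall), ``psi`` the current
    state (reconstruction from the present, the "implicit theory of change");
    the gammas let antecedent, catalyst and mechanism distort recall;
    ``sd_mem`` is pure recall noise. lam and psi are not constrained to sum
    to 1 — use :meth:`convex` for the psi = 1 - lam preset.
    """

    lam: float = Field(default=1.0, ge=0.0, le=1.0)
    psi: float = Field(default=0.0, ge=0.0, le=1.0)
    gamma_antecedent: float = 0.0
    gamma_catalyst: float = 0.0
    gamma_mechanism: float = 0.0
    sd_mem: float = Field(default=0.0, ge=0.0)

    @classmethod
    def convex(cls, lam: float, **kwargs: Any) -> "RecallParams":
        """Convex-recall preset: psi = 1 - lam."""
        return cls(lam=lam, psi=1.0 - lam, **kwargs)


class MeasurementParams(BaseModel):
    """Psychometric mode: ``ctt`` needs ``reliability``; ``irt`` needs ``item_bank``."""

    mode: Literal["ctt", "irt"] = "ctt"
    reliability: float | None = None
    item_bank: ItemBank | None = None
    rescale_0_100: bool = False

    @model_validator(mode="after")
    def _check(self) -> "MeasurementParams":
        if self.mode == "ctt":
            if self.reliability is None:
                raise ValueError("ctt mode requires 'reliability'")
            if self.item_bank is not None:
                raise ValueError("ctt mode must not set 'item_bank'")
            if not 0.0 < self.reliability <= 1.0:
                raise ValueError(f"reliability must be in (0, 1], got {self.reliability}")
        else:
            if self.item_bank is None:
                raise ValueError("irt mode requires 'item_bank'")
            if self.reliability is not None:
                raise ValueError("irt mode must not set 'reliability'")
        return self


ANCHOR_ESTIMATORS = ("mean_change_minimal_group", "mean_diff_adjacent", "roc_threshold")
DISTRIBUTION_ESTIMATORS = ("es_based", "sem_based")
ALL_ESTIMATORS = ANCHOR_ESTIMATORS + DISTRIBUTION_ESTIMATORS


class EstimatorSettings(BaseModel):
    """Which estimators to run and their knobs."""

    ids: list[str] = Field(default_factory=lambda: list(ALL_ESTIMATORS))
    roc_criterion: Literal["euclidean", "youden", "weighted"] = "euclidean"
    roc_weight: float = Field(default=0.5, gt=0.0, lt=1.0)
    guard_cutoff: float = 0.30
    es_multiplier: float = 0.5
    sem_multiplier: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "EstimatorSettings":
        unknown = [i for i in self.ids if i not in ALL_ESTIMATORS]
        if unknown:
            raise ValueError(f"unknown estimator ids: {unknown}")
        return self


class ScenarioConfig(BaseModel):
    """Full parameterization of one simulated population + study design."""

    scenario_id: str = "scenario"
    n_subjects: int = Field(ge=10)
    n_replications: int = Field(default=1, ge=1)
    base_seed: int = Field(default=0, ge=0)
    latent: LatentParams = Field(default_factory=LatentParams)
    recall: RecallParams = Field(default_factory=RecallParams)
    measurement: MeasurementParams = Field(default_factory=lambda: MeasurementParams(reliability=1.0))
    pgrc: PgrcParams
    estimators: EstimatorSettings = Field(default_factory=EstimatorSettings)


def loads_config(text: str) -> ScenarioConfig:
    """Parse and validate a scenario from a YAML/JSON string."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"could not parse scenario file{where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("scenario file must contain a mapping")
    try:
        return ScenarioConfig(**raw)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) or "<root>" for e in exc.errors())
        raise ConfigError(f"invalid scenario (fields: {fields}): {exc}") from exc


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"scenario file not found: {path}")
    return loads_config(path.read_text())


def serialize_config(config: ScenarioConfig) -> str:
    """Serialize a scenario back to YAML; round-trips through load."""
    return yaml.safe_dump(config.model_dump(), sort_keys=False)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(serialize_config(config))


def true_mpc(config: ScenarioConfig) -> tuple[float, float]:
    """Ground-truth (MPC+, MPC-) on the perceived-change continuum.

    These are the location parameters of the two thresholds adjacent to the
    middle ("no change") category: the minimal perceived change for
    improvement (positive) and deterioration (negative).
    """
    mus = [t.mu for t in config.pgrc.thresholds]
    mid = (config.pgrc.k - 1) // 2
    return mus[mid], mus[mid - 1]


def _set_path(data: dict[str, Any], path: str, value: Any) -> None:
    parts = path.split(".")
    node = data
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"unknown config path: {path}")
        node = node[part]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise ConfigError(f"unknown config path: {path}")
    node[parts[-1]] = value


def expand_grid(
    base: ScenarioConfig, factor_levels: dict[str, list[Any]] | None = None
) -> list[ScenarioConfig]:
    """Cartesian product of factor levels over a base scenario.

    Keys are dotted config paths (e.g. ``"recall.sd_mem"``); ordering is
    lexicographic over the declared factor order. Each child gets a distinct
    derived base_seed and a scenario_id recording its factor levels.
    Duplicate levels within a factor are dropped with a warning.
    """
    factor_levels = factor_levels or {}
    factors: list[tuple[str, list[Any]]] = []
    for path, levels in factor_levels.items():
        seen: list[Any] = []
        for lev in levels:
            if lev in seen:
                logger.warning("duplicate level %r for factor %s dropped", lev, path)
            else:
                seen.append(lev)
        factors.append((path, seen))

    combos = list(itertools.product(*[levels for _, levels in factors])) if factors else [()]
    seeds = np.random.SeedSequence(base.base_seed).generate_state(len(combos)) % (2**31)
    out: list[ScenarioConfig] = []
    for i, combo in enumerate(combos):
        data = base.model_dump()
        tags = []
        for (path, _), value in zip(factors, combo):
            _set_path(data, path, value)
            tags.append(f"{path}={value}")
        data["base_seed"] = int(seeds[i])
        if tags:
            data["scenario_id"] = f"{base.scenario_id}[{','.join(tags)}]"
        try:
            out.append(ScenarioConfig(**data))
        except ValidationError as exc:
            raise ConfigError(f"grid point {tags} invalid: {exc}") from exc
    return out


def degenerate_scenario(
    mpc_plus: float = 0.8,
    mpc_minus: float = -1.0,
    k: int = 3,
    n_subjects: int = 5000,
    n_replications: int = 200,
    base_seed: int = 0,
    **overrides: Any,
) -> ScenarioConfig:
    """Noise-free reference scenario: perfect recall, reliability 1, fixed thresholds.

    The latent construct evolves as sc_t2 = sc_t1 + N(0, 1), recall is exact,
    scores equal latent levels, and every subject uses exactly the population
    threshold locations — so the change score is the perceived change and the
    true MPC is recoverable in principle. The two middle-adjacent thresholds
    sit at (mpc_minus, mpc_plus); for k = 5 or 7 outer thresholds are added
    at ±2, ±4 construct units beyond them.
    """
    mus = [mpc_minus, mpc_plus]
    n_outer = (k - 3) // 2
    for i in range(1, n_outer + 1):
        mus = [mpc_minus - 2.0 * i] + mus + [mpc_plus + 2.0 * i]
    data: dict[str, Any] = dict(
        scenario_id="degenerate",
        n_subjects=n_subjects,
        n_replications=n_replications,
        base_seed=base_seed,
        latent=LatentParams(mean_sc_t1=0.0, sd_sc_t1=1.0, rho_auto=1.0, sd_resid_sc2=1.0),
        recall=RecallParams(lam=1.0, psi=0.0, sd_mem=0.0),
        measurement=MeasurementParams(mode="ctt", reliability=1.0),
        pgrc=PgrcParams(k=k, thresholds=[ThresholdSpec(mu=m, sigma=0.0) for m in mus]),
    )
    data.update(overrides)
    return ScenarioConfig(**data)
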