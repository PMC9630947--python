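"""Synthetic registry cohorts with a known treatment-assignment model.

Real hospital-registry extracts (NCDB-style) are restricted, so every
downstream stage — propensity estimation, matching, the inclusion
explainers — is exercised on simulated cohorts whose ground truth is known:
bounded integer ages, multi-level categorical covariates with configurable
marginals, and a logistic treatment model whose coefficients the user sets.
Because treatment is assigned by exactly the logistic form the logistic
estimator fits, parameter recovery is a valid end-to-end check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousCovariate",
    "CategoricalCovariate",
    "GeneratorConfig",
    "generate_cohort",
    "true_propensity",
    "encode_design",
    "load_preset",
    "write_cohort_csv",
]


class ConfigurationError(ValueError):
    """A generator or encoding configuration violates its invariants."""


@dataclass(frozen=True)
class ContinuousCovariate:
    """Truncated-normal covariate on [lo, hi].

    ``integer=True`` rounds draws to whole units (ages in years).
    """

    name: str
    lo: float
    hi: float
    mean: float | None = None  # defaults to midpoint of [lo, hi]
    sd: float | None = None    # defaults to range/4

    integer: bool = False

    kind: str = field(default="continuous", init=False)

    def validate(self) -> None:
        if not self.lo < self.hi:
            raise ConfigurationError(
                f"covariate {self.name!r}: support requires lo < hi "
                f"(got [{self.lo}, {self.hi}])"
            )
        if self.sd is not None and self.sd <= 0:
            raise ConfigurationError(f"covariate {self.name!r}: sd must be > 0")

    @property
    def effective_mean(self) -> float:
        return 0.5 * (self.lo + self.hi) if self.mean is None else self.mean

    @property
    def effective_sd(self) -> float:
        return (self.hi - self.lo) / 4.0 if self.sd is None else self.sd


@dataclass(frozen=True)
class CategoricalCovariate:
    """Categorical covariate with declared levels and marginal probabilities."""

    name: str
    levels: tuple[str, ...]
    probabilities: tuple[float, ...]

    kind: str = field(default="categorical", init=False)

    def validate(self) -> None:
        if len(self.levels) != len(self.probabilities):
            raise ConfigurationError(
                f"covariate {self.name!r}: {len(self.levels)} levels but "
                f"{len(self.probabilities)} probabilities"
            )
        if len(self.levels) < 2:
            raise ConfigurationError(
                f"covariate {self.name!r}: needs at least 2 levels"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"covariate {self.name!r}: duplicate levels")
        if any(p < 0 for p in self.probabilities):
            raise ConfigurationError(
                f"covariate {self.name!r}: negative marginal probability"
            )
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"covariate {self.name!r}: marginal probabilities sum to "
                f"{sum(self.probabilities)!r}, expected 1"
            )


Covariate = ContinuousCovariate | CategoricalCovariate


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for one synthetic cohort.

    ``treatment_coefficients`` is on the log-odds scale: one intercept
    followed by one coefficient per design column of :func:`encode_design`
    (continuous covariates contribute their raw value; a k-level categorical
    contributes k-1 dummy indicators, first declared level as reference).
    """

    n: int
    covariates: tuple[Covariate, ...]
    treatment_coefficients: tuple[float, ...]
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names in schema")
        for cov in self.covariates:
            cov.validate()
        width = design_width(self.covariates)
        if len(self.treatment_coefficients) != width + 1:
            raise ConfigurationError(
                f"treatment_coefficients has length "
                f"{len(self.treatment_coefficients)}; expected intercept + "
                f"{width} design columns = {width + 1}"
            )

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]


def design_width(covariates: Sequence[Covariate]) -> int:
    return sum(
        1 if c.kind == "continuous" else len(c.levels) - 1 for c in covariates
    )


def _sample_truncnorm(
    rng: np.random.Generator, n: int, cov: ContinuousCovariate
) -> np.ndarray:
    # Rejection sampling: supports here are narrow (a few SDs) so acceptance
    # is high; loop caps pathological configs.
    out = np.empty(n)
    filled = 0
    mean, sd = cov.effective_mean, cov.effective_sd
    for _ in range(1000):
        need = n - filled
        draw = rng.normal(mean, sd, size=max(need * 2, 16))
        ok = draw[(draw >= cov.lo) & (draw <= cov.hi)]
        take = min(need, ok.size)
        out[filled : filled + take] = ok[:take]
        filled += take
        if filled == n:
            break
    else:  # pragma: no cover - requires a support far outside mean +- sd
        raise ConfigurationError(
            f"covariate {cov.name!r}: truncated-normal support [{cov.lo}, "
            f"{cov.hi}] rejects nearly all draws from N({mean}, {sd}^2)"
        )
    if cov.integer:
        out = np.rint(out)
        np.clip(out, np.ceil(cov.lo), np.floor(cov.hi), out=out)
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort table: subject_id, covariates in schema order, T, true_score.

    Covariates are mutually independent; treatment is Bernoulli with the
    logistic probability of :func:`true_propensity`.  Identical config and
    seed give an identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cols: dict[str, np.ndarray | pd.Series] = {
        "subject_id": np.arange(config.n, dtype=np.int64)
    }
    for cov in config.covariates:
        if cov.kind == "continuous":
            vals = _sample_truncnorm(rng, config.n, cov)
            cols[cov.name] = vals.astype(np.int64) if cov.integer else vals
        else:
            idx = rng.choice(
                len(cov.levels), size=config.n, p=np.asarray(cov.probabilities)
            )
            cols[cov.name] = pd.Categorical.from_codes(
                idx, categories=list(cov.levels)
            )
    cohort = pd.DataFrame(cols)
    score = true_propensity(config, cohort)
    cohort["T"] = (rng.random(config.n) < score).astype(np.int64)
    cohort["true_score"] = score
    return cohort


def true_propensity(
    config: GeneratorConfig, covariates: pd.DataFrame | pd.Series
) -> np.ndarray:
    """Inverse-logit of intercept + design @ coefficients, one value per row."""
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame().T
    X, _ = encode_design(covariates, config.covariates)
    beta = np.asarray(config.treatment_coefficients, dtype=float)
    eta = beta[0] + X @ beta[1:]
    out = 1.0 / (1.0 + np.exp(-eta))
    return out


def encode_design(
    cohort: pd.DataFrame,
    covariates: Sequence[Covariate],
    reference_levels: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-code a cohort into a dense design matrix.

    Continuous covariates pass through; a k-level categorical becomes k-1
    indicators with the reference level omitted.  The reference defaults to
    the first declared level; ``reference_levels`` overrides per covariate.
    Column order is deterministic: schema order, levels in declared order.
    """
    reference_levels = reference_levels or {}
    columns: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov.name not in cohort.columns:
            raise ConfigurationError(f"column {cov.name!r} missing from table")
        if cov.kind == "continuous":
            columns.append(np.asarray(cohort[cov.name], dtype=float))
            names.append(cov.name)
            continue
        ref = reference_levels.get(cov.name, cov.levels[0])
        if ref not in cov.levels:
            raise ConfigurationError(
                f"reference level {ref!r} not a declared level of {cov.name!r}"
            )
        observed = np.asarray(cohort[cov.name].astype(object))
        unknown = set(observed) - set(cov.levels)
        if unknown:
            raise ConfigurationError(
                f"covariate {cov.name!r}: unknown level(s) {sorted(unknown)!r}"
            )
        for level in cov.levels:
            if level == ref:
                continue
            columns.append((observed == level).astype(float))
            names.append(f"{cov.name}[{level}]")
    X = np.column_stack(columns) if columns else np.empty((len(cohort), 0))
    return X, names


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """CSV with header, UTF-8, '.' decimal; subject_id, covariates, T order."""
    cols = [c for c in cohort.columns if c != "true_score"]
    cohort[cols].to_csv(path, index=False, lineterminator="\n")


# --- presets ---------------------------------------------------------------

def _config_from_dict(raw: dict) -> GeneratorConfig:
    covs: list[Covariate] = []
    for c in raw["covariates"]:
        if c["kind"] == "continuous":
            covs.append(
                ContinuousCovariate(
                    name=c["name"],
                    lo=c["lo"],
                    hi=c["hi"],
                    mean=c.get("mean"),
                    sd=c.get("sd"),
                    integer=c.get("integer", False),
                )
            )
        elif c["kind"] == "categorical":
            covs.append(
                CategoricalCovariate(
                    name=c["name"],
                    levels=tuple(c["levels"]),
                    probabilities=tuple(c["probabilities"]),
                )
            )
        else:
            raise ConfigurationError(f"unknown covariate kind {c['kind']!r}")
    cfg = GeneratorConfig(
        n=raw["n"],
        covariates=tuple(covs),
        treatment_coefficients=tuple(raw["treatment_coefficients"]),
        seed=raw.get("seed", 0),
    )
    cfg.validate()
    return cfg


def load_preset(
    name: str, n: int | None = None, seed: int | None = None
) -> GeneratorConfig:
    """Load a shipped preset ('hn_ncdb' or 'gbm_ncdb'), optionally overriding
    the subject count or seed."""
    ref = resources.files("matchexplain").joinpath(f"presets/{name}.json")
    try:
        raw = json.loads(ref.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise ConfigurationError(f"unknown preset {name!r}") from None
    if n is not None:
        raw["n"] = n
    if seed is not None:
        raw["seed"] = seed
    return _config_from_dict(raw)
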