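"""Synthetic CABG-style case-mix generation.

Patient risk profiles are built from eight predictors of post-surgical
mortality: centered age (continuous, years) plus seven binary risk factors
(female sex, chronic pulmonary disease, extracardiac arteriopathy, unstable
angina, moderate left-ventricular dysfunction, recent myocardial infarction,
emergency intervention).  Binary factors must each have a marginal prevalence
above 5%, mirroring the inclusion rule used to select case-mix variables from
cardiac-surgery registries.

The generator is parametric: age is a centered truncated normal and the binary
factors are Bernoulli, independent by default, with an optional latent-Gaussian
copula when a correlation structure is wanted.  The default prevalences are
stand-ins chosen as plausible values for an isolated-CABG cohort; real-registry
joint structure is explicitly out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical predictor order.  Column 0 is continuous (centered age in years);
#: the remaining seven are binary risk factors coded 0/1.
PREDICTORS: tuple[str, ...] = (
    "age",
    "sex",
    "chronic_pulmonary_disease",
    "extracardiac_arteriopathy",
    "unstable_angina",
    "lv_dysfunction_moderate",
    "recent_mi",
    "emergency",
)

BINARY_PREDICTORS: tuple[str, ...] = PREDICTORS[1:]

#: Stand-in marginal prevalences for an isolated-CABG cohort (all > 5%, the
#: variable-inclusion rule).  These are synthetic defaults, not registry values.
DEFAULT_PREVALENCES: dict[str, float] = {
    "sex": 0.25,  # proportion female
    "chronic_pulmonary_disease": 0.10,
    "extracardiac_arteriopathy": 0.11,
    "unstable_angina": 0.15,
    "lv_dysfunction_moderate": 0.25,
    "recent_mi": 0.10,
    "emergency": 0.06,
}


class ConfigError(ValueError):
    """Invalid case-mix configuration."""


@dataclass
class CaseMixConfig:
    """Configuration of the synthetic case-mix distribution.

    Parameters
    ----------
    age_sd:
        Standard deviation of centered age, in years (before truncation).
    age_bound:
        Symmetric truncation bound for centered age, in years.
    prevalences:
        Mapping of the seven binary predictor names to marginal prevalences,
        each strictly inside (0.05, 0.95).
    correlation:
        Optional 8x8 latent-Gaussian copula correlation matrix (unit diagonal,
        positive semi-definite), ordered as :data:`PREDICTORS`.  ``None`` means
        independent predictors.
    """

    age_sd: float = 10.0
    age_bound: float = 30.0
    prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.age_bound <= 0:
            raise ConfigError("age_sd and age_bound must be positive")
        if set(self.prevalences) != set(BINARY_PREDICTORS):
            raise ConfigError(
                f"prevalences must list exactly {BINARY_PREDICTORS}, "
                f"got {sorted(self.prevalences)}"
            )
        for name, p in self.prevalences.items():
            if not 0.05 < p < 0.95:
                raise ConfigError(
                    f"prevalence of {name!r} must lie in (0.05, 0.95), got {p}"
                )
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            if R.shape != (len(PREDICTORS), len(PREDICTORS)):
                raise ConfigError("correlation must be 8x8")
            if not np.allclose(R, R.T, atol=1e-12):
                raise ConfigError("correlation must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-12):
                raise ConfigError("correlation must have unit diagonal")
            evals = np.linalg.eigvalsh(R)
            if evals.min() < -1e-10:
                raise ConfigError("correlation must be positive semi-definite")
            self.correlation = R

    def to_dict(self) -> dict:
        d = {
            "age_sd": self.age_sd,
            "age_bound": self.age_bound,
            "prevalences": dict(self.prevalences),
        }
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CaseMixConfig":
        corr = d.get("correlation")
        return cls(
            age_sd=d.get("age_sd", 10.0),
            age_bound=d.get("age_bound", 30.0),
            prevalences=dict(d.get("prevalences", DEFAULT_PREVALENCES)),
            correlation=None if corr is None else np.asarray(corr, dtype=float),
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_cohort(config: CaseMixConfig, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` synthetic patients.

    Returns a DataFrame with the eight :data:`PREDICTORS` columns: centered
    age (float, years) and seven 0/1 risk factors.  Deterministic given the
    seed; ``seed`` may be an int, a ``SeedSequence`` or a ``Generator`` (the
    latter is consumed statefully, which the quota-filling sampler relies on).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _as_rng(seed)

    a = -config.age_bound / config.age_sd
    trunc = stats.truncnorm(a, -a)

    if config.correlation is None:
        u = rng.random((n, len(PREDICTORS)))
    else:
        L = np.linalg.cholesky(
            config.correlation + 1e-12 * np.eye(len(PREDICTORS))
        )
        z = rng.standard_normal((n, len(PREDICTORS))) @ L.T
        u = stats.norm.cdf(z)

    cols: dict[str, np.ndarray] = {}
    cols["age"] = config.age_sd * trunc.ppf(u[:, 0]) if n else np.empty(0)
    for j, name in enumerate(BINARY_PREDICTORS, start=1):
        p = config.prevalences[name]
        cols[name] = (u[:, j] < p).astype(np.int64) if n else np.empty(0, np.int64)

    return pd.DataFrame(cols, columns=list(PREDICTORS))
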