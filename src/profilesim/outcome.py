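"""Outcome generation: provider random intercepts with outlier structure.

Each patient's mortality indicator is drawn from a random-intercept logistic
model

    logit(p_ik) = gamma00 + alpha_0k + beta'_1 Z1 + ... + beta'_8 Z8,

where ``alpha_0k ~ N(mu, sigma^2)`` with ``mu = 0`` for normal providers and
``mu = +/- H * sigma`` for true performance outliers.  Positive ``alpha_0k``
means higher mortality, i.e. *below-average* performance; with one-sided
outliers (S=1) all outliers sit on that side.  The overall intercept
``gamma00`` is calibrated per generated dataset so the average outcome
incidence over patients hits the scenario target exactly, and every provider
must realize an incidence of at least 1% (guarding against separation in the
downstream fits).

The case-mix log-odds coefficients default to the published logistic EuroSCORE
model (Roques et al., Eur J Cardiothorac Surg 2003), restricted to the eight
predictors used here, with age coded as a centered per-year log-odds term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .assignment import AssignedCohort
from .casemix import PREDICTORS, _as_rng

NORMAL = "normal"
#: Below-average performance: higher mortality, mu = +H*sigma.
OUTLIER_LOW = "outlier-low"
#: Above-average performance: lower mortality, mu = -H*sigma.
OUTLIER_HIGH = "outlier-high"

#: Log-odds coefficients transcribed from the published logistic EuroSCORE
#: model, restricted to the eight predictors retained here.  Age is coded as a
#: centered per-year term.  Fully overridable via :class:`OutcomeModel`.
EUROSCORE_LOG_ODDS: dict[str, float] = {
    "age": 0.0666354,
    "sex": 0.3304052,
    "chronic_pulmonary_disease": 0.4931341,
    "extracardiac_arteriopathy": 0.6558917,
    "unstable_angina": 0.5677075,
    "lv_dysfunction_moderate": 0.4191643,
    "recent_mi": 0.5460218,
    "emergency": 0.7127953,
}


class IncidenceError(RuntimeError):
    """Per-provider minimum-incidence rule unattainable within retry budget."""


@dataclass
class ScenarioSpec:
    """One design point of the simulation grid.

    Fields mirror the scenario parameters: number of providers ``K``, target
    average incidence ``p_bar``, true-outlier fraction ``p_out``, shift ``H``
    in units of the random-intercept SD, number of outlier sides ``S`` (1 =
    below-average only, 2 = both), smaller provider volume ``min_volume``
    (half the providers; the rest get ``max_volume``), probability ``p_nmin``
    that an outlier receives the smaller volume, and random-intercept SD
    ``sigma`` (default 0.1942).
    """

    K: int = 50
    p_bar: float = 0.10
    p_out: float = 0.2
    H: float = 2.0
    S: int = 2
    min_volume: int = 1000
    max_volume: int = 1000
    p_nmin: float = 0.5
    sigma: float = 0.1942
    scenario: int | None = None

    def __post_init__(self) -> None:
        if self.K < 2 or self.K % 2:
            raise ValueError("K must be an even integer >= 2")
        if not 0 < self.p_bar < 1:
            raise ValueError("p_bar must lie in (0, 1)")
        if not 0 < self.p_out < 1:
            raise ValueError("p_out must lie in (0, 1)")
        if self.H < 0:
            raise ValueError("H must be non-negative")
        if self.S not in (1, 2):
            raise ValueError("S must be 1 or 2")
        if not 0 < self.min_volume <= self.max_volume <= 1000:
            raise ValueError("require 0 < min_volume <= max_volume <= 1000")
        if not 0 <= self.p_nmin <= 1:
            raise ValueError("p_nmin must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.S == 2 and self.n_outliers % 2:
            raise ValueError(
                "round(p_out * K) must be even when S == 2 (equal split)"
            )

    @property
    def n_outliers(self) -> int:
        return int(round(self.p_out * self.K))

    def to_dict(self) -> dict:
        return {
            "K": self.K, "p_bar": self.p_bar, "p_out": self.p_out,
            "H": self.H, "S": self.S, "min_volume": self.min_volume,
            "max_volume": self.max_volume, "p_nmin": self.p_nmin,
            "sigma": self.sigma, "scenario": self.scenario,
        }


@dataclass
class ProviderTruth:
    """True per-provider status fixed when generating a dataset."""

    classes: np.ndarray  # {normal, outlier-low, outlier-high} per provider
    mu: np.ndarray  # distribution mean of the random intercept
    alpha: np.ndarray  # realized random intercepts alpha_0k
    volumes: np.ndarray  # target patient volume per provider

    @property
    def K(self) -> int:
        return len(self.classes)

    @property
    def is_outlier(self) -> np.ndarray:
        return self.classes != NORMAL

    def redraw_alpha(self, seed) -> "ProviderTruth":
        """Fresh random intercepts from the same class means.

        Used when the minimum-incidence rule cannot be met by redrawing
        outcomes alone: regeneration restarts from the random-intercept stage
        while keeping classes and volumes.
        """
        rng = _as_rng(seed)
        sigma = getattr(self, "_sigma", None)
        if sigma is None:
            raise RuntimeError("sigma not recorded on this truth object")
        alpha = self.mu + sigma * rng.standard_normal(self.K)
        out = ProviderTruth(
            classes=self.classes, mu=self.mu, alpha=alpha, volumes=self.volumes
        )
        out._sigma = sigma
        return out


@dataclass
class OutcomeModel:
    """Fixed part of the outcome-generating logistic model."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(EUROSCORE_LOG_ODDS)
    )
    gamma00: float | None = None
    min_incidence: float = 0.01

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(PREDICTORS):
            raise ValueError(
                f"coefficients must cover exactly {PREDICTORS}"
            )

    @property
    def beta(self) -> np.ndarray:
        """Coefficient vector aligned with :data:`PREDICTORS`."""
        return np.array([self.coefficients[p] for p in PREDICTORS])

    @property
    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}


def mu_to_odds_ratio(mu: float) -> float:
    """Odds ratio implied by a log-odds shift of the random-intercept mean.

    E.g. a shift of ``+/- 2 * 0.1942 = +/- 0.3884`` corresponds to odds ratios
    of 1.475 and 0.678.
    """
    return float(np.exp(mu))


def allocate_provider_truth(spec: ScenarioSpec, seed) -> ProviderTruth:
    """Draw true classes, volumes and random intercepts for K providers.

    ``round(p_out * K)`` providers are outliers, split equally between the
    below-average (``mu = +H*sigma``) and above-average (``mu = -H*sigma``)
    sides when ``S == 2``, all below-average when ``S == 1``.  Half the
    providers receive the smaller volume; each outlier independently gets a
    small slot with probability ``p_nmin`` (excess demand beyond the K/2 small
    slots is reallocated to large slots).
    """
    rng = _as_rng(seed)
    K, n_out = spec.K, spec.n_outliers

    classes = np.full(K, NORMAL, dtype=object)
    outlier_idx = rng.choice(K, size=n_out, replace=False)
    if spec.S == 2:
        half = n_out // 2
        classes[outlier_idx[:half]] = OUTLIER_LOW
        classes[outlier_idx[half:]] = OUTLIER_HIGH
    else:
        classes[outlier_idx] = OUTLIER_LOW

    mu = np.zeros(K)
    mu[classes == OUTLIER_LOW] = spec.H * spec.sigma
    mu[classes == OUTLIER_HIGH] = -spec.H * spec.sigma

    volumes = np.full(K, spec.max_volume, dtype=int)
    if spec.min_volume < spec.max_volume:
        n_small = K // 2
        small_outliers = outlier_idx[rng.random(n_out) < spec.p_nmin]
        if small_outliers.size > n_small:
            keep = rng.choice(small_outliers, size=n_small, replace=False)
            small_outliers = keep
        n_fill = n_small - small_outliers.size
        normal_idx = np.setdiff1d(np.arange(K), small_outliers)
        fillers = rng.choice(normal_idx, size=n_fill, replace=False)
        volumes[small_outliers] = spec.min_volume
        volumes[fillers] = spec.min_volume

    alpha = mu + spec.sigma * rng.standard_normal(K)
    truth = ProviderTruth(classes=classes, mu=mu, alpha=alpha, volumes=volumes)
    truth._sigma = spec.sigma
    return truth


def calibrate_intercept(
    cohort: AssignedCohort,
    truth: ProviderTruth,
    beta: np.ndarray,
    target: float,
) -> float:
    """Overall intercept making the mean patient-level probability hit target.

    The expected incidence is strictly increasing in ``gamma00``, so the root
    is unique; solved by Brent's method to a residual well below 1e-6.
    """
    if not 0 < target < 1:
        raise ValueError("target incidence must lie in (0, 1)")
    Z = cohort.covariates.to_numpy(dtype=float)
    offset = truth.alpha[cohort.provider - 1] + Z @ np.asarray(beta, float)

    def resid(g: float) -> float:
        return float(expit(g + offset).mean() - target)

    return float(brentq(resid, -60.0, 60.0, xtol=1e-12, rtol=1e-14))


def draw_outcomes(
    cohort: AssignedCohort,
    truth: ProviderTruth,
    model: OutcomeModel,
    seed,
    max_retries: int = 100,
) -> np.ndarray:
    """Bernoulli outcome vector honoring the per-provider incidence floor.

    Outcomes are redrawn (same probabilities) up to ``max_retries`` times
    until every provider's realized incidence is at least
    ``model.min_incidence``; raises :class:`IncidenceError` if the floor is
    still violated, at which point the caller regenerates from the
    random-intercept stage.
    """
    if model.gamma00 is None:
        raise ValueError("gamma00 must be calibrated before drawing outcomes")
    rng = _as_rng(seed)
    Z = cohort.covariates.to_numpy(dtype=float)
    idx = cohort.provider - 1
    p = expit(model.gamma00 + truth.alpha[idx] + Z @ model.beta)
    vol = np.asarray(cohort.volumes, dtype=float)

    for _ in range(max_retries + 1):
        y = (rng.random(cohort.N) < p).astype(np.int64)
        if model.min_incidence <= 0:
            return y
        events = np.bincount(idx, weights=y, minlength=cohort.K)
        if (events / vol >= model.min_incidence - 1e-12).all():
            return y
    raise IncidenceError(
        f"minimum per-provider incidence {model.min_incidence} not reached "
        f"after {max_retries} outcome redraws"
    )
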