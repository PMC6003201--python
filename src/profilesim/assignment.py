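"""Provider assignment by multinomial logit with fixed volume quotas.

Each synthetic patient chooses one of K providers with probability

    pi_k = exp(alpha_k + beta_k * (Z1 + ... + Z8)) / sum_j exp(...)

where the per-provider coefficient ``beta_k`` is shared across the eight
case-mix variables, drawn Uniform(0, 1) for all but a reference provider whose
parameters are zero.  Because larger-beta providers attract sicker patients,
case-mix confounds crude provider comparisons by construction.

Fixed per-provider volumes are met by rejection sampling: candidates are drawn
one at a time from the case-mix generator, a provider is drawn from the
candidate's probability vector, and the candidate is discarded entirely when
that provider's quota is already full.  The implementation batches candidate
draws but is order-equivalent to the literal one-at-a-time rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .casemix import PREDICTORS, CaseMixConfig, generate_cohort, _as_rng


class SchemaError(ValueError):
    """Covariate columns do not match the model's predictors."""


class QuotaError(RuntimeError):
    """Quota filling exceeded its safety cap."""


@dataclass
class AssignmentModel:
    """Multinomial-logit provider attendance model.

    Providers are labeled ``1..K``; provider 1 is the reference with
    ``alpha = beta = 0``.  ``beta`` holds one shared coefficient per provider,
    applied identically to all eight case-mix variables.
    """

    K: int
    beta: np.ndarray
    alpha: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference: int = 1

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha is None:
            self.alpha = np.zeros(self.K)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.beta.shape != (self.K,) or self.alpha.shape != (self.K,):
            raise ValueError("alpha and beta must have length K")
        ref = self.reference - 1
        if self.beta[ref] != 0.0 or self.alpha[ref] != 0.0:
            raise ValueError("reference provider must have alpha = beta = 0")


@dataclass
class AssignedCohort:
    """Case-mix table plus attended-provider label per patient."""

    covariates: pd.DataFrame
    provider: np.ndarray  # labels in 1..K
    volumes: np.ndarray  # target (== realized) volume per provider
    K: int

    @property
    def N(self) -> int:
        return len(self.provider)

    def to_frame(self) -> pd.DataFrame:
        out = self.covariates.copy()
        out.insert(0, "provider", self.provider)
        return out

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "patient", np.arange(len(frame)))
        frame.to_csv(path, index=False)


def draw_assignment_model(K: int, seed) -> AssignmentModel:
    """Draw a provider attendance model.

    Provider 1 is the reference (all parameters zero); providers ``2..K`` get
    a single coefficient ``beta_k ~ Uniform(0, 1)`` shared across the eight
    case-mix variables.  Intercepts are all zero: volumes are fixed downstream
    by quota filling, so intercepts would only shift rejection rates.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = _as_rng(seed)
    beta = np.concatenate([[0.0], rng.uniform(0.0, 1.0, size=K - 1)])
    return AssignmentModel(K=K, beta=beta)


def assignment_probabilities(
    model: AssignmentModel, covariates: pd.DataFrame
) -> np.ndarray:
    """Per-patient attendance probabilities, shape ``(n, K)``.

    Rows are non-negative and sum to one.  Raises :class:`SchemaError` when
    the covariate columns do not match the canonical eight predictors.
    """
    if tuple(covariates.columns) != PREDICTORS:
        raise SchemaError(
            f"expected columns {PREDICTORS}, got {tuple(covariates.columns)}"
        )
    s = covariates.to_numpy(dtype=float).sum(axis=1)
    logits = model.alpha[None, :] + np.outer(s, model.beta)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One categorical draw per row of ``probs`` (0-based index)."""
    c = np.cumsum(probs, axis=1)
    u = rng.random((probs.shape[0], 1))
    return (u < c).argmax(axis=1)


def fill_quotas(
    model: AssignmentModel,
    config: CaseMixConfig,
    volumes,
    seed,
    max_draw_factor: int = 1000,
) -> AssignedCohort:
    """Sample patients until every provider holds exactly its target volume.

    Candidates are drawn from the case-mix generator, assigned a provider from
    their multinomial-logit probability vector, and discarded entirely when the
    drawn provider is already full.  A safety cap of ``max_draw_factor * N``
    candidate draws guards pathological configurations.
    """
    volumes = np.asarray(volumes, dtype=int)
    if volumes.shape != (model.K,):
        raise ValueError("volumes must have length K")
    if (volumes < 1).any():
        raise ValueError("all volumes must be >= 1")

    rng = _as_rng(seed)
    N = int(volumes.sum())
    cap = max_draw_factor * N
    remaining = volumes.copy()
    drawn = 0
    kept_cov: list[pd.DataFrame] = []
    kept_prov: list[np.ndarray] = []

    while remaining.sum() > 0:
        if drawn >= cap:
            raise QuotaError(
                f"quota filling exceeded {cap} candidate draws; "
                f"remaining per provider: {remaining.tolist()}"
            )
        n_unfilled = int((remaining > 0).sum())
        batch = int(min(cap - drawn, max(2048, 3 * remaining.sum() * model.K // max(n_unfilled, 1))))
        cov = generate_cohort(config, batch, rng)
        probs = assignment_probabilities(model, cov)
        choice = _draw_categorical(rng, probs)
        drawn += batch

        # Order-equivalent to one-at-a-time rejection: whether a candidate is
        # accepted depends only on how many earlier candidates chose the same
        # provider, so the first `remaining[k]` candidates per provider (in
        # stream order) are exactly the accepted ones.
        accepted: list[np.ndarray] = []
        for k in np.flatnonzero(remaining):
            idx = np.flatnonzero(choice == k)[: remaining[k]]
            if idx.size:
                accepted.append(idx)
                remaining[k] -= idx.size
        if accepted:
            idx = np.sort(np.concatenate(accepted))
            kept_cov.append(cov.iloc[idx])
            kept_prov.append(choice[idx] + 1)

    covariates = pd.concat(kept_cov, ignore_index=True)
    provider = np.concatenate(kept_prov)
    return AssignedCohort(
        covariates=covariates, provider=provider, volumes=volumes, K=model.K
    )
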