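"""The six risk-adjustment methods and their outlier-classification rules.

* ``LR_F`` — fixed-effects logistic regression: a case-mix-only logistic fit
  supplies the overall intercept; a second fit with K provider dummies (no
  intercept) plus case-mix supplies per-provider estimates; a provider is an
  outlier when its 95% Wald CI excludes the overall intercept.
* ``LR_R`` — random-intercept logistic regression with the eight case-mix
  variables as fixed effects; a provider is an outlier when its
  empirical-Bayes deviation exceeds two observed SDs of the random intercept.
* ``gPS_A`` — as LR_R, but adjusting for K-1 generalized propensity scores
  (the reference provider's column is dropped) instead of raw case-mix.
* ``gPS_W`` / ``gPS_WT`` — inverse-probability weighting by the gPS of the
  attended provider (optionally trimmed at the 98th percentile), followed by a
  weighted providers-only random-intercept fit and the same two-SD rule.
* ``gPS_MWS`` — marginal mean weighting through stratification: quintile
  strata on each provider's gPS, weight = stratum size x marginal share /
  stratum attendees, then as gPS_W.

All methods consume the same generated dataset.  Provider labels come out as
``normal`` / ``outlier-low`` (higher mortality than expected, i.e. worse) /
``outlier-high`` (lower mortality, i.e. better).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .assignment import AssignedCohort
from .glmm import GLMMFit, fit_random_intercept_logistic
from .outcome import NORMAL, OUTLIER_HIGH, OUTLIER_LOW

logger = logging.getLogger(__name__)

METHOD_NAMES = ("LR_F", "LR_R", "gPS_A", "gPS_W", "gPS_WT", "gPS_MWS")
RANDOM_EFFECTS_METHODS = METHOD_NAMES[1:]

_Z95 = float(stats.norm.ppf(0.975))


class MethodFailure(RuntimeError):
    """A method failed on this replicate (separation / non-convergence)."""


class PositivityError(MethodFailure):
    """A fitted attendance probability of an attended provider was zero."""


@dataclass
class GPSMatrix:
    """Fitted generalized propensity scores, shape ``(N, K)``.

    Column ``k`` is each patient's fitted probability of attending provider
    ``k+1``; rows sum to one.  ``reference`` is the column dropped when the
    scores enter a regression (linear dependence).
    """

    probs: np.ndarray
    reference: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any():
            raise ValueError("gPS entries must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("gPS rows must sum to 1 (tolerance 1e-10)")

    @property
    def K(self) -> int:
        return self.probs.shape[1]


@dataclass
class ClassificationResult:
    """Observed per-provider labels from one method on one dataset."""

    method: str
    labels: np.ndarray  # {normal, outlier-low, outlier-high} per provider
    estimate: np.ndarray  # per-provider effect (log-odds deviation)
    threshold: np.ndarray  # per-provider decision threshold (same scale)
    info: dict = field(default_factory=dict)

    @property
    def flagged(self) -> np.ndarray:
        return self.labels != NORMAL


def _labels_from(estimate: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    labels = np.full(len(estimate), NORMAL, dtype=object)
    labels[flagged & (estimate > 0)] = OUTLIER_LOW
    labels[flagged & (estimate <= 0)] = OUTLIER_HIGH
    return labels


def _fit_logit(y, X) -> "sm.discrete.discrete_model.BinaryResultsWrapper":
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is handled below
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=0)
    except Exception as exc:  # separation raises various statsmodels errors
        raise MethodFailure(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise MethodFailure("logistic fit did not converge")
    if not np.isfinite(res.bse).all():
        raise MethodFailure("non-finite standard errors (separation?)")
    return res


def classify_lrf(cohort: AssignedCohort, outcomes) -> ClassificationResult:
    """Two-stage fixed-effects logistic classification (95% Wald CI rule)."""
    y = np.asarray(outcomes, dtype=float)
    Z = cohort.covariates.to_numpy(dtype=float)
    stage1 = _fit_logit(y, sm.add_constant(Z))
    gamma_hat = float(stage1.params[0])

    D = np.zeros((cohort.N, cohort.K))
    D[np.arange(cohort.N), cohort.provider - 1] = 1.0
    stage2 = _fit_logit(y, np.hstack([D, Z]))
    est = np.asarray(stage2.params[: cohort.K], dtype=float)
    se = np.asarray(stage2.bse[: cohort.K], dtype=float)

    lo, hi = est - _Z95 * se, est + _Z95 * se
    flagged = (gamma_hat < lo) | (gamma_hat > hi)
    deviation = est - gamma_hat
    return ClassificationResult(
        method="LR_F",
        labels=_labels_from(deviation, flagged),
        estimate=deviation,
        threshold=_Z95 * se,
        info={"gamma_hat": gamma_hat, "se": se},
    )


def _classify_random_effects(
    method: str,
    y,
    X,
    groups,
    K: int,
    weights=None,
    rule: str = "model_sd",
    **fit_kwargs,
) -> ClassificationResult:
    """Shared empirical-Bayes two-SD rule used by all random-effects methods."""
    fit = fit_random_intercept_logistic(
        y, X, groups, weights=weights, compute_se=False, **fit_kwargs
    )
    if not fit.converged:
        raise MethodFailure(f"{method}: GLMM did not converge ({fit.message})")
    if rule == "model_sd":
        sd = fit.sigma
    elif rule == "eb_sd":
        sd = fit.eb_sd
    else:
        raise ValueError(f"unknown rule {rule!r}")
    eb = np.zeros(K)
    eb[np.asarray(fit.group_labels, dtype=int) - 1] = fit.eb
    flagged = np.abs(eb) > 2.0 * sd
    return ClassificationResult(
        method=method,
        labels=_labels_from(eb, flagged),
        estimate=eb,
        threshold=np.full(K, 2.0 * sd),
        info={"sigma": fit.sigma, "eb_sd": fit.eb_sd, "fit": fit},
    )


def _conditioned_design(M: np.ndarray) -> np.ndarray:
    """Intercept plus an orthonormalized covariate block.

    The random-intercept fit's sigma-hat, EB deviations and log-likelihood are
    invariant to invertible linear maps of the fixed-effect block (the
    intercept absorbs centering), so the block is replaced by scaled QR
    factors to condition the optimization.  Rank-deficient directions are
    dropped.
    """
    n = len(M)
    C = M - M.mean(axis=0)
    Q, R = np.linalg.qr(C)
    keep = np.abs(np.diag(R)) > 1e-8 * np.sqrt(n) * max(
        np.abs(np.diag(R)).max(), 1.0
    )
    return np.hstack([np.ones((n, 1)), Q[:, keep] * np.sqrt(n)])


def classify_lrr(
    cohort: AssignedCohort, outcomes, rule: str = "model_sd", **fit_kwargs
) -> ClassificationResult:
    """Random-intercept logistic regression with case-mix fixed effects."""
    Z = cohort.covariates.to_numpy(dtype=float)
    X = _conditioned_design(Z)
    return _classify_random_effects(
        "LR_R", outcomes, X, cohort.provider, cohort.K, rule=rule, **fit_kwargs
    )


def estimate_gps(cohort: AssignedCohort, tol: float = 1e-8) -> GPSMatrix:
    """Multinomial logistic generalized propensity scores on the 8 predictors."""
    if cohort.K < 2:
        raise ValueError("gPS estimation needs at least 2 providers")
    Z = cohort.covariates.to_numpy(dtype=float)
    clf = LogisticRegression(C=np.inf, solver="newton-cg", tol=tol, max_iter=200)
    clf.fit(Z, cohort.provider)
    if np.max(clf.n_iter_) >= clf.max_iter:
        raise MethodFailure("multinomial gPS model did not converge")
    probs = clf.predict_proba(Z)
    # predict_proba columns follow sorted class labels 1..K already.
    return GPSMatrix(probs=probs, reference=0)


def classify_gps_a(
    cohort: AssignedCohort,
    outcomes,
    gps: GPSMatrix,
    rule: str = "model_sd",
    **fit_kwargs,
) -> ClassificationResult:
    """Random-intercept model adjusting for K-1 gPS columns (gPS_A).

    The gPS columns enter linearly but are orthonormalized first — a pure
    reparametrization (see :func:`_conditioned_design`) that conditions the
    optimization; constant columns carry no information and drop out.
    """
    keep = [k for k in range(gps.K) if k != gps.reference]
    X = _conditioned_design(gps.probs[:, keep])
    return _classify_random_effects(
        "gPS_A", outcomes, X, cohort.provider, cohort.K, rule=rule, **fit_kwargs
    )


def ipw_weights(gps: GPSMatrix, attended: np.ndarray) -> np.ndarray:
    """Inverse of each patient's gPS for the provider actually attended."""
    attended = np.asarray(attended, dtype=int)
    p = gps.probs[np.arange(len(attended)), attended - 1]
    if (p <= 0).any():
        raise PositivityError(
            "zero fitted attendance probability for an attended provider"
        )
    return 1.0 / p


def trim_weights(weights, trim_fraction: float = 0.02) -> np.ndarray:
    """Cap weights above the (1 - trim_fraction) sample quantile.

    The cap uses the linear-interpolation sample quantile; values at or below
    it are unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    cap = np.quantile(w, 1.0 - trim_fraction)
    return np.minimum(w, cap)


def mmws_weights(
    gps: GPSMatrix, attended: np.ndarray, n_strata: int = 5
) -> np.ndarray:
    """Marginal mean weights through stratification.

    For patient i attending provider k: stratify everyone on provider k's gPS
    into ``n_strata`` quantile bins; the weight is

        (patients in i's stratum) * (marginal share attending k)
        / (attendees of k in that stratum).

    Degenerate gPS distributions can collapse strata (ties), which is logged;
    attendees always have a populated stratum by construction.
    """
    attended = np.asarray(attended, dtype=int)
    N, K = gps.probs.shape
    share = np.bincount(attended - 1, minlength=K) / N
    w = np.empty(N, dtype=float)
    qs = np.linspace(0, 1, n_strata + 1)[1:-1]
    for k in range(K):
        scores = gps.probs[:, k]
        cuts = np.quantile(scores, qs)
        strata = np.searchsorted(cuts, scores, side="right")
        n_effective = len(np.unique(strata))
        if n_effective < n_strata:
            logger.info(
                "provider %d: gPS ties collapsed strata to %d", k + 1, n_effective
            )
        stratum_size = np.bincount(strata, minlength=n_strata)
        mask = attended == k + 1
        attendees = np.bincount(strata[mask], minlength=n_strata)
        s = strata[mask]
        w[mask] = stratum_size[s] * share[k] / attendees[s]
    return w


def classify_weighted(
    cohort: AssignedCohort,
    outcomes,
    weights,
    method: str,
    rule: str = "model_sd",
    **fit_kwargs,
) -> ClassificationResult:
    """Weighted providers-only random-intercept fit with the two-SD rule.

    Used for gPS_W (raw IPW), gPS_WT (trimmed IPW) and gPS_MWS (MMW).  Since
    the linear predictor is constant within provider, patients are collapsed
    to two weighted pseudo-observations per provider (events / non-events),
    which leaves the weighted likelihood identical.
    """
    y = np.asarray(outcomes, dtype=float)
    w = np.asarray(weights, dtype=float)
    idx = cohort.provider - 1
    sw = np.bincount(idx, weights=w, minlength=cohort.K)
    swy = np.bincount(idx, weights=w * y, minlength=cohort.K)

    y2 = np.concatenate([np.ones(cohort.K), np.zeros(cohort.K)])
    w2 = np.concatenate([swy, sw - swy])
    g2 = np.concatenate([np.arange(1, cohort.K + 1)] * 2)
    X2 = np.ones((2 * cohort.K, 1))
    return _classify_random_effects(
        method, y2, X2, g2, cohort.K, weights=w2, rule=rule, **fit_kwargs
    )


def run_all_methods(
    cohort: AssignedCohort,
    outcomes,
    methods=METHOD_NAMES,
    rule: str = "model_sd",
    trim_fraction: float = 0.02,
    n_strata: int = 5,
) -> tuple[dict[str, ClassificationResult], dict[str, str]]:
    """Apply the requested methods to one dataset.

    Returns ``(results, failures)``; a failed method appears only in
    ``failures`` with the reason, the others proceed.
    """
    results: dict[str, ClassificationResult] = {}
    failures: dict[str, str] = {}
    gps = None
    need_gps = any(m.startswith("gPS") for m in methods)
    if need_gps:
        try:
            gps = estimate_gps(cohort)
        except MethodFailure as exc:
            for m in methods:
                if m.startswith("gPS"):
                    failures[m] = str(exc)

    for m in methods:
        if m.startswith("gPS") and gps is None:
            continue
        try:
            if m == "LR_F":
                results[m] = classify_lrf(cohort, outcomes)
            elif m == "LR_R":
                results[m] = classify_lrr(cohort, outcomes, rule=rule)
            elif m == "gPS_A":
                results[m] = classify_gps_a(cohort, outcomes, gps, rule=rule)
            elif m in ("gPS_W", "gPS_WT"):
                w = ipw_weights(gps, cohort.provider)
                if m == "gPS_WT":
                    w = trim_weights(w, trim_fraction)
                results[m] = classify_weighted(cohort, outcomes, w, m, rule=rule)
            elif m == "gPS_MWS":
                w = mmws_weights(gps, cohort.provider, n_strata)
                results[m] = classify_weighted(cohort, outcomes, w, m, rule=rule)
            else:
                raise ValueError(f"unknown method {m!r}")
        except MethodFailure as exc:
            logger.warning("%s failed: %s", m, exc)
            failures[m] = str(exc)
    return results, failures
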