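"""Weighted random-intercept logistic regression via adaptive quadrature.

This is the estimation engine behind the random-effects profiling methods:
a logistic mixed model

    logit P(y_i = 1 | b) = x_i' beta + b_{g(i)},      b_k ~ N(0, sigma^2),

with optional non-negative per-patient weights that multiply log-likelihood
contributions (the frequency-weight convention of ``lme4::glmer``).  The
marginal likelihood integrates the scalar random intercept per group by
adaptive Gauss-Hermite quadrature: nodes are recentered at the posterior mode
of each group's integrand and rescaled by its curvature, so a modest number of
nodes (default 15) reaches near machine-precision accuracy for the group sizes
used here.

The outer optimization runs L-BFGS-B on (beta, log sigma).  Gradients are
exact gradients of the marginal log-likelihood obtained from Fisher's
identity — the posterior expectation of the complete-data score — evaluated
with the same quadrature nodes, which keeps each objective/gradient evaluation
to a few vectorized passes over the data.

Empirical-Bayes provider effects are the posterior modes of the random
intercepts at the fitted parameters; they are deviations from the fitted
overall intercept and exhibit the usual shrinkage toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class NotConvergedError(RuntimeError):
    """Requested a quantity that requires a converged fit."""


@dataclass
class GLMMFit:
    """Result of a random-intercept logistic fit.

    ``eb`` holds the empirical-Bayes (posterior-mode) random intercepts, one
    per group in the order of ``group_labels``; they are deviations from the
    fitted overall intercept.  ``sigma`` is the random-intercept SD estimate.
    """

    coef: np.ndarray
    coef_se: np.ndarray | None
    sigma: float
    sigma_se: float | None
    eb: np.ndarray
    group_labels: np.ndarray
    loglik: float
    converged: bool
    n_quad: int
    n_iter: int
    message: str

    @property
    def eb_sd(self) -> float:
        """Sample SD of the empirical-Bayes deviations (ddof=1)."""
        return float(np.std(self.eb, ddof=1))


def _irls_logistic(y, X, w, n_iter=25, tol=1e-10):
    """Weighted logistic regression by IRLS (initialization only)."""
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    ridge = 1e-8 * np.eye(p_dim)
    for _ in range(n_iter):
        eta = X @ beta
        mu = expit(eta)
        wt = w * mu * (1 - mu) + 1e-10
        z = eta + (y - mu) / np.maximum(mu * (1 - mu), 1e-10)
        Xw = X * wt[:, None]
        try:
            step = np.linalg.solve(X.T @ Xw + ridge, X.T @ (wt * z)) - beta
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _group_modes(eta, y, w, ginv, K, sigma, b0, starts, n_iter=60, tol=1e-11):
    """Posterior modes and curvatures of the per-group integrands (Newton).

    Observations are pre-sorted by group, so per-group sums reduce to
    ``np.add.reduceat`` over contiguous slices.
    """
    b = b0.copy()
    inv_s2 = 1.0 / sigma**2
    wy = w * y
    for _ in range(n_iter):
        p = expit(eta + b[ginv])
        g1 = np.add.reduceat(wy - w * p, starts) - b * inv_s2
        g2 = np.add.reduceat(w * p * (1 - p), starts) + inv_s2
        step = g1 / g2
        np.clip(step, -4.0, 4.0, out=step)
        b += step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(eta + b[ginv])
    curv = np.add.reduceat(w * p * (1 - p), starts) + inv_s2
    return b, curv


def _agq_pieces(theta, X, y, w, ginv, K, nodes, lognw, b_warm, starts):
    """Shared computation for the AGQ log-likelihood and its gradient."""
    p_dim = X.shape[1]
    beta, sigma = theta[:p_dim], float(np.exp(theta[p_dim]))
    eta = X @ beta
    bhat, curv = _group_modes(eta, y, w, ginv, K, sigma, b_warm, starts)
    tau = 1.0 / np.sqrt(curv)
    B = bhat[None, :] + _SQRT2 * tau[None, :] * nodes[:, None]  # (Q, K)

    E = eta[None, :] + B[:, ginv]  # (Q, N)
    wy = w * y
    G = np.add.reduceat(wy[None, :] * E - w[None, :] * np.logaddexp(0.0, E),
                        starts, axis=1)
    G += -(B**2) / (2.0 * sigma**2) - np.log(sigma) - _LOG_SQRT_2PI

    A = G + lognw[:, None] + (nodes**2)[:, None]
    m = A.max(axis=0)
    S = np.exp(A - m[None, :])
    ssum = S.sum(axis=0)
    ll = float(np.sum(m + np.log(ssum) + np.log(_SQRT2 * tau)))
    rho = S / ssum[None, :]  # posterior node weights per group
    return ll, rho, B, E, bhat, sigma


def _neg_loglik_and_grad(theta, X, y, w, ginv, K, nodes, lognw, state, starts):
    ll, rho, B, E, bhat, sigma = _agq_pieces(
        theta, X, y, w, ginv, K, nodes, lognw, state["b"], starts
    )
    state["b"] = bhat
    # Fisher's identity: score = posterior expectation of complete-data score.
    P = expit(E)
    resid = np.einsum("qn,n->n", rho[:, ginv] * (y[None, :] - P), w)
    gbeta = X.T @ resid
    glogs = float(np.sum(rho * (B**2 / sigma**2 - 1.0)))
    return -ll, -np.append(gbeta, glogs)


def marginal_loglik(y, X, groups, beta, sigma, weights=None, n_quad=15) -> float:
    """Adaptive-quadrature marginal log-likelihood at given parameters.

    Exposed so the integration can be checked against dense-grid oracles.
    """
    y, X, w, ginv, K, _, starts = _prepare(y, X, groups, weights)
    nodes, nw = np.polynomial.hermite.hermgauss(n_quad)
    theta = np.append(np.asarray(beta, dtype=float), np.log(sigma))
    ll, *_ = _agq_pieces(
        theta, X, y, w, ginv, K, nodes, np.log(nw), np.zeros(K), starts
    )
    return ll


def _prepare(y, X, groups, weights):
    """Validate inputs and sort observations by group for contiguous sums."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-d with one row per observation")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights must match y in length")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
    labels, ginv = np.unique(np.asarray(groups), return_inverse=True)
    K = len(labels)
    if len(ginv) != len(y):
        raise ValueError("groups must match y in length")
    wsum = np.bincount(ginv, weights=w, minlength=K)
    if (wsum <= 0).any():
        raise ValueError("every group needs positive total weight")
    order = np.argsort(ginv, kind="stable")
    y, X, w, ginv = y[order], X[order], w[order], ginv[order]
    starts = np.searchsorted(ginv, np.arange(K))
    return y, X, w, ginv, K, labels, starts


def _moment_sigma_init(y, X, w, ginv, K, starts, beta0) -> float:
    """Method-of-moments starting value for the random-intercept SD.

    One-step per-group log-odds deviations around the no-group fit have
    variance sigma^2 + mean sampling variance; solve for sigma.
    """
    p = expit(X @ beta0)
    score = np.add.reduceat(w * (y - p), starts)
    info = np.add.reduceat(w * p * (1 - p), starts)
    info = np.maximum(info, 1e-10)
    delta = score / info
    s2 = np.mean(delta**2) - np.mean(1.0 / info)
    return float(np.sqrt(np.clip(s2, 1e-3, 4.0)))


def fit_random_intercept_logistic(
    y,
    X,
    groups,
    weights=None,
    n_quad: int = 15,
    grad_tol: float = 1e-8,
    max_iter: int = 300,
    sigma_bounds: tuple[float, float] = (1e-4, 10.0),
    compute_se: bool = True,
) -> GLMMFit:
    """Fit the (optionally weighted) random-intercept logistic model.

    Parameters
    ----------
    y, X, groups:
        Binary outcomes, fixed-effect design matrix (include an intercept
        column explicitly) and group labels.
    weights:
        Optional non-negative per-observation weights treated as frequency
        multipliers of log-likelihood contributions.  Rescaling all weights
        by a constant leaves fixed-effect point estimates unchanged but
        shrinks/inflates sigma-hat and standard errors, as with any
        frequency-weight likelihood.
    n_quad:
        Number of adaptive Gauss-Hermite nodes.
    compute_se:
        When true, Wald standard errors come from the numerically
        differentiated observed information at the optimum.

    Deterministic given inputs.  Non-convergence is flagged, not raised.
    """
    y, X, w, ginv, K, labels, starts = _prepare(y, X, groups, weights)
    p_dim = X.shape[1]
    nodes, nw = np.polynomial.hermite.hermgauss(n_quad)
    lognw = np.log(nw)
    state = {"b": np.zeros(K)}

    beta0 = _irls_logistic(y, X, w)
    sigma0 = _moment_sigma_init(y, X, w, ginv, K, starts, beta0)
    sigma0 = float(np.clip(sigma0, sigma_bounds[0] * 2, sigma_bounds[1] / 2))
    x0 = np.append(beta0, np.log(sigma0))
    bounds = [(None, None)] * p_dim + [
        (np.log(sigma_bounds[0]), np.log(sigma_bounds[1]))
    ]
    args = (X, y, w, ginv, K, nodes, lognw, state, starts)
    options = {"maxiter": max_iter, "ftol": 1e-12, "gtol": grad_tol}
    res = minimize(
        _neg_loglik_and_grad, x0, args=args, jac=True,
        method="L-BFGS-B", bounds=bounds, options=options,
    )
    if not res.success:
        # line-search breakdowns occasionally abort L-BFGS-B; restart once
        # from a neutral variance-component value
        state["b"] = np.zeros(K)
        retry = minimize(
            _neg_loglik_and_grad, np.append(beta0, np.log(0.3)), args=args,
            jac=True, method="L-BFGS-B", bounds=bounds, options=options,
        )
        if retry.success or retry.fun < res.fun:
            res = retry

    theta = res.x
    sigma = float(np.exp(theta[p_dim]))
    ll, _, _, _, bhat, _ = _agq_pieces(
        theta, X, y, w, ginv, K, nodes, lognw, state["b"], starts
    )
    converged = bool(res.success) and np.isfinite(ll)

    coef_se = sigma_se = None
    if compute_se and converged:
        H = _numerical_hessian(theta, args)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if (d > 0).all():
                coef_se = np.sqrt(d[:p_dim])
                sigma_se = float(np.sqrt(d[p_dim]) * sigma)  # delta method
        except np.linalg.LinAlgError:
            pass

    return GLMMFit(
        coef=theta[:p_dim].copy(),
        coef_se=coef_se,
        sigma=sigma,
        sigma_se=sigma_se,
        eb=bhat.copy(),
        group_labels=labels,
        loglik=ll,
        converged=converged,
        n_quad=n_quad,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def _numerical_hessian(theta, args, h_scale: float = 1e-5) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    n = len(theta)
    H = np.empty((n, n))
    for j in range(n):
        h = h_scale * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _neg_loglik_and_grad(tp, *args)
        _, gm = _neg_loglik_and_grad(tm, *args)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def empirical_bayes_deviations(fit: GLMMFit) -> np.ndarray:
    """Posterior-mode random intercepts (deviations from the fitted intercept).

    Raises :class:`NotConvergedError` for unconverged fits.
    """
    if not fit.converged:
        raise NotConvergedError(
            f"fit did not converge: {fit.message}"
        )
    return fit.eb.copy()
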