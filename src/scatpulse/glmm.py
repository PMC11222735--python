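"""Random-intercept generalized linear mixed models.

Fits Poisson and logistic GLMMs with a single Gaussian random intercept
by maximum likelihood, integrating the random effect per group with
adaptive Gauss-Hermite quadrature (the integrand is re-centred at its
mode and scaled by its curvature before applying the Hermite rule, so a
modest number of nodes is accurate even for sharp integrands).  Wald
standard errors come from the numerical Hessian of the marginal
log-likelihood at the optimum.  Observation weights enter as frequency
weights multiplying each observation's log-likelihood contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.stats import norm

__all__ = ["GLMMResult", "fit_glmm"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_ETA_CLIP = 30.0


@dataclass
class GLMMResult:
    """Fitted random-intercept GLMM."""

    params: np.ndarray          # fixed-effect estimates
    se: np.ndarray              # Wald standard errors
    sigma: float                # random-intercept SD
    loglik: float
    converged: bool
    names: list[str] = field(default_factory=list)
    n_obs: int = 0
    n_groups: int = 0

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.params - z * self.se,
                                self.params + z * self.se])

    def coef(self, name: str) -> tuple[float, float, float]:
        """(estimate, lo95, hi95) for the named fixed effect."""
        i = self.names.index(name)
        ci = self.conf_int()
        return float(self.params[i]), float(ci[i, 0]), float(ci[i, 1])


def _loglik_obs(y: np.ndarray, eta: np.ndarray, family: str) -> np.ndarray:
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == "poisson":
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)
    # Bernoulli
    return y * eta - np.logaddexp(0.0, eta)


def _mean(eta: np.ndarray, family: str) -> np.ndarray:
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return np.exp(eta) if family == "poisson" else special.expit(eta)


def _variance(eta: np.ndarray, family: str) -> np.ndarray:
    mu = _mean(eta, family)
    return mu if family == "poisson" else mu * (1.0 - mu)


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    family: str = "poisson",
    weights: np.ndarray | None = None,
    n_quad: int = 15,
    names: list[str] | None = None,
) -> GLMMResult:
    """Fit ``g(E[y]) = X beta + u_group``, ``u ~ N(0, sigma^2)``.

    Parameters
    ----------
    y, X, groups
        Response, design matrix (include the intercept column), and a
        group label per observation.
    family
        ``"poisson"`` (log link) or ``"binomial"`` (Bernoulli, logit link).
    weights
        Frequency weights per observation (default all 1).
    """
    if family not in ("poisson", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    _, idx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = int(idx.max()) + 1
    n, p = X.shape

    nodes, ghw = np.polynomial.hermite.hermgauss(n_quad)
    log_ghw = np.log(ghw)

    def group_sum(v: np.ndarray) -> np.ndarray:
        return np.bincount(idx, weights=v, minlength=n_groups)

    def posterior_mode(eta0: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-group mode and curvature of the integrand exponent."""
        u = np.zeros(n_groups)
        for _ in range(60):
            eta = eta0 + sigma * u[idx]
            grad = sigma * group_sum(w * (y - _mean(eta, family))) - u
            hess = -(sigma ** 2) * group_sum(w * _variance(eta, family)) - 1.0
            step = grad / hess
            # Damp large steps to keep exp() in range on the way in.
            step = np.clip(step, -4.0, 4.0)
            u = u - step
            if np.max(np.abs(grad)) < 1e-10:
                break
        eta = eta0 + sigma * u[idx]
        hess = -(sigma ** 2) * group_sum(w * _variance(eta, family)) - 1.0
        return u, hess

    def marginal_loglik(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:p], theta[p]
        sigma = np.exp(log_sigma)
        eta0 = X @ beta
        u_hat, hess = posterior_mode(eta0, sigma)
        tau = 1.0 / np.sqrt(-hess)
        # h_g evaluated at the adapted nodes, (K, G)
        h = np.empty((n_quad, n_groups))
        for k, x_k in enumerate(nodes):
            u_k = u_hat + np.sqrt(2.0) * tau * x_k
            ll = group_sum(w * _loglik_obs(y, eta0 + sigma * u_k[idx], family))
            h[k] = ll - 0.5 * u_k ** 2 - _LOG_SQRT_2PI
        inner = special.logsumexp(h + (log_ghw + nodes ** 2)[:, None], axis=0)
        return float(np.sum(0.5 * np.log(2.0) + np.log(tau) + inner))

    def nll(theta: np.ndarray) -> float:
        val = marginal_loglik(theta)
        return -val if np.isfinite(val) else 1e12

    # Start: intercept at the link-transformed weighted mean, slopes 0.
    beta0 = np.zeros(p)
    ybar = max(np.sum(w * y) / np.sum(w), 1e-3)
    if family == "poisson":
        beta0[0] = np.log(ybar)
    else:
        ybar = min(ybar, 1.0 - 1e-3)
        beta0[0] = np.log(ybar / (1.0 - ybar))
    theta0 = np.append(beta0, np.log(0.3))
    bounds = [(-30.0, 30.0)] * p + [(-6.0, 3.0)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 300, "ftol": 1e-12,
                                     "gtol": 1e-8})
    theta = res.x
    sigma = float(np.exp(theta[p]))

    # Numerical Hessian (central differences) of the negative log-likelihood.
    k = p + 1
    h_step = 1e-4 * np.maximum(1.0, np.abs(theta))
    hess = np.zeros((k, k))
    f0 = nll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h_step[i]
            ej = np.zeros(k); ej[j] = h_step[j]
            if i == j:
                fpp = nll(theta + ei)
                fmm = nll(theta - ei)
                hess[i, i] = (fpp - 2 * f0 + fmm) / h_step[i] ** 2
            else:
                fpp = nll(theta + ei + ej)
                fpm = nll(theta + ei - ej)
                fmp = nll(theta - ei + ej)
                fmm = nll(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * h_step[i] * h_step[j])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, np.inf))
        cov_ok = bool(np.all(np.isfinite(se)))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, np.inf))
        cov_ok = False

    # Flag separation / degenerate fits: estimates at the clip boundary or
    # exploding standard errors.
    degenerate = bool(np.any(np.abs(theta[:p]) > 15.0) or np.any(se > 50.0)
                      or np.any(se == 0.0))
    converged = bool(res.success) and cov_ok and not degenerate
    return GLMMResult(
        params=theta[:p].copy(), se=se, sigma=sigma,
        loglik=float(-res.fun), converged=converged,
        names=list(names) if names else [f"x{i}" for i in range(p)],
        n_obs=n, n_groups=n_groups)
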