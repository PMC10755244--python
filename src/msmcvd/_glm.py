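"""Weighted logistic regression with cluster-robust (sandwich) covariance.

This is the estimation engine behind the IPT treatment models and the
weighted pooled logistic (discrete-time hazard) fits.  Point estimates
maximize the weighted Bernoulli log-likelihood by Newton/IRLS; the
covariance is the person-clustered sandwich estimator

    V = B^{-1} (sum_g s_g s_g') B^{-1} * G/(G-1)

where B is the weighted Fisher information, s_g the summed weighted score
of cluster g, and G the number of clusters.  With estimated IPT weights the
sandwich is conservative, which is the standard choice for MSMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LogitFit", "fit_weighted_logit", "ConvergenceError", "SeparationError"]

PROB_FLOOR = 1e-8


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the step-size trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class SeparationError(RuntimeError):
    """Fitted probabilities hit 0/1: quasi-separation / positivity failure."""


@dataclass
class LogitFit:
    """A fitted (weighted) logistic regression."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray                 # cluster-robust
    cov_model: np.ndarray           # inverse Fisher information
    n_obs: int
    n_clusters: int
    converged: bool
    llf: float
    step_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, dtype=float) @ self.params
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
                "ci_low": self.params - 1.959963984540054 * se,
                "ci_high": self.params + 1.959963984540054 * se,
            },
            index=self.names,
        )


def _wllf(X, y, w, beta):
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    mu = np.clip(mu, PROB_FLOOR, 1 - PROB_FLOOR)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


def _irls(X, y, w, tol, max_iter):
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6)
    # warm start on the intercept-like direction if a constant column exists
    const = np.where(np.ptp(X, axis=0) == 0)[0]
    if const.size:
        beta[const[0]] = np.log(ybar / (1 - ybar)) / X[0, const[0]]
    trace: list[float] = []
    llf = _wllf(X, y, w, beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = w * mu * (1 - mu)
        grad = X.T @ (w * (y - mu))
        info = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # dampen absurd steps (quasi-separation)
        norm_step = float(np.max(np.abs(step)))
        if norm_step > 10.0:
            step *= 10.0 / norm_step
            norm_step = 10.0
        # step-halving keeps the weighted log-likelihood monotone
        new_beta = beta + step
        new_llf = _wllf(X, y, w, new_beta)
        halvings = 0
        while new_llf < llf - 1e-12 and halvings < 20:
            step *= 0.5
            norm_step *= 0.5
            new_beta = beta + step
            new_llf = _wllf(X, y, w, new_beta)
            halvings += 1
        improvement = new_llf - llf
        beta, llf = new_beta, new_llf
        trace.append(norm_step)
        if norm_step < tol:
            return beta, info, trace, True
        # likelihood plateau with a drifting coefficient: a covariate level
        # carries no events and its coefficient walks to -inf; accept the
        # fit once the likelihood is stationary
        if 0 <= improvement < 1e-10 * (abs(llf) + 1.0):
            return beta, info, trace, True
    return beta, info, trace, False


def fit_weighted_logit(
    X,
    y,
    weights=None,
    clusters=None,
    names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    check_separation: bool = False,
) -> LogitFit:
    """Fit a weighted logistic regression with clustered sandwich covariance.

    Parameters
    ----------
    X : (n, p) design matrix (include the constant column yourself).
    y : binary response in {0, 1}.
    weights : observation weights (IPT weights); default all ones.
    clusters : cluster labels (person ids) for the sandwich; default each
        observation its own cluster (HC0-type robust covariance).
    check_separation : raise :class:`SeparationError` if any fitted
        probability is numerically 0 or 1 (used by the positivity screen).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    beta, info, trace, converged = _irls(X, y, w, tol, max_iter)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    separated = bool(np.any(mu <= PROB_FLOOR) | np.any(mu >= 1 - PROB_FLOOR))
    if not converged and not (check_separation and separated):
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last step {trace[-1]:.3e})",
            trace,
        )
    if check_separation and separated:
        bad = int(np.argmax((mu <= PROB_FLOOR) | (mu >= 1 - PROB_FLOOR)))
        raise SeparationError(
            "fitted probability numerically 0 or 1 at row "
            f"{bad}; covariate pattern: "
            + ", ".join(f"{nm}={v:g}" for nm, v in zip(names, X[bad]))
        )
    score = X * (w * (y - mu))[:, None]
    if clusters is None:
        meat = score.T @ score
        n_clusters = n
        corr = n / max(n - 1, 1)
    else:
        codes, _ = pd.factorize(np.asarray(clusters), sort=False)
        n_clusters = int(codes.max()) + 1
        grouped = np.zeros((n_clusters, p))
        np.add.at(grouped, codes, score)
        meat = grouped.T @ grouped
        corr = n_clusters / max(n_clusters - 1, 1)
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(info)
    cov = corr * bread @ meat @ bread
    mu_c = np.clip(mu, PROB_FLOOR, 1 - PROB_FLOOR)
    llf = float(np.sum(w * (y * np.log(mu_c) + (1 - y) * np.log1p(-mu_c))))
    return LogitFit(
        names=list(names),
        params=beta,
        cov=cov,
        cov_model=bread,
        n_obs=n,
        n_clusters=n_clusters,
        converged=converged,
        llf=llf,
        step_trace=trace,
    )
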