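"""Random-intercept linear mixed models via profiled (RE)ML.

A single grouping factor with an i.i.d. Gaussian intercept per group:

    y = X @ beta + u[g] + eps,   u[g] ~ N(0, sigma_u^2),  eps ~ N(0, sigma_e^2).

The variance ratio gamma = sigma_u^2 / sigma_e^2 is profiled out: for fixed
gamma the GLS solution and the error variance have closed forms built from
per-group sufficient statistics, so each likelihood evaluation is O(n p^2)
with no per-group linear algebra.  This is the workhorse behind both the
measurement-error model (person intercept over recall days) and the outcome
models (family intercept over siblings); it has to be fast because the
imputation loop refits the outcome model hundreds of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy import optimize

__all__ = ["LMMFit", "fit_random_intercept"]

_LOG_GAMMA_LO = -12.0
_LOG_GAMMA_HI = 8.0


@dataclass
class LMMFit:
    """Result of a random-intercept LMM fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    loglik: float
    reml: bool
    n_obs: int
    n_groups: int
    colnames: list[str] = field(default_factory=list)
    converged: bool = True
    # per-group shrinkage material, kept for BLUPs
    group_labels: np.ndarray | None = None
    blups: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def gamma(self) -> float:
        return self.sigma_u2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf

    def coef(self, name: str) -> float:
        return float(self.beta[self.colnames.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.colnames.index(name)])


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Sort by group and return per-group sums plus global cross products."""
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    # start index of each group block
    starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
    sizes = np.diff(np.r_[starts, len(gs)])
    S = np.add.reduceat(Xs, starts, axis=0)        # (G, p) group sums of X
    ssy = np.add.reduceat(ys, starts)              # (G,) group sums of y
    XtX = Xs.T @ Xs
    Xty = Xs.T @ ys
    yty = float(ys @ ys)
    labels = gs[starts]
    return Xs, ys, labels, starts, sizes, S, ssy, XtX, Xty, yty


def fit_random_intercept(
    y,
    X,
    groups,
    reml: bool = True,
    colnames: list[str] | None = None,
) -> LMMFit:
    """Fit ``y = X beta + u[group] + eps`` by profiled (RE)ML.

    Parameters
    ----------
    y, X, groups
        Response (n,), design matrix (n, p) including an intercept column,
        and group labels (n,) of any sortable dtype.
    reml
        Restricted maximum likelihood if True (the default, used for
        reported estimates); plain ML otherwise (used for information
        criteria in subset selection and for Box-Cox profiling).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or X.ndim != 2 or len(y) != len(X) or len(groups) != len(y):
        raise ValueError("y, X and groups must have matching first dimension")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("NaN in model inputs")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")

    (_, _, labels, _, sizes, S, ssy, XtX, Xty, yty) = _group_stats(X, y, groups)

    def profile(gamma: float):
        # c_i = gamma / (1 + gamma * n_i); A_i = I - c_i * J
        c = gamma / (1.0 + gamma * sizes)
        XtAX = XtX - (S * c[:, None]).T @ S
        XtAy = Xty - S.T @ (c * ssy)
        ytAy = yty - float(c @ ssy**2)
        try:
            beta = np.linalg.solve(XtAX, XtAy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtAX, XtAy, rcond=None)[0]
        rss = ytAy - 2.0 * beta @ XtAy + beta @ XtAX @ beta
        rss = max(rss, 1e-300)
        logdet_v = float(np.log1p(gamma * sizes).sum())
        if reml:
            sig2 = rss / (n - p)
            sign, logdet_x = np.linalg.slogdet(XtAX)
            crit = (n - p) * np.log(sig2) + logdet_v + logdet_x
        else:
            sig2 = rss / n
            crit = n * np.log(sig2) + logdet_v
        return crit, beta, sig2, XtAX

    def crit_of_log_gamma(t: float) -> float:
        return profile(np.exp(t))[0]

    with warnings.catch_warnings():
        # flat profiles near the boundary trip benign RuntimeWarnings in brent
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize_scalar(
            crit_of_log_gamma, bounds=(_LOG_GAMMA_LO, _LOG_GAMMA_HI), method="bounded",
            options={"xatol": 1e-8},
        )
    gamma = float(np.exp(res.x))
    crit, beta, sig2, XtAX = profile(gamma)
    # boundary check: a pure fixed-effects fit may beat the interior optimum
    crit0, beta0, sig20, XtAX0 = profile(0.0)
    if crit0 <= crit:
        gamma, crit, beta, sig2, XtAX = 0.0, crit0, beta0, sig20, XtAX0

    sigma_e2 = float(sig2)
    sigma_u2 = float(gamma * sigma_e2)
    dof = n - p if reml else n
    loglik = -0.5 * (crit + dof * (1.0 + np.log(2.0 * np.pi)))
    try:
        cov_beta = sigma_e2 * np.linalg.inv(XtAX)
    except np.linalg.LinAlgError:
        cov_beta = sigma_e2 * np.linalg.pinv(XtAX)

    # BLUPs: u_i = gamma/(1 + gamma n_i) * (summed residual of group i)
    resid_sum = ssy - S @ beta
    blups = gamma * resid_sum / (1.0 + gamma * sizes) if gamma > 0 else np.zeros_like(resid_sum)

    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        loglik=float(loglik),
        reml=reml,
        n_obs=n,
        n_groups=len(sizes),
        colnames=list(colnames) if colnames is not None else [f"x{j}" for j in range(p)],
        converged=bool(res.success),
        group_labels=labels,
        blups=blups,
    )
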