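"""Usual-intake estimation from repeated error-prone daily exposures.

Stage 1 of the three-stage analysis.  Each daily variable is modelled
univariately on a Box-Cox transformed scale with a person random intercept
and fixed effects for sex, weekend, age, parental education and BMI z-score
(sex enters through interactions, equivalent to sex-stratified fits with
shared machinery).  The fitted model supports two read-outs:

* regression calibration (``predict_usual_rc``): the shrunken person effect
  (BLUP) back-transformed with a second-order bias correction for the
  within-day error, weighted 5/7 weekday + 2/7 weekend;
* conditional random draws (``draw_usual_mi``): person effects sampled from
  their Gaussian posterior given the person's reports — the imputation
  variant, fitted with the outcome z-score as an extra covariate.

Energy proportions are never modelled directly: morning/evening window
energies and total energy are each given their own error model and the usual
proportion is the ratio of usual window energy to usual total energy, times
100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import fit_random_intercept
from .recall_processing import EXPOSURE_NAMES

__all__ = [
    "ErrorModelFit",
    "MODELED_VARS",
    "DEFAULT_LAMBDA_GRID",
    "fit_error_model",
    "predict_usual_rc",
    "draw_usual_mi",
    "usual_energy_proportion",
    "usual_exposures_table",
]

#: daily variables that get their own error model (proportions are derived)
MODELED_VARS = [
    "morning_kcal",
    "evening_kcal",
    "total_kcal",
    "healthy_kcal",
    "eating_window_h",
    "presleep_fasting_h",
    "eating_frequency",
]

DEFAULT_LAMBDA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)

_WD_WEIGHT, _WE_WEIGHT = 5.0 / 7.0, 2.0 / 7.0


def _boxcox(x: np.ndarray, lam: float, shift: float) -> np.ndarray:
    xs = x + shift
    if lam == 0.0:
        return np.log(xs)
    return (np.power(xs, lam) - 1.0) / lam


def _boxcox_inv(eta: np.ndarray, lam: float, shift: float) -> np.ndarray:
    if lam == 0.0:
        return np.exp(eta) - shift
    base = np.clip(lam * eta + 1.0, 1e-12, None)
    return np.power(base, 1.0 / lam) - shift


def _boxcox_inv_dd(eta: np.ndarray, lam: float) -> np.ndarray:
    """Second derivative of the inverse transform (for bias correction)."""
    if lam == 0.0:
        return np.exp(eta)
    if lam == 1.0:
        return np.zeros_like(np.asarray(eta, dtype=float))
    base = np.clip(lam * eta + 1.0, 1e-12, None)
    return (1.0 - lam) * np.power(base, 1.0 / lam - 2.0)


@dataclass
class _PersonCache:
    ids: np.ndarray          # unique participant ids, sorted
    n_days: np.ndarray       # recalls per person
    mean_resid: np.ndarray   # mean transformed-scale residual per person
    X_wd: np.ndarray         # covariate profile, weekend = 0
    X_we: np.ndarray         # covariate profile, weekend = 1


@dataclass
class ErrorModelFit:
    """Fitted Stage-1 error model for one daily variable."""

    var: str
    lam: float
    shift: float
    beta: np.ndarray
    colnames: list[str]
    sigma_u2: float
    sigma_e2: float
    loglik: float
    n_obs: int
    n_persons: int
    include_outcome: bool
    converged: bool
    cache: _PersonCache = field(repr=False, default=None)


def _design(df: pd.DataFrame, include_outcome: bool):
    """Fixed-effect design: main effects plus sex-by-covariate interactions."""
    female = (df["sex"].to_numpy() == "F").astype(float)
    base = {
        "weekend": df["weekend"].to_numpy(dtype=float),
        "age_c": df["age"].to_numpy(dtype=float) - 12.0,
        "isced_high": (df["isced"].to_numpy() == "high").astype(float),
        "bmi_z": df["bmi_z"].to_numpy(dtype=float),
    }
    if include_outcome:
        base["outcome_z"] = df["outcome_z"].to_numpy(dtype=float)
    cols = [np.ones(len(df)), female] + list(base.values())
    names = ["intercept", "female"] + list(base)
    for k, v in base.items():
        cols.append(female * v)
        names.append(f"female:{k}")
    return np.column_stack(cols), names


def _merged_days(daily, covariates, include_outcome, outcome):
    cov_cols = ["participant_id", "sex", "age", "isced", "bmi_z"]
    df = daily.merge(covariates[cov_cols], on="participant_id", how="left", validate="m:1")
    if df["sex"].isna().any():
        raise ValueError("some recall days lack participant covariates")
    if include_outcome:
        if outcome is None:
            raise ValueError("include_outcome=True requires an outcome series")
        out = pd.Series(np.asarray(outcome.values, dtype=float), index=outcome.index)
        df["outcome_z"] = out.reindex(df["participant_id"]).to_numpy()
        if np.isnan(df["outcome_z"]).any():
            raise ValueError("outcome z-score missing for some participants")
    return df.sort_values(["participant_id", "day_index"], kind="stable").reset_index(drop=True)


def _build_cache(df, fit_beta, lam, shift, colnames, var, include_outcome):
    y_t = _boxcox(df[var].to_numpy(dtype=float), lam, shift)
    X, _ = _design(df, include_outcome)
    resid = y_t - X @ fit_beta
    pid = df["participant_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
    n_days = np.diff(np.r_[starts, len(pid)])
    mean_resid = np.add.reduceat(resid, starts) / n_days
    # person-level profiles: one row per person at weekend = 0 and 1
    prof = df.iloc[starts].copy()
    prof_wd = prof.copy()
    prof_wd["weekend"] = 0.0
    prof_we = prof.copy()
    prof_we["weekend"] = 1.0
    X_wd, _ = _design(prof_wd, include_outcome)
    X_we, _ = _design(prof_we, include_outcome)
    return _PersonCache(pid[starts], n_days, mean_resid, X_wd, X_we)


def fit_error_model(
    daily: pd.DataFrame,
    covariates: pd.DataFrame,
    var: str,
    include_outcome: bool = False,
    outcome: pd.Series | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> ErrorModelFit:
    """Fit the transformed random-intercept error model for one variable.

    The Box-Cox parameter is chosen on a grid by profile (ML) likelihood with
    the Jacobian term, ties broken toward lambda = 1 (less transformation);
    the winning model is refitted by REML.  Requires at least two
    participants with two or more recall days, otherwise the within-person
    variance is unidentifiable.
    """
    if var not in daily.columns:
        raise ValueError(f"daily table has no column {var!r}")
    df = _merged_days(daily, covariates, include_outcome, outcome)
    df = df[np.isfinite(df[var].to_numpy(dtype=float))].reset_index(drop=True)
    counts = df.groupby("participant_id", sort=False).size()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            "need >= 2 participants with >= 2 recall days to identify "
            "the within-person variance"
        )
    y = df[var].to_numpy(dtype=float)
    needs_positive = any(l < 1.0 for l in lambda_grid)
    shift = float(max(0.0, 1e-6 - y.min())) if needs_positive else 0.0
    X, names = _design(df, include_outcome)
    groups = df["participant_id"].to_numpy()

    best = None
    log_y = np.log(y + shift) if needs_positive else None
    for lam in sorted(lambda_grid):
        y_t = _boxcox(y, lam, shift)
        fit = fit_random_intercept(y_t, X, groups, reml=False, colnames=names)
        jac = 0.0 if lam == 1.0 and shift == 0.0 else float((lam - 1.0) * np.sum(np.log(y + shift)))
        ll = fit.loglik + jac
        if best is None or ll >= best[0] - 1e-9:
            best = (ll, lam)
    lam = best[1]

    y_t = _boxcox(y, lam, shift)
    fit = fit_random_intercept(y_t, X, groups, reml=True, colnames=names)
    if not fit.converged:
        raise RuntimeError(f"error model for {var!r} did not converge")
    cache = _build_cache(df, fit.beta, lam, shift, names, var, include_outcome)
    return ErrorModelFit(
        var=var,
        lam=lam,
        shift=shift,
        beta=fit.beta,
        colnames=names,
        sigma_u2=fit.sigma_u2,
        sigma_e2=fit.sigma_e2,
        loglik=fit.loglik,
        n_obs=len(df),
        n_persons=len(counts),
        include_outcome=include_outcome,
        converged=True,
        cache=cache,
    )


def _person_effects(fit: ErrorModelFit):
    """(BLUP, posterior variance) of the person effect, per person."""
    c = fit.cache
    if fit.sigma_u2 <= 1e-12:
        return np.zeros(len(c.ids)), np.zeros(len(c.ids))
    if fit.sigma_e2 <= 1e-12:
        return c.mean_resid.copy(), np.zeros(len(c.ids))
    shrink = fit.sigma_u2 / (fit.sigma_u2 + fit.sigma_e2 / c.n_days)
    blup = shrink * c.mean_resid
    post_var = 1.0 / (1.0 / fit.sigma_u2 + c.n_days / fit.sigma_e2)
    return blup, post_var


def _usual_from_effects(fit: ErrorModelFit, u: np.ndarray) -> np.ndarray:
    """Weekday/weekend-weighted back-transform with 2nd-order bias correction."""
    c = fit.cache
    eta_wd = c.X_wd @ fit.beta + u
    eta_we = c.X_we @ fit.beta + u
    corr = 0.5 * fit.sigma_e2
    val_wd = _boxcox_inv(eta_wd, fit.lam, fit.shift) + corr * _boxcox_inv_dd(eta_wd, fit.lam)
    val_we = _boxcox_inv(eta_we, fit.lam, fit.shift) + corr * _boxcox_inv_dd(eta_we, fit.lam)
    return _WD_WEIGHT * val_wd + _WE_WEIGHT * val_we


def predict_usual_rc(fit: ErrorModelFit) -> pd.Series:
    """Regression-calibration usual values, indexed by participant id."""
    blup, _ = _person_effects(fit)
    return pd.Series(_usual_from_effects(fit, blup), index=fit.cache.ids, name=fit.var)


def draw_usual_mi(fit: ErrorModelFit, rng: np.random.Generator, z: np.ndarray | None = None) -> pd.Series:
    """One conditional draw of usual values (the imputation read-out).

    The person effect is sampled from N(BLUP, (1/sigma_u^2 + n/sigma_e^2)^-1).
    ``z`` optionally supplies pre-drawn standard normals (for copula use).
    """
    if not fit.include_outcome:
        raise ValueError("draw_usual_mi requires an outcome-conditioned fit")
    blup, post_var = _person_effects(fit)
    if z is None:
        z = rng.standard_normal(len(blup))
    u = blup + np.sqrt(post_var) * z
    return pd.Series(_usual_from_effects(fit, u), index=fit.cache.ids, name=fit.var)


def usual_energy_proportion(window_kcal, total_kcal):
    """Usual window-energy percentage: 100 * usual window EI / usual total EI."""
    window = np.asarray(window_kcal, dtype=float)
    total = np.asarray(total_kcal, dtype=float)
    if np.any(total <= 0):
        raise ValueError("usual total energy must be positive")
    pct = 100.0 * window / total
    return float(pct) if pct.ndim == 0 else pct


def _assemble(vals: dict[str, pd.Series], provenance: str, draw_index=None) -> pd.DataFrame:
    ids = vals["total_kcal"].index
    morning = usual_energy_proportion(vals["morning_kcal"].to_numpy(), vals["total_kcal"].to_numpy())
    evening = usual_energy_proportion(vals["evening_kcal"].to_numpy(), vals["total_kcal"].to_numpy())
    out = pd.DataFrame(
        {
            "participant_id": np.asarray(ids),
            "morning_pct": np.clip(morning, 0.0, 100.0),
            "evening_pct": np.clip(evening, 0.0, 100.0),
            "eating_window_h": np.clip(vals["eating_window_h"].to_numpy(), 1e-6, None),
            "presleep_fasting_h": np.clip(vals["presleep_fasting_h"].to_numpy(), 0.0, None),
            "eating_frequency": np.clip(vals["eating_frequency"].to_numpy(), 1e-6, None),
            "total_kcal": vals["total_kcal"].to_numpy(),
            "healthy_kcal": vals["healthy_kcal"].to_numpy(),
            "provenance": provenance,
        }
    )
    if draw_index is not None:
        out["draw_index"] = draw_index
    return out


def fit_all_error_models(
    daily, covariates, include_outcome=False, outcome=None, lambda_grid=DEFAULT_LAMBDA_GRID
) -> dict[str, ErrorModelFit]:
    return {
        v: fit_error_model(daily, covariates, v, include_outcome, outcome, lambda_grid)
        for v in MODELED_VARS
    }


def usual_exposures_table(
    daily: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "rc",
    outcome: pd.Series | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_draws: int = 1,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    fits: dict[str, ErrorModelFit] | None = None,
) -> pd.DataFrame:
    """Usual exposures for every participant, by RC prediction or MI draws.

    ``mode='rc'`` returns one row per participant; ``mode='mi'`` returns
    ``n_draws`` stacked draws (column ``draw_index``) from outcome-conditioned
    fits.  Pre-computed ``fits`` can be supplied to amortise Stage-1 cost
    across many draws.
    """
    if mode not in ("rc", "mi"):
        raise ValueError("mode must be 'rc' or 'mi'")
    include_outcome = mode == "mi"
    if fits is None:
        fits = fit_all_error_models(daily, covariates, include_outcome, outcome, lambda_grid)
    if mode == "rc":
        vals = {v: predict_usual_rc(f) for v, f in fits.items()}
        return _assemble(vals, "regression_calibration")
    if rng is None:
        rng = np.random.default_rng(seed)
    frames = []
    for m in range(n_draws):
        vals = {v: draw_usual_mi(f, rng) for v, f in fits.items()}
        frames.append(_assemble(vals, "mi_draw", draw_index=m))
    return pd.concat(frames, ignore_index=True)
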