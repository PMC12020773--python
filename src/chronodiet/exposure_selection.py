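"""Single-exposure analysis: exhaustive best-subset selection + bootstrap CIs.

All 2^5 - 1 non-empty subsets of the five usual exposures are fitted (on
natural units, so coefficients read per-hour / per-percent) with the basic
covariates always included and a family random intercept; subsets are ranked
by an information criterion on ML fits and the winner is refitted by REML.
Confidence intervals come from a cluster (family-level) bootstrap so the
random-effect structure survives resampling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import fit_random_intercept
from .recall_processing import EXPOSURE_NAMES

__all__ = ["SubsetResult", "best_subset", "bootstrap_ci"]


@dataclass
class SubsetResult:
    selected: list[str]
    betas: dict[str, float]
    ses: dict[str, float]
    criterion: str
    criterion_value: float
    all_criteria: dict[tuple, float] = field(default_factory=dict)
    cis: dict[str, tuple[float, float]] | None = None
    n_bootstrap: int = 0


def _design(data: pd.DataFrame, exposures: list[str], covariate_cols: list[str]):
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for e in exposures:
        cols.append(data[e].to_numpy(dtype=float))
        names.append(e)
    for c in covariate_cols:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def _basic_covariate_cols(data: pd.DataFrame) -> list[str]:
    """Materialise the basic adjustment set as numeric columns (in place)."""
    cols = []
    if "age_c" not in data:
        data["age_c"] = data["age"].astype(float) - 12.0
    cols.append("age_c")
    cols.append("bmi_z")
    if "isced_high" not in data:
        data["isced_high"] = (data["isced"] == "high").astype(float)
    cols.append("isced_high")
    if "female" not in data:
        data["female"] = (data["sex"] == "F").astype(float)
    cols.append("female")
    for c in sorted(pd.unique(data["country"]))[1:]:
        name = f"country_{c}"
        if name not in data:
            data[name] = (data["country"] == c).astype(float)
        cols.append(name)
    for extra in ("usual_total_kcal", "usual_healthy_kcal", "sleep_h"):
        if extra in data.columns:
            cols.append(extra)
    return cols


def _criterion_value(fit, criterion: str) -> float:
    # parameters: fixed effects + two variance components
    n_par = len(fit.beta) + 2
    if criterion == "bic":
        return -2.0 * fit.loglik + n_par * np.log(fit.n_obs)
    if criterion == "aic":
        return -2.0 * fit.loglik + 2.0 * n_par
    raise ValueError(f"unknown criterion {criterion!r}")


def best_subset(
    data: pd.DataFrame,
    outcome_col: str,
    exposures: list[str] | None = None,
    criterion: str = "bic",
    group_col: str = "family_id",
) -> SubsetResult:
    """Exhaustive subset search over the exposures with covariates fixed.

    ``data`` holds one row per participant with the outcome z-score, the
    usual exposures on natural units, the basic covariates and the family id.
    Rank-deficient subsets are skipped with a warning.
    """
    exposures = list(EXPOSURE_NAMES) if exposures is None else list(exposures)
    if not exposures:
        raise ValueError("need at least one candidate exposure")
    data = data.copy()
    cov_cols = _basic_covariate_cols(data)
    y = data[outcome_col].to_numpy(dtype=float)
    groups = data[group_col].to_numpy()

    all_criteria: dict[tuple, float] = {}
    best_key, best_val = None, np.inf
    for r in range(1, len(exposures) + 1):
        for subset in itertools.combinations(exposures, r):
            X, names = _design(data, list(subset), cov_cols)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                warnings.warn(f"rank-deficient design for subset {subset}; skipped")
                continue
            fit = fit_random_intercept(y, X, groups, reml=False, colnames=names)
            val = _criterion_value(fit, criterion)
            all_criteria[subset] = val
            if val < best_val:
                best_key, best_val = subset, val
    if best_key is None:
        raise RuntimeError("no subset could be fitted")

    X, names = _design(data, list(best_key), cov_cols)
    refit = fit_random_intercept(y, X, groups, reml=True, colnames=names)
    betas = {e: refit.coef(e) for e in best_key}
    ses = {e: refit.coef_se(e) for e in best_key}
    return SubsetResult(
        selected=list(best_key),
        betas=betas,
        ses=ses,
        criterion=criterion,
        criterion_value=best_val,
        all_criteria=all_criteria,
    )


def bootstrap_ci(
    data: pd.DataFrame,
    outcome_col: str,
    selected: list[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    group_col: str = "family_id",
    resample: str = "family",
    max_failure_rate: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% CIs for the selected coefficients.

    Families (default) or individuals are resampled with replacement; each
    replicate refits the selected model by REML.  Resampled families get
    fresh group labels so a family drawn twice contributes two independent
    random intercepts.
    """
    if resample not in ("family", "individual"):
        raise ValueError("resample must be 'family' or 'individual'")
    data = data.copy().reset_index(drop=True)
    cov_cols = _basic_covariate_cols(data)
    rng = np.random.default_rng(seed)

    if resample == "family":
        fam = data[group_col].to_numpy()
        uniq = pd.unique(fam)
        members: dict = {f: np.flatnonzero(fam == f) for f in uniq}
    n = len(data)

    draws: dict[str, list[float]] = {e: [] for e in selected}
    failed = 0
    for b in range(n_bootstrap):
        if resample == "family":
            fams = rng.choice(len(uniq), size=len(uniq), replace=True)
            idx = np.concatenate([members[uniq[f]] for f in fams])
            groups = np.repeat(
                np.arange(len(fams)), [len(members[uniq[f]]) for f in fams]
            )
        else:
            idx = rng.choice(n, size=n, replace=True)
            groups = np.arange(n)
        boot = data.iloc[idx]
        X, names = _design(boot, selected, cov_cols)
        y = boot[outcome_col].to_numpy(dtype=float)
        try:
            fit = fit_random_intercept(y, X, groups, reml=True, colnames=names)
            for e in selected:
                draws[e].append(fit.coef(e))
        except Exception as exc:  # noqa: BLE001
            failed += 1
            if failed > max_failure_rate * n_bootstrap:
                raise RuntimeError(
                    f"{failed} bootstrap refits failed (> {max_failure_rate:.0%})"
                ) from exc
    return {
        e: (
            float(np.percentile(draws[e], 2.5)),
            float(np.percentile(draws[e], 97.5)),
        )
        for e in selected
    }
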