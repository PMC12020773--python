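"""Stage 3 and the imputation loop: outcome models pooled by Rubin's rule.

Linear mixed models of outcome z-scores on meal-timing pattern membership
(versus the "early-often" reference) and covariates, with a family random
intercept for the sibling structure.  ``run_three_stage`` wires the whole
correction together: Stage-1 outcome-conditioned error models supply random
usual-exposure draws, each draw is classified with the frozen Stage-2 model,
the outcome model is refitted, and the M per-imputation estimates are pooled
with Rubin's rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMFit, fit_random_intercept
from . import mtp_clustering
from . import usual_exposure_model as uem
from .recall_processing import EXPOSURE_NAMES

__all__ = [
    "ModelSpec",
    "MIResult",
    "COVARIATE_SETS",
    "standardize_outcome",
    "compute_homa_ir",
    "fit_lmm",
    "rubins_rule",
    "run_three_stage",
    "run_naive",
]

COVARIATE_SETS = ("basic", "puberty", "energy_hfi", "fully_adjusted")
REFERENCE_PATTERN = "early-often"
MTP_CONTRASTS = ("late-long", "late-infrequent-short")

HOMA_CONSTANT = 22.5


@dataclass
class ModelSpec:
    outcome: str = "homa_ir_z"
    covariate_set: str = "basic"
    reference: str = REFERENCE_PATTERN
    group_col: str = "family_id"

    def __post_init__(self) -> None:
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"covariate_set must be one of {COVARIATE_SETS}")


@dataclass
class MIResult:
    """Rubin-pooled contrast: point estimate, variance split and 95% CI."""

    contrast: str
    beta: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def standardize_outcome(values, age, sex, degree: int = 2) -> np.ndarray:
    """Sex-specific, age-detrended z-scores.

    Within each sex the values are residualised on a low-order polynomial in
    age and scaled by the residual SD — a simplified stand-in for reference-
    curve standardisation.  Requires >= 30 observations per sex.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    z = np.full(len(values), np.nan)
    for s in np.unique(sex):
        m = sex == s
        if m.sum() < 30:
            raise ValueError(f"need >= 30 observations per sex (got {m.sum()} for {s!r})")
        coefs = np.polyfit(age[m], values[m], deg=degree)
        resid = values[m] - np.polyval(coefs, age[m])
        sd = resid.std(ddof=1)
        if sd <= 0:
            raise ValueError("outcome has zero residual variance")
        z[m] = resid / sd
    return z


def compute_homa_ir(glucose_mmol_l, insulin_uu_ml, constant: float = HOMA_CONSTANT):
    """HOMA-IR = insulin (uU/mL) * glucose (mmol/L) / 22.5."""
    g = np.asarray(glucose_mmol_l, dtype=float)
    i = np.asarray(insulin_uu_ml, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("glucose and insulin must be positive")
    out = i * g / constant
    return float(out) if out.ndim == 0 else out


def _outcome_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the outcome model: MTP dummies + covariate set."""
    patterns = [p for p in pd.unique(data["mtp"]) if p != spec.reference]
    if len(patterns) + 1 != data["mtp"].nunique():
        raise ValueError(f"reference pattern {spec.reference!r} absent from labels")
    patterns = sorted(patterns)
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for p in patterns:
        cols.append((data["mtp"].to_numpy() == p).astype(float))
        names.append(f"mtp:{p}")
    cols += [
        data["age"].to_numpy(dtype=float) - 12.0,
        data["bmi_z"].to_numpy(dtype=float),
        (data["isced"].to_numpy() == "high").astype(float),
        (data["sex"].to_numpy() == "F").astype(float),
    ]
    names += ["age_c", "bmi_z", "isced_high", "female"]
    countries = sorted(pd.unique(data["country"]))[1:]
    for c in countries:
        cols.append((data["country"].to_numpy() == c).astype(float))
        names.append(f"country:{c}")
    if spec.covariate_set == "puberty":
        cols.append(data["puberty"].to_numpy(dtype=float))
        names.append("puberty")
    if spec.covariate_set in ("energy_hfi", "fully_adjusted"):
        cols.append(data["usual_total_kcal"].to_numpy(dtype=float) / 100.0)
        names.append("usual_total_kcal_100")
        cols.append(data["usual_healthy_kcal"].to_numpy(dtype=float) / 100.0)
        names.append("usual_healthy_kcal_100")
    if spec.covariate_set == "fully_adjusted":
        cols.append(data["sleep_h"].to_numpy(dtype=float))
        names.append("sleep_h")
    return np.column_stack(cols), names


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> tuple[dict, LMMFit]:
    """Outcome LMM with family random intercept; returns MTP contrasts.

    ``data`` needs columns: the outcome, ``mtp``, the covariates of the
    requested set, and the family grouping column.  A singular family
    variance falls back to zero (ordinary least squares) inside the solver.
    """
    y = data[spec.outcome].to_numpy(dtype=float)
    X, names = _outcome_design(data, spec)
    fit = fit_random_intercept(y, X, data[spec.group_col].to_numpy(), reml=True, colnames=names)
    contrasts = {
        n.split("mtp:", 1)[1]: (fit.coef(n), fit.coef_se(n))
        for n in names
        if n.startswith("mtp:")
    }
    return contrasts, fit


def rubins_rule(estimates, variances) -> MIResult:
    """Pool M point estimates and their squared SEs by Rubin's rule.

    beta = mean estimate; W = mean variance; B = between-imputation variance;
    T = W + (1 + 1/M) B; df = (M-1) (1 + W / ((1 + 1/M) B))^2; the 95% CI is
    beta +/- t_{df, 0.975} sqrt(T) (normal quantile when B = 0).
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(est)
    if m < 1:
        raise ValueError("need at least one estimate")
    if m == 1:
        warnings.warn("Rubin pooling with M=1: returning the single fit")
        beta, w = float(est[0]), float(var[0])
        half = stats.norm.ppf(0.975) * np.sqrt(w)
        return MIResult("", beta, w, 0.0, w, np.inf, beta - half, beta + half, 1)
    beta = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1))
    t_var = w + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", over="ignore"):
        rel = np.float64(w) / ((1.0 + 1.0 / m) * np.float64(b)) if b > 0 else np.inf
        df = float((m - 1) * np.square(1.0 + rel))
    if np.isfinite(df) and df < 1e12:
        q = stats.t.ppf(0.975, df)
    else:
        df = np.inf
        q = stats.norm.ppf(0.975)
    half = q * np.sqrt(t_var)
    return MIResult("", beta, w, b, t_var, float(df), beta - half, beta + half, m)


def _participant_plausibility(daily: pd.DataFrame) -> pd.Series:
    """Participant-level misreporter flag: > half of retained days flagged."""
    flagged = daily["plausibility"].eq("misreporter").groupby(daily["participant_id"]).mean()
    return flagged > 0.5


def _analysis_frame(usual, covariates, outcomes, model, spec):
    data = covariates.merge(outcomes, on="participant_id").merge(
        usual[["participant_id", "total_kcal", "healthy_kcal"] + EXPOSURE_NAMES],
        on="participant_id",
    )
    data = data.rename(
        columns={"total_kcal": "usual_total_kcal", "healthy_kcal": "usual_healthy_kcal"}
    )
    data["mtp"] = mtp_clustering.assign(model, data)
    if spec.covariate_set == "fully_adjusted" and "sleep_h" not in data.columns:
        from .recall_processing import compute_sleep_duration

        data["sleep_h"] = [
            compute_sleep_duration((we, nwe, wd, nwd))
            for we, nwe, wd, nwd in zip(
                data["sleep_noct_we"], data["sleep_nap_we"],
                data["sleep_noct_wd"], data["sleep_nap_wd"],
            )
        ]
    return data


@dataclass
class ThreeStageResult:
    results: dict[str, MIResult]
    mtp_model: mtp_clustering.MTPModel
    rc_usual: pd.DataFrame
    m_completed: int
    m_failed: int
    stage2_shares: dict[str, float] = field(default_factory=dict)


def run_three_stage(
    daily: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    spec: ModelSpec,
    m_imputations: int = 500,
    seed: int = 0,
    k: int = 3,
    n_starts: int = 25,
    lambda_grid=uem.DEFAULT_LAMBDA_GRID,
    plausible_only: bool = False,
    max_failure_rate: float = 0.05,
) -> ThreeStageResult:
    """The full misclassification-corrected association analysis.

    Stage 1 fits regression-calibration error models, Stage 2 freezes a
    k-means pattern model on the RC usual exposures, then M times: draw usual
    exposures from the outcome-conditioned Stage-1 fits, classify with the
    frozen Stage-2 model, refit the outcome LMM, and finally pool the
    contrast estimates with Rubin's rule.

    Days flagged ``excluded_low_energy`` are dropped up front; with
    ``plausible_only`` participants classified as misreporters (majority of
    days flagged) are dropped as well.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    if "plausibility" in daily.columns:
        daily = daily[daily["plausibility"] != "excluded_low_energy"]
        if plausible_only:
            mis = _participant_plausibility(daily)
            keep = mis.index[~mis]
            daily = daily[daily["participant_id"].isin(keep)]
    daily = daily.reset_index(drop=True)
    ids = pd.Index(pd.unique(daily["participant_id"]))
    covariates = covariates[covariates["participant_id"].isin(ids)].reset_index(drop=True)
    outcomes = outcomes[outcomes["participant_id"].isin(ids)].reset_index(drop=True)
    outcome_series = outcomes.set_index("participant_id")[spec.outcome]

    # Stage 1 (RC) + Stage 2: frozen classification function
    rc_fits = uem.fit_all_error_models(daily, covariates, lambda_grid=lambda_grid)
    rc_usual = uem.usual_exposures_table(daily, covariates, mode="rc", fits=rc_fits)
    mtp_model, train_names = mtp_clustering.fit_mtp_model(
        rc_usual, k=k, n_starts=n_starts, seed=seed
    )
    shares = pd.Series(train_names).value_counts(normalize=True).to_dict()

    # Stage 1 (MI variant): outcome-conditioned error models
    mi_fits = uem.fit_all_error_models(
        daily, covariates, include_outcome=True, outcome=outcome_series,
        lambda_grid=lambda_grid,
    )

    est: dict[str, list[float]] = {c: [] for c in MTP_CONTRASTS}
    var: dict[str, list[float]] = {c: [] for c in MTP_CONTRASTS}
    failed = 0
    for m in range(m_imputations):
        try:
            drawn = uem.usual_exposures_table(
                daily, covariates, mode="mi", fits=mi_fits, rng=rng, n_draws=1
            )
            data = _analysis_frame(drawn, covariates, outcomes, mtp_model, spec)
            contrasts, _ = fit_lmm(data, spec)
            for c, (b, se) in contrasts.items():
                est[c].append(b)
                var[c].append(se**2)
        except Exception as exc:  # noqa: BLE001 - failures are counted, not fatal
            failed += 1
            warnings.warn(f"imputation {m} failed: {exc}")
            if failed > max_failure_rate * m_imputations:
                raise RuntimeError(
                    f"{failed} of {m + 1} imputations failed (> {max_failure_rate:.0%})"
                ) from exc
    results = {}
    for c in est:
        if est[c]:
            r = rubins_rule(est[c], var[c])
            r.contrast = c
            results[c] = r
    return ThreeStageResult(results, mtp_model, rc_usual, m_imputations - failed, failed, shares)


def run_naive(
    daily: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    k: int = 3,
    n_starts: int = 25,
) -> dict[str, tuple[float, float]]:
    """Uncorrected comparator: one day per person, one clustering, one fit.

    Uses each participant's first retained recall day as the exposure,
    clusters those single-day values, and fits the outcome model once —
    the analysis whose estimates the three-stage procedure de-attenuates.
    """
    if "plausibility" in daily.columns:
        daily = daily[daily["plausibility"] != "excluded_low_energy"]
    first = (
        daily.sort_values(["participant_id", "day_index"], kind="stable")
        .groupby("participant_id", as_index=False)
        .first()
    )
    single = first[["participant_id"] + EXPOSURE_NAMES].copy()
    single["total_kcal"] = first["total_kcal"]
    single["healthy_kcal"] = first["healthy_kcal"]
    model, _ = mtp_clustering.fit_mtp_model(single, k=k, n_starts=n_starts, seed=seed)
    data = _analysis_frame(single, covariates, outcomes, model, spec)
    contrasts, _ = fit_lmm(data, spec)
    return contrasts
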