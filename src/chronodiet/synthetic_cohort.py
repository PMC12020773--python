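"""Synthetic cohort generator for the meal-timing analysis pipeline.

Builds a population of children/adolescents carrying one of three latent
meal-timing archetypes, emits meal-level 24-hr recall records whose derived
daily exposures equal the participant's true usual exposures plus day-to-day
noise, and simulates metabolic outcome z-scores with a family random
intercept — so every downstream stage (exposure derivation, usual-intake
modelling, clustering, MI association) can be exercised and validated
against known ground truth.

The default archetype signatures, exposure means/SDs, recall-repeat
probabilities and outcome contrasts are calibrated to a published European
children's cohort; all of them are plain config on :class:`PopulationSpec`
and :class:`ArchetypeSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recall_processing import EXPOSURE_NAMES, GOLDBERG_CUTOFFS, compute_bmr

__all__ = [
    "ArchetypeSpec",
    "PopulationSpec",
    "default_archetypes",
    "generate_participants",
    "generate_true_exposures",
    "generate_recalls",
    "generate_outcomes",
    "simulate_cohort",
]

ARCHETYPE_NAMES = ("early-often", "late-long", "late-infrequent-short")

# mean z-score signatures of the three archetypes on
# (morning %, evening %, eating window, pre-sleep fasting, eating frequency)
_ARCHETYPE_Z = {
    "early-often": (0.83, -0.54, 0.17, -0.66, 0.64),
    "late-long": (-0.42, 0.23, 0.53, 0.00, 0.08),
    "late-infrequent-short": (-0.53, 0.41, -0.98, 0.89, -0.98),
}
_ARCHETYPE_WEIGHTS = (791 / 2195, 819 / 2195, 585 / 2195)

COUNTRIES = ("ITA", "EST", "CYP", "BEL", "SWE", "GER", "HUN", "ESP")
_COUNTRY_PROBS = np.array([587, 549, 171, 176, 233, 289, 87, 103], dtype=float)
_COUNTRY_PROBS /= _COUNTRY_PROBS.sum()


@dataclass(frozen=True)
class ArchetypeSpec:
    """A latent meal-timing archetype: label, mixing weight, z signature."""

    name: str
    mix_weight: float
    exposure_mean_z: tuple[float, ...]

    def validate(self) -> None:
        if not 0 < self.mix_weight < 1:
            raise ValueError(f"mix_weight for {self.name!r} must be in (0,1)")
        if len(self.exposure_mean_z) != 5:
            raise ValueError(f"exposure_mean_z for {self.name!r} must have 5 entries")
        if any(abs(z) > 3 for z in self.exposure_mean_z):
            raise ValueError(f"exposure_mean_z for {self.name!r} outside [-3, 3]")


def default_archetypes(separation: float = 1.0) -> list[ArchetypeSpec]:
    """The three default archetypes, optionally scaling the z signatures."""
    return [
        ArchetypeSpec(n, w, tuple(separation * z for z in _ARCHETYPE_Z[n]))
        for n, w in zip(ARCHETYPE_NAMES, _ARCHETYPE_WEIGHTS)
    ]


@dataclass
class PopulationSpec:
    """Everything the generator needs; defaults emulate the reference cohort.

    ``person_sd`` (between-person spread within an archetype) defaults to the
    value that makes the marginal SD of each true exposure equal
    ``exposure_scale`` given the archetype mixture.  ``within_person_sd``
    (day-to-day noise) defaults to ``within_ratio`` times ``exposure_scale``;
    the reference study reports no within-person variance components, so the
    1.0 default ratio is a modelling choice.
    """

    n_participants: int = 1000
    seed: int = 0
    sibling_rate: float = 0.10
    exposure_mean: tuple[float, ...] = (25.5, 35.8, 11.5, 2.5, 4.16)
    exposure_scale: tuple[float, ...] = (5.8, 4.3, 0.6, 0.4, 0.4)
    person_sd: tuple[float, ...] | None = None
    within_person_sd: tuple[float, ...] | None = None
    within_ratio: float = 1.0
    recall_count_probs: tuple[float, float, float] = (0.494, 0.273, 0.233)
    outcome_effects: dict = field(
        default_factory=lambda: {
            "homa_ir_z": (0.06, 0.19),
            "hba1c_z": (-0.02, -0.02),
            "triglycerides_z": (0.02, 0.05),
        }
    )
    family_sd: float = 0.3
    residual_sd: float = 1.0
    # covariate structure
    age_mean: float = 11.75
    age_sd: float = 1.6
    age_archetype_shift: tuple[float, float, float] = (-1.25, 0.5, 0.95)
    bmi_mean: float = 0.59
    bmi_sd: float = 1.05
    bmi_archetype_shift: tuple[float, float, float] = (-0.3, 0.07, 0.36)
    outcome_age_effect: float = 0.05
    outcome_bmi_effect: float = 0.10
    # recall-day construction
    weekend_shift: tuple[float, ...] = (0.0, 0.0, -0.5, 0.0, 0.0)
    misreport_rate: float = 0.2
    low_energy_rate: float = 0.02
    goldberg_cutoffs: tuple[float, float] = GOLDBERG_CUTOFFS
    healthy_prob: float = 0.3
    energy_day_cv: float = 0.12
    frequency_rounding: str = "stochastic"  # or "round": deterministic days
    max_day_retries: int = 100

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not 0 <= self.sibling_rate <= 1:
            raise ValueError("sibling_rate must be in [0, 1]")
        if abs(sum(self.recall_count_probs) - 1.0) > 1e-9:
            raise ValueError("recall_count_probs must sum to 1")
        for name in ("exposure_scale", "within_person_sd", "person_sd"):
            v = getattr(self, name)
            if v is not None and any(s < 0 for s in v):
                raise ValueError(f"{name} entries must be >= 0")
        if len(self.exposure_mean) != 5 or len(self.exposure_scale) != 5:
            raise ValueError("exposure_mean/exposure_scale must have 5 entries")
        if self.family_sd < 0 or self.residual_sd < 0:
            raise ValueError("family_sd/residual_sd must be >= 0")

    def resolved_person_sd(self, archetypes: list[ArchetypeSpec]) -> np.ndarray:
        if self.person_sd is not None:
            return np.asarray(self.person_sd, dtype=float)
        w = np.array([a.mix_weight for a in archetypes])
        Z = np.array([a.exposure_mean_z for a in archetypes])
        between = (w[:, None] * Z**2).sum(0) - ((w[:, None] * Z).sum(0)) ** 2
        scale = np.asarray(self.exposure_scale)
        return np.sqrt(np.clip(1.0 - between, 0.0, None)) * scale

    def resolved_within_sd(self) -> np.ndarray:
        if self.within_person_sd is not None:
            return np.asarray(self.within_person_sd, dtype=float)
        return self.within_ratio * np.asarray(self.exposure_scale)


def _rng(spec: PopulationSpec, stage: int) -> np.random.Generator:
    # per-stage stream so each generate_* call is reproducible in isolation
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stage]))


def generate_participants(
    spec: PopulationSpec, archetypes: list[ArchetypeSpec] | None = None
) -> pd.DataFrame:
    """Draw the participant covariate table with latent archetype labels.

    Siblings (a ``sibling_rate`` fraction of participants, paired) share a
    family id and country.  Age and BMI z-score are shifted per archetype so
    covariate confounding is present and adjustment matters.
    """
    archetypes = archetypes or default_archetypes()
    spec.validate()
    for a in archetypes:
        a.validate()
    if abs(sum(a.mix_weight for a in archetypes) - 1.0) > 1e-9:
        raise ValueError("archetype mix_weights must sum to 1")
    rng = _rng(spec, 1)
    n = spec.n_participants
    names = [a.name for a in archetypes]
    weights = [a.mix_weight for a in archetypes]
    label = rng.choice(names, size=n, p=weights)
    shift_map = dict(zip(names, spec.age_archetype_shift))
    bmi_shift_map = dict(zip(names, spec.bmi_archetype_shift))

    age = spec.age_mean + np.array([shift_map[l] for l in label]) + rng.normal(0, spec.age_sd, n)
    age = np.clip(age, 6.0, 17.5)
    sex = rng.choice(["M", "F"], size=n)
    country = rng.choice(COUNTRIES, size=n, p=_COUNTRY_PROBS)
    isced = rng.choice(["low", "high"], size=n, p=[0.49, 0.51])
    bmi_z = spec.bmi_mean + np.array([bmi_shift_map[l] for l in label]) + rng.normal(0, spec.bmi_sd, n)
    puberty = (rng.random(n) < 1.0 / (1.0 + np.exp(-(age - 12.0) / 0.8))).astype(int)
    weight = np.clip(10.0 + 3.2 * age + 3.0 * bmi_z + rng.normal(0, 4.0, n), 16.0, 110.0)

    family_id = np.array([f"F{i:05d}" for i in range(n)], dtype=object)
    n_pairs = int(np.floor(n * spec.sibling_rate / 2.0))
    if n_pairs > 0:
        idx = rng.choice(n, size=2 * n_pairs, replace=False)
        for a_i, b_i in zip(idx[:n_pairs], idx[n_pairs:]):
            family_id[b_i] = family_id[a_i]
            country[b_i] = country[a_i]

    sleep_noct_wd = np.clip(rng.normal(9.5, 0.7, n), 6.0, 12.0)
    sleep_noct_we = np.clip(rng.normal(9.8, 0.8, n), 6.0, 13.0)
    nap_wd = np.where(rng.random(n) < 0.15, rng.uniform(0.3, 1.0, n), 0.0)
    nap_we = np.where(rng.random(n) < 0.25, rng.uniform(0.3, 1.2, n), 0.0)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "family_id": family_id,
            "latent_archetype": label,
            "age": age,
            "sex": sex,
            "country": country,
            "isced": isced,
            "bmi_z": bmi_z,
            "puberty": puberty,
            "weight_kg": weight,
            "sleep_noct_wd": sleep_noct_wd,
            "sleep_nap_wd": nap_wd,
            "sleep_noct_we": sleep_noct_we,
            "sleep_nap_we": nap_we,
        }
    )


# natural-unit feasibility bounds used by rejection sampling
_TRUE_BOUNDS = dict(
    morning_min=2.0, evening_min=2.0, sum_max=96.0, window_min=4.0,
    fasting_min=0.3, freq_min=2.6,
)


def _valid_exposures(E: np.ndarray, bounds=_TRUE_BOUNDS) -> np.ndarray:
    m, e, w, f, q = E.T
    return (
        (m >= bounds["morning_min"])
        & (e >= bounds["evening_min"])
        & (m + e <= bounds["sum_max"])
        & (w >= bounds["window_min"])
        & (f >= bounds["fasting_min"])
        & (q >= bounds["freq_min"])
    )


def generate_true_exposures(
    participants: pd.DataFrame,
    archetypes: list[ArchetypeSpec],
    spec: PopulationSpec,
) -> pd.DataFrame:
    """True usual exposures: population mean + archetype z * scale + person noise.

    Natural-unit constraints (proportions in range, positive window/fasting/
    frequency) are enforced by resampling the person-level noise, not by
    truncation, to avoid point masses at the bounds.
    """
    spec.validate()
    z_map = {a.name: np.asarray(a.exposure_mean_z, dtype=float) for a in archetypes}
    unknown = set(participants["latent_archetype"]) - set(z_map)
    if unknown:
        raise ValueError(f"unknown archetype labels: {sorted(unknown)}")
    rng = _rng(spec, 2)
    scale = np.asarray(spec.exposure_scale, dtype=float)
    mean = np.asarray(spec.exposure_mean, dtype=float)
    person_sd = spec.resolved_person_sd(archetypes)

    Zc = np.stack([z_map[l] for l in participants["latent_archetype"]])
    base = mean + Zc * scale
    E = base + rng.normal(0.0, person_sd, size=base.shape)
    for _ in range(1000):
        bad = ~_valid_exposures(E)
        if not bad.any():
            break
        E[bad] = base[bad] + rng.normal(0.0, person_sd, size=(bad.sum(), 5))
    else:
        raise RuntimeError("could not generate feasible true exposures")

    out = pd.DataFrame(E, columns=EXPOSURE_NAMES)
    out.insert(0, "participant_id", participants["participant_id"].to_numpy())
    return out


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(int)


def generate_recalls(
    participants: pd.DataFrame,
    true_exposures: pd.DataFrame,
    spec: PopulationSpec,
) -> pd.DataFrame:
    """Emit meal-level recall rows whose derived exposures hit their targets.

    Per day: target exposures = truth + weekend shift + day noise; a day is
    laid out as first meal (morning window), last meal (evening window) and
    snacks in the neutral midday zone, with energies solved so the derived
    morning/evening shares match the targets exactly.  Total energy is tied
    to the participant's BMR so Goldberg plausibility is controllable:
    misreporter-prone participants (a ``misreport_rate`` fraction) report
    below the lower cutoff.  Infeasible geometry is resampled up to
    ``max_day_retries`` and then raises.
    """
    spec.validate()
    rng = _rng(spec, 3)
    truth = true_exposures.set_index("participant_id").loc[
        participants["participant_id"], EXPOSURE_NAMES
    ].to_numpy()
    within_sd = spec.resolved_within_sd()
    wshift = np.asarray(spec.weekend_shift, dtype=float)
    lo_cut = spec.goldberg_cutoffs[0]
    hi_cut = spec.goldberg_cutoffs[1]

    bmr = compute_bmr(
        participants["age"].to_numpy(), participants["sex"].to_numpy(),
        participants["weight_kg"].to_numpy(),
    )

    rows: list[tuple] = []
    n = len(participants)
    n_days_cat = rng.choice([1, 2, 3], size=n, p=list(spec.recall_count_probs))
    extra = rng.poisson(0.5, size=n)
    misreporter = rng.random(n) < spec.misreport_rate
    # reporting propensity is a participant-level trait; days jitter around it
    base_ratio = np.where(
        misreporter,
        rng.uniform(0.55, lo_cut - 0.10, n),
        np.clip(rng.normal(1.55, 0.22, n), lo_cut + 0.07, hi_cut - 0.07),
    )

    for i, pid in enumerate(participants["participant_id"]):
        n_days = int(n_days_cat[i]) if n_days_cat[i] < 3 else int(3 + min(extra[i], 2))
        for d in range(n_days):
            weekend = bool(rng.random() < 2.0 / 7.0)
            for attempt in range(spec.max_day_retries + 1):
                target = truth[i] + (wshift if weekend else 0.0) + rng.normal(0, within_sd)
                m, e, w, f, q = target
                if not _valid_exposures(target[None, :])[0]:
                    continue
                if spec.frequency_rounding == "round":
                    n_occ = int(round(max(q, 1.0)))
                else:
                    n_occ = int(_stochastic_round(np.array([max(q, 1.0)]), rng)[0])
                if n_occ < 3:
                    continue
                # first meal must sit in [05:30, 10:30], last in [17:12, 23:45]
                t0_lo = max(330.0, 1032.0 - w * 60.0)
                t0_hi = min(630.0, 1425.0 - w * 60.0)
                if t0_lo >= t0_hi:
                    continue
                t0 = rng.uniform(t0_lo, t0_hi)
                t_last = t0 + w * 60.0
                mid = np.sort(rng.uniform(660.0, min(t_last - 30.0, 1015.0), n_occ - 2))
                times = np.r_[t0, mid, t_last]
                if spec.low_energy_rate > 0 and rng.random() < spec.low_energy_rate:
                    total = rng.uniform(150.0, 480.0)
                else:
                    ratio = base_ratio[i] * (1.0 + spec.energy_day_cv * rng.standard_normal())
                    # day jitter must not flip the participant's Goldberg side
                    if misreporter[i]:
                        ratio = min(ratio, lo_cut - 0.05)
                    else:
                        ratio = min(max(ratio, lo_cut + 0.02), hi_cut - 0.02)
                    total = bmr[i] * ratio
                mid_share = max(0.0, 1.0 - (m + e) / 100.0)
                mid_split = rng.dirichlet(np.full(n_occ - 2, 4.0)) * mid_share
                energies = np.r_[m / 100.0, mid_split, e / 100.0] * total
                healthy = rng.random(n_occ) < spec.healthy_prob
                wake = t0 - rng.uniform(15.0, 60.0)
                bed = t_last + f * 60.0
                for j in range(n_occ):
                    rows.append(
                        (pid, d, int(weekend), times[j], energies[j], int(healthy[j]), wake, bed)
                    )
                break
            else:
                raise RuntimeError(
                    f"infeasible recall-day geometry for participant {pid} "
                    f"after {spec.max_day_retries} retries"
                )

    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "day_index", "weekend", "occasion_time_min",
            "energy_kcal", "healthy", "wake_min", "bed_min",
        ],
    )


def generate_outcomes(participants: pd.DataFrame, spec: PopulationSpec) -> pd.DataFrame:
    """Outcome z-scores: covariate effects + archetype contrast + family + noise.

    Contrasts are expressed versus the "early-often" archetype in the order
    (late-long, late-infrequent-short).
    """
    spec.validate()
    rng = _rng(spec, 4)
    n = len(participants)
    fam = participants["family_id"].to_numpy()
    uniq = pd.unique(fam)
    fam_eff = dict(zip(uniq, rng.normal(0.0, spec.family_sd, len(uniq))))
    fam_vec = np.array([fam_eff[f] for f in fam])

    base = (
        spec.outcome_age_effect * (participants["age"].to_numpy() - spec.age_mean)
        + spec.outcome_bmi_effect * (participants["bmi_z"].to_numpy() - spec.bmi_mean)
    )
    label = participants["latent_archetype"].to_numpy()
    out = {"participant_id": participants["participant_id"].to_numpy()}
    for name, (b_ll, b_lis) in spec.outcome_effects.items():
        contrast = np.where(
            label == "late-long", b_ll, np.where(label == "late-infrequent-short", b_lis, 0.0)
        )
        out[name] = base + contrast + fam_vec + rng.normal(0.0, spec.residual_sd, n)
    return pd.DataFrame(out)


def simulate_cohort(
    spec: PopulationSpec, archetypes: list[ArchetypeSpec] | None = None
):
    """Convenience wrapper running all four generators with one spec.

    Returns (participants, true_exposures, recalls, outcomes).
    """
    archetypes = archetypes or default_archetypes()
    participants = generate_participants(spec, archetypes)
    truth = generate_true_exposures(participants, archetypes, spec)
    recalls = generate_recalls(participants, truth, spec)
    outcomes = generate_outcomes(participants, spec)
    return participants, truth, recalls, outcomes
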