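"""Derive daily meal-timing exposures from meal-level 24-hr recall records.

Converts per-occasion records (clock time, energy, healthy flag, wake and bed
times) into the five daily exposures — morning energy %, evening energy %,
eating window, pre-sleep fasting and eating frequency — plus energy
aggregates, applies the <500 kcal day exclusion, computes habitual sleep
duration, and flags misreported days via Goldberg cutoffs on the ratio of
reported energy intake to Schofield basal metabolic rate.

Clock-time conventions
----------------------
Occasion times are minutes since midnight of the recall day; post-midnight
intake carries times >= 1440.  The morning window is [05:00, 11:00) and the
evening window [17:00, 24:00), both half-open so a boundary occasion is never
double counted.  By default post-midnight occasions fall outside both
windows; ``count_post_midnight=True`` folds times mod 24 h back into the
evening window instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RecallRecord",
    "DailyExposures",
    "SleepReport",
    "EXPOSURE_NAMES",
    "MORNING_WINDOW_MIN",
    "EVENING_WINDOW_MIN",
    "SCHOFIELD_CONSTANTS",
    "GOLDBERG_CUTOFFS",
    "derive_daily_exposures",
    "derive_daily_exposures_table",
    "exclude_low_energy",
    "compute_sleep_duration",
    "compute_bmr",
    "classify_goldberg",
    "flag_plausibility",
]

#: canonical order of the five meal-timing exposures
EXPOSURE_NAMES = [
    "morning_pct",
    "evening_pct",
    "eating_window_h",
    "presleep_fasting_h",
    "eating_frequency",
]

MORNING_WINDOW_MIN = (300, 660)     # [05:00, 11:00)
EVENING_WINDOW_MIN = (1020, 1440)   # [17:00, 24:00)

#: Schofield weight-based BMR equations, kcal/day = a * weight_kg + b,
#: keyed by sex and age band [lo, hi).
SCHOFIELD_CONSTANTS = {
    ("M", 3, 10): (22.706, 504.3),
    ("M", 10, 18): (17.686, 658.2),
    ("F", 3, 10): (20.315, 485.9),
    ("F", 10, 18): (13.384, 692.6),
}

#: default plausibility bounds on EI/BMR (pediatric adaptation; configurable)
GOLDBERG_CUTOFFS = (1.05, 2.28)

PLAUSIBLE = "plausible"
MISREPORTER = "misreporter"
EXCLUDED_LOW_ENERGY = "excluded_low_energy"


@dataclass
class RecallRecord:
    """One day's meal-level report for one participant.

    ``occasions`` is a list of ``(time_min, energy_kcal, healthy)`` tuples
    sorted by time; ``bed_min`` may be None (fasting becomes missing) and may
    precede the last occasion (fasting is then negative and flagged upstream
    rather than clipped).
    """

    participant_id: object
    weekend: bool
    occasions: list[tuple[float, float, bool]]
    wake_min: float | None = None
    bed_min: float | None = None

    def __post_init__(self) -> None:
        if len(self.occasions) == 0:
            raise ValueError("RecallRecord needs at least one occasion")
        times = [t for t, _, _ in self.occasions]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("occasion times must be sorted non-decreasing")
        if any(e < 0 for _, e, _ in self.occasions):
            raise ValueError("occasion energies must be >= 0")


@dataclass
class DailyExposures:
    participant_id: object
    weekend: bool
    total_kcal: float
    healthy_kcal: float
    unhealthy_kcal: float
    morning_kcal: float
    evening_kcal: float
    morning_pct: float
    evening_pct: float
    eating_window_h: float
    presleep_fasting_h: float | None
    eating_frequency: int
    plausibility: str = PLAUSIBLE


@dataclass
class SleepReport:
    nocturnal_we: float
    nap_we: float
    nocturnal_wd: float
    nap_wd: float


def _window_mask(times: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return (times >= lo) & (times < hi)


def _evening_mask(times: np.ndarray, count_post_midnight: bool) -> np.ndarray:
    m = _window_mask(times, *EVENING_WINDOW_MIN)
    if count_post_midnight:
        # fold post-midnight intake (00:00-05:00 next day) into the evening
        m = m | ((times >= 1440) & (times < 1440 + MORNING_WINDOW_MIN[0]))
    return m


def _count_occasions(times: np.ndarray, merge_gap_min: float) -> int:
    if merge_gap_min <= 0:
        return len(times)
    return int(1 + np.sum(np.diff(times) > merge_gap_min))


def derive_daily_exposures(
    record: RecallRecord,
    merge_gap_min: float = 0.0,
    count_post_midnight: bool = False,
) -> DailyExposures:
    """Compute the five meal-timing exposures and energy totals for one day.

    Morning/evening energy shares use the half-open clock windows above;
    the eating window is last-minus-first occasion time and pre-sleep fasting
    is bedtime-minus-last occasion time, both in hours.  Eating frequency
    counts occasions after merging those closer than ``merge_gap_min``
    (default 0: every reported occasion counts).
    """
    times = np.array([t for t, _, _ in record.occasions], dtype=float)
    energies = np.array([e for _, e, _ in record.occasions], dtype=float)
    healthy = np.array([h for _, _, h in record.occasions], dtype=bool)

    total = float(energies.sum())
    if total <= 0:
        raise ValueError("day has zero total energy")
    healthy_kcal = float(energies[healthy].sum())
    morning = float(energies[_window_mask(times, *MORNING_WINDOW_MIN)].sum())
    evening = float(energies[_evening_mask(times, count_post_midnight)].sum())
    window_h = float(times[-1] - times[0]) / 60.0
    fasting_h = None
    if record.bed_min is not None:
        fasting_h = float(record.bed_min - times[-1]) / 60.0
    return DailyExposures(
        participant_id=record.participant_id,
        weekend=record.weekend,
        total_kcal=total,
        healthy_kcal=healthy_kcal,
        unhealthy_kcal=total - healthy_kcal,
        morning_kcal=morning,
        evening_kcal=evening,
        morning_pct=min(100.0 * morning / total, 100.0),
        evening_pct=min(100.0 * evening / total, 100.0),
        eating_window_h=window_h,
        presleep_fasting_h=fasting_h,
        eating_frequency=_count_occasions(times, merge_gap_min),
    )


def derive_daily_exposures_table(
    recalls: pd.DataFrame,
    merge_gap_min: float = 0.0,
    count_post_midnight: bool = False,
) -> pd.DataFrame:
    """Vectorised :func:`derive_daily_exposures` over a meal-level table.

    ``recalls`` columns: participant_id, day_index, weekend, occasion_time_min,
    energy_kcal, healthy, bed_min (wake_min optional).  Returns one row per
    (participant_id, day_index).
    """
    required = {"participant_id", "day_index", "weekend", "occasion_time_min", "energy_kcal", "healthy"}
    missing = required - set(recalls.columns)
    if missing:
        raise ValueError(f"recalls table missing columns: {sorted(missing)}")
    df = recalls.sort_values(
        ["participant_id", "day_index", "occasion_time_min"], kind="stable"
    ).reset_index(drop=True)

    t = df["occasion_time_min"].to_numpy(dtype=float)
    e = df["energy_kcal"].to_numpy(dtype=float)
    h = df["healthy"].to_numpy(dtype=bool)
    key = df["participant_id"].astype(str) + "\x00" + df["day_index"].astype(str)
    starts = np.flatnonzero(np.r_[True, key.to_numpy()[1:] != key.to_numpy()[:-1]])
    ends = np.r_[starts[1:], len(df)] - 1

    total = np.add.reduceat(e, starts)
    healthy_kcal = np.add.reduceat(np.where(h, e, 0.0), starts)
    morning = np.add.reduceat(np.where(_window_mask(t, *MORNING_WINDOW_MIN), e, 0.0), starts)
    evening = np.add.reduceat(np.where(_evening_mask(t, count_post_midnight), e, 0.0), starts)
    first, last = t[starts], t[ends]
    if merge_gap_min > 0:
        # diffs cross group borders, so fall back to a per-day loop here
        freq = np.empty(len(starts))
        for i, (s, eidx) in enumerate(zip(starts, ends)):
            freq[i] = _count_occasions(t[s : eidx + 1], merge_gap_min)
    else:
        freq = (ends - starts + 1).astype(float)
    bed = (
        df["bed_min"].to_numpy(dtype=float)[starts]
        if "bed_min" in df.columns
        else np.full(len(starts), np.nan)
    )
    if np.any(total <= 0):
        raise ValueError("day with zero total energy in recalls table")

    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy()[starts],
            "day_index": df["day_index"].to_numpy()[starts],
            "weekend": df["weekend"].to_numpy()[starts].astype(int),
            "total_kcal": total,
            "healthy_kcal": healthy_kcal,
            "unhealthy_kcal": total - healthy_kcal,
            "morning_kcal": morning,
            "evening_kcal": evening,
            "morning_pct": np.minimum(100.0 * morning / total, 100.0),
            "evening_pct": np.minimum(100.0 * evening / total, 100.0),
            "eating_window_h": (last - first) / 60.0,
            "presleep_fasting_h": (bed - last) / 60.0,
            "eating_frequency": freq,
        }
    )
    return out


def exclude_low_energy(daily: pd.DataFrame, threshold_kcal: float = 500.0):
    """Partition day rows into (retained, excluded) by total energy.

    A day is excluded iff total energy is strictly below ``threshold_kcal``.
    """
    low = daily["total_kcal"] < threshold_kcal
    return daily.loc[~low].copy(), daily.loc[low].copy()


def compute_sleep_duration(report: SleepReport | tuple) -> float:
    """Habitual daily sleep: 2/7 weighting of weekend, 5/7 of weekday hours."""
    if isinstance(report, tuple):
        report = SleepReport(*report)
    parts = (report.nocturnal_we, report.nap_we, report.nocturnal_wd, report.nap_wd)
    if any(p < 0 for p in parts):
        raise ValueError("sleep components must be >= 0")
    return 2.0 / 7.0 * (report.nocturnal_we + report.nap_we) + 5.0 / 7.0 * (
        report.nocturnal_wd + report.nap_wd
    )


def compute_bmr(age, sex, weight_kg, constants=None):
    """Schofield weight-based basal metabolic rate (kcal/day).

    ``age`` in years must lie in [3, 18]; ``sex`` is 'M'/'F'.  Accepts scalars
    or aligned arrays.
    """
    constants = constants or SCHOFIELD_CONSTANTS
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    sex_arr = np.asarray(sex)
    if np.any((age < 3) | (age > 18)):
        raise ValueError("age out of supported range [3, 18]")
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    bmr = np.full(age.shape, np.nan)
    for (s, lo, hi), (a, b) in constants.items():
        m = (sex_arr == s) & (age >= lo) & ((age < hi) | (hi == 18))
        bmr = np.where(m, a * weight + b, bmr)
    if np.any(np.isnan(bmr)):
        raise ValueError("no Schofield band matched some (sex, age)")
    return float(bmr) if bmr.ndim == 0 else bmr


def classify_goldberg(ei_kcal, bmr_kcal, cutoffs=GOLDBERG_CUTOFFS):
    """Label a recall day plausible/misreported by the EI/BMR ratio."""
    ei = np.asarray(ei_kcal, dtype=float)
    bmr = np.asarray(bmr_kcal, dtype=float)
    if np.any(bmr <= 0):
        raise ValueError("bmr must be positive")
    lo, hi = cutoffs
    ratio = ei / bmr
    label = np.where((ratio >= lo) & (ratio <= hi), PLAUSIBLE, MISREPORTER)
    return str(label) if label.ndim == 0 else label


def flag_plausibility(
    daily: pd.DataFrame,
    participants: pd.DataFrame,
    cutoffs=GOLDBERG_CUTOFFS,
    low_energy_kcal: float = 500.0,
) -> pd.DataFrame:
    """Attach a plausibility label to every day row.

    Days under ``low_energy_kcal`` get ``excluded_low_energy``; the rest are
    classified by Goldberg cutoffs against the participant's Schofield BMR.
    """
    cov = participants.set_index("participant_id")
    age = cov.loc[daily["participant_id"], "age"].to_numpy()
    sex = cov.loc[daily["participant_id"], "sex"].to_numpy()
    weight = cov.loc[daily["participant_id"], "weight_kg"].to_numpy()
    bmr = compute_bmr(age, sex, weight)
    label = classify_goldberg(daily["total_kcal"].to_numpy(), bmr, cutoffs)
    label = np.asarray(label, dtype=object)
    label[daily["total_kcal"].to_numpy() < low_energy_kcal] = EXCLUDED_LOW_ENERGY
    out = daily.copy()
    out["plausibility"] = label
    return out
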