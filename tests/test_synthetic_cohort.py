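import numpy as np
import pandas as pd
import pytest

from chronodiet import recall_processing as rp
from chronodiet import synthetic_cohort as sc
from chronodiet.recall_processing import EXPOSURE_NAMES, derive_daily_exposures_table


class TestGenerateParticipants:
    def test_archetype_counts_within_binomial_bounds(self):
        arch = [
            sc.ArchetypeSpec("early-often", 0.36, (0.8, -0.5, 0.2, -0.7, 0.6)),
            sc.ArchetypeSpec("late-long", 0.37, (-0.4, 0.2, 0.5, 0.0, 0.1)),
            sc.ArchetypeSpec("late-infrequent-short", 0.27, (-0.5, 0.4, -1.0, 0.9, -1.0)),
        ]
        spec = sc.PopulationSpec(n_participants=1000, seed=5)
        parts = sc.generate_participants(spec, arch)
        counts = parts["latent_archetype"].value_counts()
        for a in arch:
            expected = 1000 * a.mix_weight
            sd = np.sqrt(1000 * a.mix_weight * (1 - a.mix_weight))
            assert abs(counts[a.name] - expected) < 3 * sd

    def test_zero_sibling_rate_unique_families(self):
        spec = sc.PopulationSpec(n_participants=200, seed=1, sibling_rate=0.0)
        parts = sc.generate_participants(spec)
        assert parts["family_id"].is_unique

    def test_siblings_share_family_and_country(self):
        spec = sc.PopulationSpec(n_participants=400, seed=2, sibling_rate=0.3)
        parts = sc.generate_participants(spec)
        dup = parts[parts.duplicated("family_id", keep=False)]
        assert len(dup) > 0
        for _, grp in dup.groupby("family_id"):
            assert grp["country"].nunique() == 1

    def test_seeded_reproducibility(self):
        spec = sc.PopulationSpec(n_participants=150, seed=42)
        a = sc.generate_participants(spec)
        b = sc.generate_participants(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_age_confounding_direction(self):
        spec = sc.PopulationSpec(n_participants=3000, seed=3)
        parts = sc.generate_participants(spec)
        means = parts.groupby("latent_archetype")["age"].mean()
        assert means["early-often"] < means["late-long"] < means["late-infrequent-short"]

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="n_participants"):
            sc.generate_participants(sc.PopulationSpec(n_participants=1))
        with pytest.raises(ValueError, match="recall_count_probs"):
            sc.generate_participants(
                sc.PopulationSpec(n_participants=10, recall_count_probs=(0.5, 0.5, 0.5))
            )


class TestGenerateTrueExposures:
    def test_zero_noise_substitution(self):
        # morning mean 25.5, SD 5.8, early-often z 0.83 -> 25.5 + 0.83*5.8
        arch = sc.default_archetypes()
        spec = sc.PopulationSpec(n_participants=50, seed=4, person_sd=(0, 0, 0, 0, 0))
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        early = truth[parts["latent_archetype"].to_numpy() == "early-often"]
        assert np.allclose(early["morning_pct"], 25.5 + 0.83 * 5.8)
        assert np.allclose(early["morning_pct"], 30.314)

    def test_degenerate_archetypes_share_population_mean(self):
        arch = [
            sc.ArchetypeSpec("early-often", 0.4, (0,) * 5),
            sc.ArchetypeSpec("late-long", 0.3, (0,) * 5),
            sc.ArchetypeSpec("late-infrequent-short", 0.3, (0,) * 5),
        ]
        spec = sc.PopulationSpec(n_participants=40, seed=5, person_sd=(0, 0, 0, 0, 0))
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        for name, mean in zip(EXPOSURE_NAMES, spec.exposure_mean):
            assert np.allclose(truth[name], mean)

    def test_morning_ordering_across_archetypes(self):
        arch = sc.default_archetypes()
        spec = sc.PopulationSpec(n_participants=2000, seed=6)
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        m = truth.groupby(parts["latent_archetype"].to_numpy())["morning_pct"].mean()
        assert m["early-often"] > m["late-long"] > m["late-infrequent-short"]

    def test_unknown_label_error(self):
        arch = sc.default_archetypes()
        spec = sc.PopulationSpec(n_participants=20, seed=7)
        parts = sc.generate_participants(spec, arch)
        parts.loc[0, "latent_archetype"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            sc.generate_true_exposures(parts, arch, spec)

    def test_natural_unit_constraints(self):
        spec = sc.PopulationSpec(n_participants=2000, seed=8)
        arch = sc.default_archetypes()
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        assert (truth["morning_pct"] + truth["evening_pct"] <= 100).all()
        assert (truth["morning_pct"] >= 0).all()
        assert (truth[["eating_window_h", "presleep_fasting_h", "eating_frequency"]] > 0).all().all()

    def test_marginal_calibration_to_reference_values(self):
        # grand means/SDs of true exposures within 3 MC SEs of the reference table
        spec = sc.PopulationSpec(n_participants=2500, seed=9)
        arch = sc.default_archetypes()
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        n = len(truth)
        for name, mean, sd in zip(EXPOSURE_NAMES, spec.exposure_mean, spec.exposure_scale):
            x = truth[name].to_numpy()
            assert abs(x.mean() - mean) < 3 * sd / np.sqrt(n), name
            assert abs(x.std(ddof=1) - sd) < 3.5 * sd / np.sqrt(2 * n), name


class TestGenerateRecalls:
    def test_recall_count_distribution(self):
        spec = sc.PopulationSpec(n_participants=2000, seed=10)
        arch = sc.default_archetypes()
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        recalls = sc.generate_recalls(parts, truth, spec)
        days = recalls.groupby("participant_id")["day_index"].nunique()
        share_one = (days == 1).mean()
        se = np.sqrt(0.494 * 0.506 / 2000)
        assert abs(share_one - 0.494) < 3 * se
        share_two = (days == 2).mean()
        assert abs(share_two - 0.273) < 3 * np.sqrt(0.273 * 0.727 / 2000)

    def test_single_recall_probs(self):
        spec = sc.PopulationSpec(n_participants=100, seed=11, recall_count_probs=(1.0, 0.0, 0.0))
        arch = sc.default_archetypes()
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        recalls = sc.generate_recalls(parts, truth, spec)
        assert (recalls.groupby("participant_id")["day_index"].nunique() == 1).all()

    def test_occasions_sorted_and_energies_positive(self):
        spec = sc.PopulationSpec(n_participants=100, seed=12)
        arch = sc.default_archetypes()
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        recalls = sc.generate_recalls(parts, truth, spec)
        for _, grp in recalls.groupby(["participant_id", "day_index"]):
            assert grp["occasion_time_min"].is_monotonic_increasing
        assert (recalls["energy_kcal"] >= 0).all()

    def test_seeded_determinism(self):
        spec = sc.PopulationSpec(n_participants=80, seed=13)
        arch = sc.default_archetypes()
        parts = sc.generate_participants(spec, arch)
        truth = sc.generate_true_exposures(parts, arch, spec)
        a = sc.generate_recalls(parts, truth, spec)
        b = sc.generate_recalls(parts, truth, spec)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateOutcomes:
    def test_all_zero_effects_give_zero(self):
        spec = sc.PopulationSpec(
            n_participants=50, seed=14, family_sd=0.0, residual_sd=0.0,
            outcome_age_effect=0.0, outcome_bmi_effect=0.0,
            outcome_effects={"homa_ir_z": (0.0, 0.0)},
        )
        parts = sc.generate_participants(spec)
        out = sc.generate_outcomes(parts, spec)
        assert np.allclose(out["homa_ir_z"], 0.0)

    def test_contrast_mean_recovery(self):
        spec = sc.PopulationSpec(
            n_participants=8000, seed=15, family_sd=0.0,
            outcome_age_effect=0.0, outcome_bmi_effect=0.0,
            outcome_effects={"homa_ir_z": (0.0, 0.5)},
        )
        parts = sc.generate_participants(spec)
        out = sc.generate_outcomes(parts, spec)
        lis = out.loc[parts["latent_archetype"].to_numpy() == "late-infrequent-short", "homa_ir_z"]
        assert abs(lis.mean() - 0.5) < 3 / np.sqrt(len(lis))

    def test_sibling_correlation_from_family_effect(self):
        def sib_corr(family_sd, seed):
            spec = sc.PopulationSpec(
                n_participants=4000, seed=seed, sibling_rate=0.5, family_sd=family_sd,
                outcome_age_effect=0.0, outcome_bmi_effect=0.0,
                outcome_effects={"homa_ir_z": (0.0, 0.0)},
            )
            parts = sc.generate_participants(spec)
            out = sc.generate_outcomes(parts, spec)
            df = parts[["participant_id", "family_id"]].merge(out, on="participant_id")
            pairs = df[df.duplicated("family_id", keep=False)].sort_values("family_id")
            g = pairs.groupby("family_id")["homa_ir_z"]
            first, second = g.nth(0).to_numpy(), g.nth(1).to_numpy()
            return np.corrcoef(first, second)[0, 1]

        # ICC = family_sd^2 / (family_sd^2 + residual_sd^2)
        assert sib_corr(1.0, 16) > 0.35
        assert abs(sib_corr(0.0, 17)) < 0.08

    def test_reference_archetype_has_zero_contrast(self):
        spec = sc.PopulationSpec(
            n_participants=5000, seed=18, family_sd=0.0, residual_sd=0.0,
            outcome_age_effect=0.0, outcome_bmi_effect=0.0,
        )
        parts = sc.generate_participants(spec)
        out = sc.generate_outcomes(parts, spec)
        early = parts["latent_archetype"].to_numpy() == "early-often"
        assert np.allclose(out.loc[early, "homa_ir_z"], 0.0)


def test_day_level_exposures_unbiased_for_truth():
    # day noise is mean zero: per-participant day means scatter around truth
    spec = sc.PopulationSpec(
        n_participants=500, seed=19, recall_count_probs=(0.0, 0.0, 1.0),
        weekend_shift=(0, 0, 0, 0, 0), low_energy_rate=0.0,
    )
    arch = sc.default_archetypes()
    parts = sc.generate_participants(spec, arch)
    truth = sc.generate_true_exposures(parts, arch, spec)
    recalls = sc.generate_recalls(parts, truth, spec)
    daily = derive_daily_exposures_table(recalls)
    merged = daily.merge(truth, on="participant_id", suffixes=("", "_true"))
    for col in ("morning_pct", "eating_window_h", "presleep_fasting_h"):
        diff = merged[col] - merged[col + "_true"]
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(len(diff)), col


class TestArchetypeSpecValidation:
    def test_mix_weight_bounds(self):
        with pytest.raises(ValueError, match="mix_weight"):
            sc.ArchetypeSpec("early-often", 1.5, (0,) * 5).validate()

    def test_signature_length(self):
        with pytest.raises(ValueError, match="5 entries"):
            sc.ArchetypeSpec("early-often", 0.5, (0, 0, 0)).validate()

    def test_signature_range(self):
        with pytest.raises(ValueError, match="\\[-3, 3\\]"):
            sc.ArchetypeSpec("early-often", 0.5, (4, 0, 0, 0, 0)).validate()

    def test_weights_must_sum_to_one(self):
        arch = [
            sc.ArchetypeSpec("early-often", 0.5, (0,) * 5),
            sc.ArchetypeSpec("late-long", 0.3, (0,) * 5),
            sc.ArchetypeSpec("late-infrequent-short", 0.3, (0,) * 5),
        ]
        with pytest.raises(ValueError, match="sum to 1"):
            sc.generate_participants(sc.PopulationSpec(n_participants=10), arch)
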