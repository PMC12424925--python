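"""Synthetic cohort generation, preprocessing rules, and resampling."""

import numpy as np
import pandas as pd
import pytest

import agearch as a
from agearch.errors import (
    ConfigurationError,
    InsufficientVisitsError,
    MatchingInfeasibleError,
    ParameterError,
)


class TestSimulateGenotypes:
    def test_symmetric_maf_mean_dosage(self):
        g = a.simulate_genotypes(4000, 1, maf_range=(0.5, 0.5), seed=1)
        assert set(np.unique(g.dosages)) <= {0, 1, 2}
        assert g.dosages.mean() == pytest.approx(1.0, abs=0.05)

    def test_frequencies_within_binomial_bounds(self):
        g = a.simulate_genotypes(5000, 2000, maf_range=(0.05, 0.5), seed=2)
        emp = g.dosages.mean(axis=0) / 2.0
        se = np.sqrt(g.allele_freqs * (1 - g.allele_freqs) / (2 * 5000))
        within = np.abs(emp - g.allele_freqs) <= 3 * se
        assert within.mean() >= 0.95
        assert np.all((emp > 0) & (emp < 1))

    def test_seed_determinism(self):
        g1 = a.simulate_genotypes(100, 50, seed=7)
        g2 = a.simulate_genotypes(100, 50, seed=7)
        assert np.array_equal(g1.dosages, g2.dosages)

    @pytest.mark.parametrize("maf", [(0.0, 0.5), (0.1, 0.6), (-0.1, 0.2), (0.4, 0.2)])
    def test_invalid_maf_range(self, maf):
        with pytest.raises(ParameterError):
            a.simulate_genotypes(10, 5, maf_range=maf, seed=0)


class TestSimulateCohort:
    def test_null_heritability_gives_no_genetic_signal(self, small_genotypes):
        cfg = a.CohortConfig(traits=[a.TraitSpec("t", h2=0.0)])
        table, states = a.simulate_cohort(small_genotypes, cfg, seed=5)
        y = table.trait_at_visit("t", 1).to_numpy()
        # G is identically zero at h2=0, so check against a random genetic score
        z = small_genotypes.standardized() @ np.random.default_rng(0).normal(size=80)
        r = np.corrcoef(y, z)[0, 1]
        assert abs(r) < 3 / np.sqrt(small_genotypes.n)

    def test_variance_decomposes(self):
        geno = a.simulate_genotypes(4000, 300, seed=8)
        cfg = a.CohortConfig(traits=[a.TraitSpec("t", h2=0.5, ea_increment_var=0.05)])
        _, states = a.simulate_cohort(geno, cfg, seed=9)
        st = states["t"]
        lb5 = st.liability_at_bin[:, 4]
        parts = st.G.var() + st.E0.var() + st.ea_increments.cumsum(axis=1)[:, 4].var()
        assert lb5.var() == pytest.approx(parts, rel=0.05)

    def test_no_measurement_error_means_identical_visits(self, small_genotypes):
        cfg = a.CohortConfig(
            traits=[a.TraitSpec("t", h2=0.4, measurement_error_var=0.0)],
            visit_offsets=(0.0, 5.0),
        )
        table, _ = a.simulate_cohort(small_genotypes, cfg, seed=5)
        v1 = table.trait_at_visit("t", 1).to_numpy()
        v2 = table.trait_at_visit("t", 2).to_numpy()
        assert np.corrcoef(v1, v2)[0, 1] == pytest.approx(1.0)

    def test_baseline_ages_in_range_and_visits_increasing(self, marker_cohort):
        _, table, _ = marker_cohort
        ages = table.individuals["baseline_age"]
        assert ages.between(40, 79).all()
        wide = table.visits.pivot_table(index="id", columns="visit", values="age")
        assert (wide.diff(axis=1).iloc[:, 1:] > 0).all().all() or wide.shape[1] == 1

    def test_diagnoses_precede_censoring(self, marker_cohort):
        _, table, _ = marker_cohort
        merged = table.diagnoses.merge(table.individuals[["id", "censor_age"]], on="id")
        assert (merged["age_at_diagnosis"] <= merged["censor_age"]).all()

    def test_unknown_loading_target_rejected(self, small_genotypes):
        cfg = a.CohortConfig(traits=[a.TraitSpec("t", loads_on="nope")])
        with pytest.raises(ConfigurationError):
            a.simulate_cohort(small_genotypes, cfg, seed=0)


class TestLongitudinalLiability:
    def test_zero_decay_keeps_liability_constant(self):
        df = a.simulate_longitudinal_liability(500, "stationary_decay", 0.0, (45, 50, 55), 0.0, seed=3)
        wide = df.pivot_table(index="id", columns="visit", values="liability")
        assert np.allclose(wide[1], wide[2])
        assert np.allclose(wide[1], wide[3])

    def test_stationary_decay_closed_form(self):
        df = a.simulate_longitudinal_liability(
            30_000, "stationary_decay", 0.02, (45.0, 55.0), 0.0, seed=4
        )
        wide = df.pivot_table(index="id", columns="visit", values="value")
        r = np.corrcoef(wide[1], wide[2])[0, 1]
        assert r == pytest.approx(np.exp(-0.2), abs=0.01)

    def test_stationary_correlations_multiply_but_wiener_grows(self):
        ages = (45.0, 50.0, 55.0)
        stat = a.simulate_longitudinal_liability(30_000, "stationary_decay", 0.03, ages, 0.0, seed=5)
        wide = stat.pivot_table(index="id", columns="visit", values="value")
        r12 = np.corrcoef(wide[1], wide[2])[0, 1]
        r23 = np.corrcoef(wide[2], wide[3])[0, 1]
        r13 = np.corrcoef(wide[1], wide[3])[0, 1]
        assert r13 == pytest.approx(r12 * r23, abs=0.02)
        wien = a.simulate_longitudinal_liability(30_000, "wiener", 0.05, ages, 0.0, seed=5)
        w = wien.pivot_table(index="id", columns="visit", values="value")
        variances = w.var().to_numpy()
        assert variances[1] > variances[0] and variances[2] > variances[1]
        assert np.diff(variances) == pytest.approx([0.25, 0.25], rel=0.1)

    def test_errors(self):
        with pytest.raises(InsufficientVisitsError):
            a.simulate_longitudinal_liability(10, "wiener", 0.1, (45.0,), 0.0, seed=0)
        with pytest.raises(ParameterError):
            a.simulate_longitudinal_liability(10, "brownian_bridge", 0.1, (45.0, 50.0), 0.0, seed=0)


class TestMedicationCorrection:
    @pytest.fixture
    def toy_cohort(self):
        individuals = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "sex": [0, 1, 0, 1],
                "baseline_age": [45.0, 55.0, 65.0, 75.0],
                "censor_age": [80.0] * 4,
                "hypertension_med": [1, 0, 0, 1],
                "insulin_med": [1, 0, 0, 0],
            }
        )
        visits = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"] * 2,
                "visit": [1] * 8,
                "age": [45.0, 55.0, 65.0, 75.0] * 2,
                "trait": ["sbp"] * 4 + ["hba1c"] * 4,
                "value": [130.0, 120.0, 140.0, 150.0, 40.0, 38.0, 42.0, 36.0],
            }
        )
        return a.CohortTable(
            individuals=individuals,
            visits=visits,
            diagnoses=pd.DataFrame(columns=["id", "disease", "age_at_diagnosis"]),
        )

    def test_absolute_rule_printed_constants(self, toy_cohort):
        rules = [a.MedicationRule("sbp", "hypertension_med", 15.0, "absolute")]
        out = a.apply_medication_correction(toy_cohort, rules)
        corr = out.trait_at_visit("sbp_corrected", 1)
        assert corr["a"] == pytest.approx(145.0)  # 130 + 15, flagged
        assert corr["b"] == pytest.approx(120.0)  # unflagged unchanged
        # uncorrected column retained
        assert out.trait_at_visit("sbp", 1)["a"] == pytest.approx(130.0)

    def test_insulin_rule_arithmetic(self, toy_cohort):
        rules = [a.MedicationRule("hba1c", "insulin_med", 1.3 * 10.929, "absolute")]
        out = a.apply_medication_correction(toy_cohort, rules)
        assert out.trait_at_visit("hba1c_corrected", 1)["a"] == pytest.approx(54.2077)

    def test_sd_mode_uses_whole_population_sd(self, toy_cohort):
        rules = [a.MedicationRule("sbp", "hypertension_med", 1.0, "sd")]
        out = a.apply_medication_correction(toy_cohort, rules)
        sd = np.std([130.0, 120.0, 140.0, 150.0], ddof=1)
        assert out.trait_at_visit("sbp_corrected", 1)["d"] == pytest.approx(150.0 + sd)

    def test_unknown_flag_or_trait(self, toy_cohort):
        with pytest.raises(ConfigurationError):
            a.apply_medication_correction(
                toy_cohort, [a.MedicationRule("sbp", "statin", 1.0, "sd")]
            )
        with pytest.raises(ConfigurationError):
            a.apply_medication_correction(
                toy_cohort, [a.MedicationRule("ldl", "insulin_med", 1.0, "sd")]
            )

    def test_default_rules_match_published_constants(self):
        by_key = {(r.trait, r.flag): r for r in a.cohort.DEFAULT_MEDICATION_RULES}
        assert by_key[("sbp", "hypertension_med")].correction == 15.0
        assert by_key[("dbp", "hypertension_med")].correction == 10.0
        assert by_key[("hba1c", "insulin_med")].correction == pytest.approx(14.2077)


class TestAgeMatchedResample:
    def test_shifted_groups_match_after_weighting(self):
        rng = np.random.default_rng(12)
        ages = np.concatenate([rng.normal(50, 6, 4000), rng.normal(60, 6, 4000)])
        labels = np.repeat([0, 1], 4000)
        i0, i1 = a.age_matched_resample(ages, labels, 1500, seed=13)
        assert abs(ages[i0].mean() - ages[i1].mean()) < 1.0
        assert len(set(i0)) == 1500 and len(set(i1)) == 1500

    def test_identical_distributions_trivially_match(self):
        rng = np.random.default_rng(14)
        ages = rng.uniform(40, 79, 2000)
        labels = rng.integers(0, 2, 2000)
        i0, i1 = a.age_matched_resample(ages, labels, 300, seed=15)
        assert abs(ages[i0].mean() - ages[i1].mean()) < 2.0

    def test_errors(self):
        ages = np.concatenate([np.linspace(40, 50, 100), np.linspace(70, 79, 100)])
        labels = np.repeat([0, 1], 100)
        with pytest.raises(MatchingInfeasibleError):
            a.age_matched_resample(ages, labels, 50, seed=0)
        with pytest.raises(MatchingInfeasibleError):
            a.age_matched_resample(np.linspace(40, 60, 50), np.repeat([0, 1], 25), 26, seed=0)
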