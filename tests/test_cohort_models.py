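"""Individual-level cohort regressions, standardization, pooling and exclusions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from duogenie.cohort_models import (
    CohortAssoc,
    apply_exclusions,
    fit_snp_model,
    meta_across_cohorts,
    ponderal_index,
    standardize_outcomes,
)
from duogenie.errors import DegenerateInputError, InsufficientInputError, IntegrityError
from duogenie.synthetic_data import GenerativeConfig, simulate_cohorts, simulate_duo_cohort


def small_cohort(seed=1, n=2000, **kwargs):
    cfg = GenerativeConfig(n_individuals=n, n_snps=2, seed=seed, **kwargs)
    return simulate_duo_cohort(cfg)


class TestStandardize:
    def test_outcomes_zscored_within_cohort(self):
        cohorts = simulate_cohorts(GenerativeConfig(n_snps=2, seed=4), sizes=(800, 400), labels=("a", "b"))
        for cohort in cohorts:
            std = standardize_outcomes(cohort)
            for col in std.outcome_columns:
                assert std.data[col].mean() == pytest.approx(0.0, abs=1e-10)
                assert std.data[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_already_standard_is_fixed_point(self):
        cohort = small_cohort()
        once = standardize_outcomes(cohort)
        twice = standardize_outcomes(once)
        for col in once.outcome_columns:
            assert np.allclose(once.data[col], twice.data[col], atol=1e-12)

    def test_ponderal_index_definition(self):
        # 3.5 kg at 0.50 m -> 28 kg/m^3
        assert ponderal_index(np.array([3.5]), np.array([0.50]))[0] == pytest.approx(28.0)

    def test_ponderal_index_derived_before_zscoring(self):
        cohort = small_cohort()
        std = standardize_outcomes(cohort)
        assert "ponderal_index" in std.data.columns
        assert "sum_skinfolds_mm" in std.data.columns

    def test_zero_variance_outcome_named(self):
        cohort = small_cohort()
        data = cohort.data.copy()
        data["birth_length_cm"] = 50.0
        broken = dataclasses.replace(cohort, data=data)
        with pytest.raises(DegenerateInputError, match="birth_length_cm"):
            standardize_outcomes(broken)

    def test_missing_values_preserved(self):
        cohort = small_cohort()
        data = cohort.data.copy()
        data.loc[:49, "birth_length_cm"] = np.nan
        std = standardize_outcomes(dataclasses.replace(cohort, data=data))
        assert std.data["birth_length_cm"].isna().sum() == 50


class TestFitSnpModel:
    def test_confounding_correction(self):
        """Unadjusted child-only fit absorbs half the maternal effect; the
        maternal-adjusted fit recovers the pure fetal effect."""
        cohort = small_cohort(seed=31, n=10_000, beta_fetal=[0.1, 0.1], beta_maternal=0.2)
        std = standardize_outcomes(cohort, outcomes=["birth_weight_sd"])
        snp = std.snp_ids[0]
        unadjusted = fit_snp_model(std, snp, "birth_weight_sd", adjust_maternal=False)
        adjusted = fit_snp_model(std, snp, "birth_weight_sd", adjust_maternal=True)
        assert unadjusted.beta == pytest.approx(0.2, abs=3 * unadjusted.se)
        assert adjusted.beta == pytest.approx(0.1, abs=3 * adjusted.se)
        assert abs(unadjusted.beta - 0.2) < abs(unadjusted.beta - 0.1)

    def test_null_type_i_error(self):
        """|beta| < 2.5 se nearly always when the SNP has no effect."""
        hits = 0
        n_rep = 60
        for r in range(n_rep):
            cohort = small_cohort(seed=4000 + r, n=2000, beta_fetal=[0.0, 0.0])
            std = standardize_outcomes(cohort, outcomes=["birth_weight_sd"])
            assoc = fit_snp_model(std, std.snp_ids[0], "birth_weight_sd")
            hits += abs(assoc.beta) < 2.5 * assoc.se
        assert hits >= int(0.95 * n_rep) - 2

    def test_sex_subsets_agree_for_sex_independent_outcome(self):
        cohort = small_cohort(seed=33, n=20_000, beta_fetal=[0.15, 0.0], sex_effect_sd=0.0)
        std = standardize_outcomes(cohort, outcomes=["birth_weight_sd"])
        snp = std.snp_ids[0]
        female = dataclasses.replace(std, data=std.data[std.data.sex == 0].reset_index(drop=True))
        male = dataclasses.replace(std, data=std.data[std.data.sex == 1].reset_index(drop=True))
        # sex is constant within a subset: drop it from the design via maternal-only adjustment
        a = fit_snp_model_no_sex(female, snp)
        b = fit_snp_model_no_sex(male, snp)
        assert a == pytest.approx(b, abs=3 * 0.02)

    def test_listwise_deletion_counted(self):
        cohort = small_cohort(seed=35)
        data = cohort.data.copy()
        data.loc[:99, "gestational_age"] = np.nan
        std = standardize_outcomes(dataclasses.replace(cohort, data=data), outcomes=["birth_weight_sd"])
        assoc = fit_snp_model(std, std.snp_ids[0], "birth_weight_sd")
        assert assoc.n_used == cohort.n - 100

    def test_constant_dosage_rank_deficient(self):
        cohort = small_cohort(seed=36)
        data = cohort.data.copy()
        data[f"c_{cohort.snp_ids[0]}"] = 1.0
        broken = standardize_outcomes(
            dataclasses.replace(cohort, data=data), outcomes=["birth_weight_sd"]
        )
        with pytest.raises(DegenerateInputError):
            fit_snp_model(broken, cohort.snp_ids[0], "birth_weight_sd")

    def test_standardization_invariance(self):
        """Rescaling an outcome by any positive constant leaves betas unchanged."""
        cohort = small_cohort(seed=37, n=3000, beta_fetal=[0.1, 0.0])
        base = standardize_outcomes(cohort, outcomes=["birth_weight_g"])
        scaled_data = cohort.data.copy()
        scaled_data["birth_weight_g"] *= 12.34
        scaled = standardize_outcomes(
            dataclasses.replace(cohort, data=scaled_data), outcomes=["birth_weight_g"]
        )
        a = fit_snp_model(base, cohort.snp_ids[0], "birth_weight_g")
        b = fit_snp_model(scaled, cohort.snp_ids[0], "birth_weight_g")
        assert a.beta == pytest.approx(b.beta, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)


def fit_snp_model_no_sex(cohort, snp_id):
    """Child-dosage coefficient without the sex covariate (constant in subsets)."""
    import statsmodels.api as sm

    frame = cohort.data[["birth_weight_sd", f"c_{snp_id}", f"m_{snp_id}", "gestational_age"]].dropna()
    X = sm.add_constant(frame.iloc[:, 1:].to_numpy())
    return float(sm.OLS(frame.iloc[:, 0].to_numpy(), X).fit().params[1])


class TestMetaAcrossCohorts:
    def make(self, cohort, beta, se, snp="rs1", outcome="bw"):
        return CohortAssoc(cohort=cohort, snp_id=snp, outcome=outcome, beta=beta, se=se, n_used=500)

    def test_closed_form(self):
        pooled, het = meta_across_cohorts([self.make("a", 0.1, 0.1), self.make("b", 0.3, 0.1)])
        assert pooled.beta == pytest.approx(0.2)
        assert pooled.se == pytest.approx(0.0707, abs=1e-4)
        assert het.q_df == 1

    def test_replication_shrinks_se(self):
        pooled, het = meta_across_cohorts([self.make("a", 0.1, 0.1), self.make("a2", 0.1, 0.1)])
        assert pooled.beta == pytest.approx(0.1)
        assert pooled.se == pytest.approx(0.1 / np.sqrt(2))
        assert het.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_mixed_inputs_rejected(self):
        with pytest.raises(IntegrityError):
            meta_across_cohorts([self.make("a", 0.1, 0.1), self.make("b", 0.1, 0.1, snp="rs2")])
        with pytest.raises(InsufficientInputError):
            meta_across_cohorts([self.make("a", 0.1, 0.1)])

    def test_homogeneous_cohorts_low_i2(self):
        """Cohorts sharing one true effect show little heterogeneity (median I² < 25)."""
        i2s = []
        for r in range(30):
            cfg = GenerativeConfig(n_snps=1, beta_fetal=[0.1], seed=6000 + r)
            cohorts = simulate_cohorts(cfg, sizes=(1500, 1000, 700, 900), labels=list("abcd"))
            assocs = [
                fit_snp_model(standardize_outcomes(c, outcomes=["birth_weight_sd"]),
                              c.snp_ids[0], "birth_weight_sd")
                for c in cohorts
            ]
            _, het = meta_across_cohorts(assocs)
            i2s.append(het.i2)
        assert np.median(i2s) < 25


class TestExclusions:
    def test_low_birthweight_rule(self):
        cohort = small_cohort(seed=40, n=500)
        data = cohort.data.copy()
        data.loc[0, "birth_weight_g"] = 2100.0
        data.loc[1:, "birth_weight_g"] = data.loc[1:, "birth_weight_g"].clip(lower=2500)
        mod = dataclasses.replace(cohort, data=data)
        kept, counts = apply_exclusions(mod, min_birthweight_g=2200.0)
        assert counts["low_birthweight"] == 1
        assert kept.n == cohort.n - 1

    def test_disabled_rules_identity(self):
        cohort = small_cohort(seed=41, n=300)
        kept, counts = apply_exclusions(
            cohort, min_birthweight_g=None, drop_multiple_births=False, max_report_discrepancy_g=None
        )
        assert kept.data.equals(cohort.data)
        assert counts == {}

    def test_report_discrepancy_rule(self):
        cohort = small_cohort(seed=42, n=300)
        data = cohort.data.copy()
        data["birth_weight_g_report2"] = data["birth_weight_g"]
        data.loc[5, "birth_weight_g_report2"] = data.loc[5, "birth_weight_g"] + 600.0
        mod = dataclasses.replace(cohort, data=data)
        kept, counts = apply_exclusions(mod, min_birthweight_g=None, max_report_discrepancy_g=500.0)
        assert counts["report_discrepancy"] == 1
        assert "id" in kept.data.columns and len(kept.data) == 299

    def test_multiple_birth_rule(self):
        cfg = GenerativeConfig(
            n_individuals=2000, n_snps=1, include_multiple_births=True,
            multiple_birth_rate=0.05, seed=43,
        )
        cohort = simulate_duo_cohort(cfg)
        kept, counts = apply_exclusions(cohort, min_birthweight_g=None)
        assert counts["multiple_birth"] == int(cohort.data["multiple_birth"].sum())
        assert kept.n == cohort.n - counts["multiple_birth"]


class TestFullRecovery:
    def test_cross_cohort_then_cross_snp_pooling_recovers_truth(self):
        """Four cohorts, 14 proportional SNPs: per-SNP fixed-effects pooling then
        random-effects pooling across SNPs recovers the mean per-allele effect,
        and the dose-response slope recovers the generating proportionality."""
        from duogenie.dose_response import fit_weighted_slope
        from duogenie.snp_pooling import pool_random

        cfg = GenerativeConfig(n_snps=14, proportionality_slope=2.0, seed=50)
        truth = cfg.resolved_beta_fetal()
        adult = cfg.resolved_adult_betas()
        cohorts = [
            standardize_outcomes(c, outcomes=["birth_weight_sd"])
            for c in simulate_cohorts(cfg, sizes=(5000, 2000, 700, 1900), labels=list("abcd"))
        ]
        per_snp = []
        for snp in cohorts[0].snp_ids:
            assocs = [fit_snp_model(c, snp, "birth_weight_sd") for c in cohorts]
            pooled, _ = meta_across_cohorts(assocs)
            per_snp.append((pooled.beta, pooled.se))
        across = pool_random(per_snp)
        assert abs(across.estimate - truth.mean()) < 2 * across.se
        fit = fit_weighted_slope(
            [(a, b, s) for a, (b, s) in zip(adult, per_snp)]
        )
        assert abs(fit.slope - 2.0) < 2 * fit.slope_se
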