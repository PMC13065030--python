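"""Linear models, ANCOVA, stratified slopes, and the count/rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

import earlygad as eg
from earlygad.cohort import GenerativeParams, RegionParams
from earlygad.stats import build_design, fit_linear_model

# ------------------------------------------------------------- linear model


class TestFitLinearModel:
    def test_exact_data_recovered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"intercept": 1.0, "a": rng.random(30), "b": rng.random(30)}
        )
        beta = np.array([2.0, -1.5, 0.7])
        y = X.values @ beta
        fit = fit_linear_model(X, y)
        assert np.allclose(fit.estimates, beta, atol=1e-10)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self):
        """Estimates and standard errors agree with a direct normal-equations
        solve on a random 20×3 design."""
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((20, 3)), columns=["x0", "x1", "x2"])
        y = rng.random(20)
        fit = fit_linear_model(X, y)
        Xm = X.values
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        resid = y - Xm @ beta
        s2 = resid @ resid / (20 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(Xm.T @ Xm)))
        tvals = beta / se
        pvals = 2 * sps.t.sf(np.abs(tvals), 20 - 3)
        assert np.allclose(fit.estimates, beta, atol=1e-10)
        assert np.allclose(fit.standard_errors, se, atol=1e-10)
        assert np.allclose(fit.p_values, pvals, atol=1e-12)

    def test_intercept_only_gives_sample_mean(self):
        y = np.array([1.0, 2.0, 6.0, 7.0])
        fit = fit_linear_model(pd.DataFrame({"intercept": np.ones(4)}), y)
        assert fit.estimates[0] == pytest.approx(y.mean())

    def test_rank_deficiency_names_offender(self):
        X = pd.DataFrame({"intercept": np.ones(10), "dup": np.ones(10)})
        with pytest.raises(ValueError, match="dup|intercept"):
            fit_linear_model(X, np.arange(10.0))


# ------------------------------------------------------------------ ANCOVA


def _cohort(params, n_day, n_night, seed):
    return eg.generate_cohort(params, n_day=n_day, n_night=n_night, seed=seed)


def _one_region(mu_day, mu_night, beta_day, beta_night, sd):
    return GenerativeParams(
        regions={"cerebral_cortex": RegionParams(mu_day, mu_night, beta_day, beta_night, sd)}
    )


class TestAncova:
    def test_reduces_to_t_test_without_covariate_variation(self):
        """With constant age/sex/diagnosis the adjusted model is exactly the
        pooled two-sample t-test."""
        rng = np.random.default_rng(2)
        n = 60
        cohort = pd.DataFrame(
            {
                "age": 63.0,
                "sex": "female",
                "diagnosis": "IPD",
                "scan_period": ["day"] * n + ["night"] * n,
                "cerebral_cortex": np.concatenate(
                    [rng.normal(-166, 20, n), rng.normal(-161, 20, n)]
                ),
            }
        )
        p_ancova = eg.ancova_group_pvalue(cohort, "cerebral_cortex")
        day = cohort[cohort.scan_period == "day"].cerebral_cortex
        night = cohort[cohort.scan_period == "night"].cerebral_cortex
        p_t = sps.ttest_ind(day, night, equal_var=True).pvalue
        assert p_ancova == pytest.approx(p_t, abs=1e-6)

    def test_detects_day_night_gap_at_study_size(self):
        """Power above 0.5 for the reported cortical day−night gap
        (−166.4 vs −160.9 ms) at the study's 307/140 split."""
        params = _one_region(-166.4, -160.9, 0.0, 0.0, 22.0)
        hits = 0
        reps = 60
        for r in range(reps):
            cohort = _cohort(params, 307, 140, seed=100 + r)
            if eg.ancova_group_pvalue(cohort, "cerebral_cortex") < 0.05:
                hits += 1
        assert hits / reps > 0.5

    def test_adjusts_for_diagnosis_confounding(self):
        """A pure diagnosis effect with period-imbalanced diagnosis mix must
        not masquerade as a period effect."""
        params = GenerativeParams(
            regions={"cerebral_cortex": RegionParams(-160.0, -160.0, 0.0, 0.0, 5.0)},
            diagnosis_offsets={
                d: (-30.0 if d == "IPD" else 0.0) for d in eg.DIAGNOSES
            },
        )
        reject = 0
        reps = 40
        for r in range(reps):
            cohort = _cohort(params, 250, 250, seed=300 + r)
            if eg.ancova_group_pvalue(cohort, "cerebral_cortex") < 0.05:
                reject += 1
        # unadjusted comparison would reject nearly always here
        assert reject / reps < 0.15

    def test_single_period_rejected(self):
        cohort = _cohort(GenerativeParams(), 30, 0, seed=1)
        with pytest.raises(ValueError, match="day and night"):
            eg.ancova_group_pvalue(cohort, "cerebral_cortex")

    def test_reference_level_relabeling_invariance(self):
        """The period p-value does not depend on which diagnosis class is
        the treatment-coding reference."""
        cohort = _cohort(GenerativeParams(), 120, 80, seed=11)
        pvals = []
        for ref in ("Other", "IPD", "ET"):
            design = build_design(cohort, period=True, diagnosis_reference=ref)
            fit = fit_linear_model(design, cohort["cerebral_cortex"])
            pvals.append(fit.coefficient("period[day]")["p"])
        assert pvals[0] == pytest.approx(pvals[1], abs=1e-10)
        assert pvals[0] == pytest.approx(pvals[2], abs=1e-10)


class TestAgeSlopes:
    def test_noiseless_slope_recovered_exactly(self):
        params = _one_region(-166.4, -160.9, -0.47, -0.34, 0.0)
        cohort = _cohort(params, 100, 60, seed=3)
        beta, _ = eg.age_slope_by_period(cohort, "cerebral_cortex", "day")
        assert beta == pytest.approx(-0.47, abs=1e-10)
        beta_n, _ = eg.age_slope_by_period(cohort, "cerebral_cortex", "night")
        assert beta_n == pytest.approx(-0.34, abs=1e-10)

    def test_zero_slope_with_offsets_still_zero(self):
        """Nonzero sex/diagnosis offsets do not leak into the age slope."""
        params = GenerativeParams(
            regions={"cerebral_cortex": RegionParams(-160.0, -160.0, 0.0, 0.0, 0.0)},
            sex_offsets={"male": 0.0, "female": 8.0},
            diagnosis_offsets={d: i * 3.0 for i, d in enumerate(eg.DIAGNOSES)},
        )
        cohort = _cohort(params, 120, 60, seed=4)
        beta, _ = eg.age_slope_by_period(cohort, "cerebral_cortex", "day")
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_small_stratum_rejected(self):
        cohort = _cohort(GenerativeParams(), 30, 5, seed=5)
        with pytest.raises(ValueError, match="minimum 10"):
            eg.age_slope_by_period(cohort, "cerebral_cortex", "night")

    def test_mean_recovered_slope_within_tolerance(self):
        """Monte-Carlo slope recovery: the mean fitted daytime β over 20
        replicate cohorts is within 0.1 ms/year of the generative −0.47."""
        params = _one_region(-166.4, -160.9, -0.47, -0.34, 22.0)
        betas = [
            eg.age_slope_by_period(
                _cohort(params, 307, 140, seed=500 + r), "cerebral_cortex", "day"
            )[0]
            for r in range(20)
        ]
        assert np.mean(betas) == pytest.approx(-0.47, abs=0.1)


class TestInteraction:
    def test_equal_slopes_noiseless_coefficient_zero(self):
        params = _one_region(-166.4, -160.9, -0.47, -0.47, 0.0)
        cohort = _cohort(params, 80, 60, seed=6)
        design = build_design(cohort, period=True, interaction=True)
        fit = fit_linear_model(design, cohort["cerebral_cortex"])
        assert fit.coefficient("age:period[day]")["estimate"] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_power_for_one_ms_per_year_slope_difference(self):
        """Slopes differing by 1.0 ms/year at study size are detected with
        power > 0.8."""
        params = _one_region(-166.4, -160.9, -1.0, 0.0, 22.0)
        hits = sum(
            eg.interaction_pvalue(_cohort(params, 307, 140, seed=700 + r), "cerebral_cortex") < 0.05
            for r in range(30)
        )
        assert hits / 30 > 0.8


# --------------------------------------------------------- rank / count tests


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = eg.mann_whitney_u(x, x)
        assert p >= 0.99

    def test_exact_small_sample_matches_enumeration_oracle(self):
        """Exhaustive enumeration over all rank assignments (5 vs 5)."""
        x = np.array([1.2, 3.4, 0.5, 7.7, 2.2])
        y = np.array([4.1, 8.0, 6.3, 5.5, 9.9])
        u_obs, p = eg.mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        center = len(x) * len(y) / 2
        count = 0
        total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            ranks = sps.rankdata(pooled)
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_large_shift_reaches_floor(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 40)
        _, p_shift = eg.mann_whitney_u(x, x + 100.0)
        assert p_shift < 1e-9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            eg.mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_sex_by_period_table_with_yates(self):
        """The day/night sex table [[140, 59], [167, 81]] gives p = 0.562
        with continuity correction."""
        assert eg.chi_square_pvalue([[140, 59], [167, 81]], yates=True) == pytest.approx(
            0.562, abs=0.005
        )

    def test_diagnosis_by_period_table(self):
        table = [[84, 64], [64, 17], [39, 13], [10, 3], [7, 3], [103, 40]]
        assert eg.chi_square_pvalue(table, yates=False) == pytest.approx(
            0.007, abs=0.002
        )

    def test_independent_table_gives_p_one(self):
        # exactly proportional to its margins -> statistic 0
        table = np.outer([10, 20, 30], [4, 6]) / 10.0
        assert eg.chi_square_pvalue(table, yates=False) == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            eg.chi_square_pvalue([[0, 0], [5, 3]])


class TestFisher:
    def test_pairwise_bonferroni_reproduces_adjusted_p(self):
        """The IPD-vs-ET diagnosis contrast with 15 pairwise comparisons
        lands on the reported adjusted p ≈ 0.013."""
        table = [[84, 64], [64, 17], [39, 13], [10, 3], [7, 3], [103, 40]]
        res = eg.pairwise_fisher_bonferroni(
            table, ["IPD", "ET", "MSA", "PSP", "VaP", "Other"]
        )
        row = res[(res.row_a == "IPD") & (res.row_b == "ET")].iloc[0]
        assert row.p_adjusted == pytest.approx(0.013, abs=0.002)
        assert (res.p_adjusted <= 1.0).all()

    def test_symmetric_table_raw_p_one(self):
        assert eg.fisher_exact_pvalue([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_oracle(self):
        """Two-sided point-probability Fisher p equals exhaustive
        enumeration of all tables with the observed margins."""
        tables = [([3, 7], [8, 2]), ([5, 1], [2, 6]), ([4, 4], [4, 4]), ([9, 1], [1, 9])]
        for a, b in tables:
            obs = np.array([a, b])
            p_impl = eg.fisher_exact_pvalue(obs)
            r1, r2 = obs.sum(axis=1)
            c1 = obs[:, 0].sum()
            n = obs.sum()

            def point_prob(x):
                return (
                    comb(r1, x, exact=True)
                    * comb(r2, c1 - x, exact=True)
                    / comb(n, c1, exact=True)
                )

            p_obs = point_prob(obs[0, 0])
            lo, hi = max(0, c1 - r2), min(r1, c1)
            p_oracle = sum(
                point_prob(x)
                for x in range(lo, hi + 1)
                if point_prob(x) <= p_obs * (1 + 1e-12)
            )
            assert p_impl == pytest.approx(p_oracle, abs=1e-10)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            eg.fisher_exact_pvalue([[1, 2, 3], [4, 5, 6]])


class TestRegionalStatsTable:
    def test_full_table_runs_on_default_cohort(self, default_cohort):
        table = eg.regional_stats_table(default_cohort)
        assert set(table.region) == set(eg.REGIONS)
        for col in ("ancova_period_p", "interaction_p"):
            assert table[col].between(0, 1).all()
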