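"""Normality gating, omnibus and pairwise comparisons, exactness oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pdsubtypes import (
    CohortSpec,
    ComparisonResult,
    default_profiles,
    generate_cohort,
    ks_normality,
    mann_whitney_exact,
    omnibus,
    pairwise,
    validate_solution,
)


class TestKsNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])

    def test_constant_sample_reported_non_normal(self):
        result = ks_normality([2.0] * 10)
        assert result.p_value == 0.0 and result.significant

    def test_nominal_level_under_normal_null(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            ks_normality(rng.normal(size=300)).significant for _ in range(200)
        )
        assert rejections / 200 <= 0.10

    def test_power_against_uniform(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            ks_normality(rng.uniform(size=1000)).significant for _ in range(40)
        )
        assert rejections == 40


class TestOmnibus:
    def test_identical_groups_yield_null_result(self):
        result = omnibus([[1, 1, 1], [1, 1, 1], [1, 1, 1]], parametric=False)
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(1, 1, size=25)
        f_result = omnibus([a, b], parametric=True)
        t_result = pairwise(a, b, parametric=True)
        assert f_result.statistic == pytest.approx(t_result.statistic**2)
        assert f_result.p_value == pytest.approx(t_result.p_value)

    def test_kruskal_wallis_statistic_from_rank_formula(self):
        """Tie-corrected H matches a directly coded rank-sum expression."""
        groups = [[1.0, 3.0, 5.0], [2.0, 2.0, 6.0], [4.0, 7.0, 8.0]]
        result = omnibus(groups, parametric=False)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start:start + len(g)]
            h += len(g) * (r.mean() - (n + 1) / 2) ** 2
            start += len(g)
        h *= 12 / (n * (n + 1))
        _, ties = np.unique(pooled, return_counts=True)
        h /= 1 - np.sum(ties**3 - ties) / (n**3 - n)
        assert result.statistic == pytest.approx(h)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            omnibus([[1, 2], []], parametric=True)


class TestPairwise:
    def test_textbook_exact_case(self):
        result = pairwise([1, 2], [3, 4], parametric=False)
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1 / 3)

    def test_identical_samples_parametric(self):
        result = pairwise([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], parametric=True)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_exact_matches_scipy_enumeration_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = pooled[:n1], pooled[n1:]
            u, p = mann_whitney_exact(a, b)
            ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert p == pytest.approx(ref.pvalue)
            assert u == min(ref.statistic, n1 * n2 - ref.statistic)

    def test_exact_handles_ties_via_midranks(self):
        u, p = mann_whitney_exact([1, 1, 2], [2, 3, 3])
        # oracle: count arrangements by explicit permutation of group masks
        pooled = np.array([1, 1, 2, 2, 3, 3], float)
        ranks = sps.rankdata(pooled)
        mu = 9 / 2
        obs = abs(ranks[:3].sum() - 6 - mu)
        hits = total = 0
        for mask in itertools.combinations(range(6), 3):
            u1 = ranks[list(mask)].sum() - 6
            total += 1
            hits += abs(u1 - mu) >= obs - 1e-12
        assert p == pytest.approx(hits / total)

    def test_two_sample_kruskal_equals_mann_whitney_without_ties(self):
        rng = np.random.default_rng(4)
        a = rng.permutation(np.arange(1.0, 31.0))[:14]
        b = np.setdiff1d(np.arange(1.0, 31.0), a)
        kw = omnibus([a, b], parametric=False)
        mw = pairwise(a, b, parametric=False)
        assert kw.p_value == pytest.approx(mw.p_value, abs=1e-6)

    def test_type_one_error_near_nominal_level(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a, b = rng.normal(size=(2, 200))
            rejections += pairwise(a, b, parametric=False).significant
        assert 0.03 <= rejections / reps <= 0.07

    def test_p_values_in_unit_interval(self):
        with pytest.raises(ValueError):
            ComparisonResult("x", "t", 0.0, 1.5)


class TestValidateSolution:
    def test_separated_profiles_significant_everywhere(self):
        cohort = generate_cohort(CohortSpec(n=500, seed=6))
        labels = [r.latent_cluster for r in cohort]
        report = validate_solution(cohort, labels)
        assert [e.variable for e in report.entries] == [
            "age", "disease_duration", "hy_stage", "pdq39_cognition",
        ]
        for entry in report.entries:
            assert entry.omnibus.significant
            assert len(entry.pairwise) == 6  # all subgroup pairs
        frame = report.to_frame()
        assert frame.attrs["multiple_testing_correction"].startswith("none")

    def test_null_profiles_reject_near_alpha(self):
        import dataclasses

        yo = default_profiles()[0]
        clones = [dataclasses.replace(yo, label=lab, weight=0.25)
                  for lab in ("YO", "TD", "NTD", "RDP")]
        rejections = trials = 0
        for seed in range(40):
            cohort = generate_cohort(CohortSpec(n=160, seed=seed, profiles=clones))
            labels = [r.latent_cluster for r in cohort]
            report = validate_solution(cohort, labels)
            for entry in report.entries:
                trials += 1
                rejections += entry.omnibus.significant
        assert 0.005 <= rejections / trials <= 0.12

    def test_single_subgroup_rejected(self, cohort209):
        with pytest.raises(ValueError):
            validate_solution(cohort209, ["ALL"] * len(cohort209))
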