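"""Agreement metrics, grading, and the comparison-test battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pttbp.simulate import CohortGroupSpec, simulate_cohort
from pttbp.stats import (
    agreement_metrics,
    compare_groups,
    ieee_grade,
    ks_normality,
    mann_whitney_u,
    t_test_two_sample,
    wilcoxon_signed_rank,
)


class TestAgreement:
    def test_perfect_agreement(self):
        rep = agreement_metrics([70, 80, 90], [70, 80, 90])
        assert (rep.mad, rep.rmse, rep.bias) == (0.0, 0.0, 0.0)
        assert rep.pcc == pytest.approx(1.0)

    def test_constant_offset(self):
        rep = agreement_metrics([72, 82, 92], [70, 80, 90])
        assert rep.mad == pytest.approx(2.0)
        assert rep.rmse == pytest.approx(2.0)
        assert rep.bias == pytest.approx(2.0)
        assert rep.loa_width == pytest.approx(0.0)

    def test_hand_computed_example(self):
        rep = agreement_metrics([70, 80, 90, 100], [72, 77, 91, 98])
        assert rep.mad == pytest.approx(2.0)
        assert rep.rmse == pytest.approx(math.sqrt((4 + 9 + 1 + 4) / 4), abs=1e-9)

    def test_mad_never_exceeds_rmse(self, rng):
        for _ in range(30):
            est, ref = rng.normal(90, 10, 25), rng.normal(90, 10, 25)
            rep = agreement_metrics(est, ref)
            assert rep.mad <= rep.rmse + 1e-12
            assert rep.loa_low <= rep.bias <= rep.loa_high

    def test_constant_side_flags_undefined_pcc(self):
        rep = agreement_metrics([80.0, 80.0, 80.0], [70.0, 80.0, 90.0])
        assert not rep.pcc_defined


class TestIeeeGrade:
    @pytest.mark.parametrize(
        "mad,grade", [(2.90, "A"), (5.0, "A"), (5.36, "B"), (6.5, "C"), (10.0, "D")]
    )
    def test_grading_table(self, mad, grade):
        assert ieee_grade(mad) == grade

    def test_monotone_non_improving(self):
        grades = [ieee_grade(m) for m in np.linspace(0, 12, 60)]
        assert grades == sorted(grades)

    def test_negative_mad_rejected(self):
        with pytest.raises(ValueError):
            ieee_grade(-1.0)


def _exact_mwu_p(x, y):
    """Oracle: exhaustively enumerate all rank assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    n_total = 0
    n_extreme = 0
    mean_u = nx * len(y) / 2
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = sum(sorted(ranks.values())[i] for i in combo) - nx * (nx + 1) / 2
        n_total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


def _exact_wsr_p(d):
    """Oracle: enumerate all 2^n sign patterns of the absolute differences."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    n_extreme = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            n_extreme += 1
    return n_extreme / 2 ** len(d)


class TestMannWhitney:
    def test_separated_samples_anchor(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert _exact_mwu_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(15):
            nx, ny = rng.integers(2, 6), rng.integers(2, 6)
            pooled = rng.permutation(rng.normal(size=nx + ny))
            x, y = pooled[:nx], pooled[nx:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(_exact_mwu_p(x, y), abs=1e-12)

    def test_identical_multisets_symmetric(self):
        _, p = mann_whitney_u([3.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_approximation_close_to_exact(self, rng):
        from scipy import stats as sps

        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(0.5, 1, size=6)
            _, p_exact = mann_whitney_u(x, y)
            p_approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert abs(p_exact - p_approx) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_anchor(self):
        _, p = wilcoxon_signed_rank([1, 2, 3])
        assert p == pytest.approx(0.25)
        assert _exact_wsr_p([1, 2, 3]) == pytest.approx(0.25)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(10):
            d = rng.normal(0.3, 1.0, int(rng.integers(4, 9)))
            d = d[d != 0]
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(_exact_wsr_p(d), abs=1e-12)

    def test_antisymmetry(self, rng):
        d = rng.normal(size=8)
        assert wilcoxon_signed_rank(d)[1] == pytest.approx(wilcoxon_signed_rank(-d)[1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])


class TestKsNormality:
    def test_gaussian_usually_passes(self):
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=1000)
            passes += ks_normality(x)[2]
        assert passes >= 90

    def test_bimodal_fails(self, rng):
        x = np.concatenate([rng.normal(-5, 1, 500), rng.normal(5, 1, 500)])
        assert ks_normality(x)[2] is False

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.full(10, 3.0))

    def test_lilliefors_is_stricter(self, rng):
        x = rng.normal(size=200)
        _, p_std, _ = ks_normality(x)
        _, p_lil, _ = ks_normality(x, lilliefors=True)
        assert p_lil <= p_std + 0.05


class TestTTest:
    def test_cohort_height_summary(self):
        """Anchored worked example: cohort height summaries give p ~ .19."""
        _, p = t_test_two_sample(173.9, 9.6, 26, 169.6, 11.5, 18)
        assert round(p, 2) == 0.19

    def test_cohort_age_summary(self):
        _, p = t_test_two_sample(26.7, 3.7, 26, 44.1, 11.7, 18)
        assert p < 0.001

    def test_equal_summaries(self):
        t, p = t_test_two_sample(10.0, 2.0, 12, 10.0, 2.0, 12)
        assert t == 0.0
        assert p == pytest.approx(1.0)


def _coef_table(rng, k1_a, k1_b, n=20, sd=0.3):
    rows = []
    for g, k1_mean, bmi in (("a", k1_a, 23.0), ("b", k1_b, 36.0)):
        for i in range(n):
            rows.append(
                {
                    "participant_id": f"{g}{i}",
                    "K1_DBP": rng.normal(k1_mean, sd),
                    "K2_DBP": rng.normal(62, 5),
                    "bmi": rng.normal(bmi, 2.0),
                    "sex": "male",
                    "race": "other",
                    "age": 30.0,
                }
            )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_routing_and_report_fields(self, rng):
        cmp = compare_groups(_coef_table(rng, 2.4, 1.2), "obesity", "K1_DBP")
        assert cmp.test == "mann_whitney_u"
        assert cmp.group_names == ("nonobese", "obese")
        assert cmp.group_n[0] >= 3 and cmp.group_n[1] >= 3
        assert 0 <= cmp.p <= 1

    def test_large_effect_detected(self, rng):
        detected = sum(
            compare_groups(_coef_table(rng, 2.4, 1.2), "obesity", "K1_DBP").significant
            for _ in range(10)
        )
        assert detected == 10

    def test_age_boundary_goes_to_older(self):
        row = pd.Series({"age": 40.0, "bmi": 25.0, "sex": "male", "race": "other"})
        from pttbp.stats import _assign_group

        assert _assign_group(row, "age") == "older"

    def test_min_group_size_enforced(self, rng):
        table = _coef_table(rng, 2.0, 2.0, n=2)
        with pytest.raises(ValueError, match="participants per group"):
            compare_groups(table, "obesity", "K1_DBP")

    def test_cohort_groups_separated_by_construction(self):
        specs = [
            CohortGroupSpec(name="lean", k1_dbp_mean=2.4, k1_dbp_sd=0.3, bmi_mean=23, bmi_sd=2),
            CohortGroupSpec(name="obese", k1_dbp_mean=1.2, k1_dbp_sd=0.3, bmi_mean=36, bmi_sd=2),
        ]
        _, table, _ = simulate_cohort(specs, 20, seed=9, signals=False)
        cmp = compare_groups(table, "obesity", "K1_DBP")
        assert cmp.significant
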