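import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest

from promatch.errors import InputError, PreconditionError
from promatch.outcomes import (classify_improvement, cohen_d_from_proportions,
                               compare_outcomes, compute_mcid, mann_whitney_rbc,
                               mcnemar, nnt_from_d)


def pair_count_u(t, c):
    """Exhaustive U oracle: pairs with t > c plus half the ties."""
    return sum((1.0 if x > y else 0.5 if x == y else 0.0)
               for x in t for y in c)


def permutation_two_sided_p(t, c):
    """Exact permutation p for untied data: symmetric tail mass of U."""
    pooled = list(t) + list(c)
    n1 = len(t)
    center = n1 * len(c) / 2.0
    obs = abs(pair_count_u(t, c) - center)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        tt = [pooled[i] for i in comb]
        cc = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(pair_count_u(tt, cc) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_complete_separation(self):
        u, p, rbc = mann_whitney_rbc([4, 5, 6], [1, 2, 3])
        assert u == 9 and rbc == 1.0

    def test_identical_groups(self):
        u, p, rbc = mann_whitney_rbc([1, 2, 3], [1, 2, 3])
        assert rbc == 0.0

    def test_interleaved_example(self):
        # pairs with t > c: (3,2), (5,2), (5,4) -> U = 3, rbc = 0
        u, p, rbc = mann_whitney_rbc([1, 3, 5], [2, 4])
        assert u == pair_count_u([1, 3, 5], [2, 4]) == 3
        assert rbc == 0.0

    def test_all_tied_degenerate(self):
        u, p, rbc = mann_whitney_rbc([7, 7], [7, 7, 7])
        assert (u, p, rbc) == (3.0, 1.0, 0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_u_matches_pair_count_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
        c = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
        u, _, rbc = mann_whitney_rbc(t, c)
        assert math.isclose(u, pair_count_u(t, c))
        assert -1.0 <= rbc <= 1.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_exact_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7, size=2)
        pooled = rng.permutation(np.arange(n1 + n2, dtype=float))  # no ties
        t, c = pooled[:n1], pooled[n1:]
        _, p, _ = mann_whitney_rbc(t, c)
        assert math.isclose(p, permutation_two_sided_p(t, c), rel_tol=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_u_complement_and_rbc_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=rng.integers(2, 20))
        c = rng.normal(size=rng.integers(2, 20))
        ut, _, rt = mann_whitney_rbc(t, c)
        uc, _, rc = mann_whitney_rbc(c, t)
        assert math.isclose(ut + uc, len(t) * len(c))
        assert math.isclose(rt, -rc, abs_tol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_rbc([], [1.0])


class TestMCID:
    def test_constant_baselines_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert compute_mcid([30.0, 30.0, 30.0]) == 0.0

    def test_half_sd_convention(self):
        # two-point samples with sample SD exactly 7.70 and 12.54
        a = 7.70 / math.sqrt(2.0)
        assert math.isclose(compute_mcid([32.10 - a, 32.10 + a]), 3.85)
        b = 12.54 / math.sqrt(2.0)
        assert math.isclose(compute_mcid([49.69 - b, 49.69 + b]), 6.27)

    def test_requires_two_scores(self):
        with pytest.raises(PreconditionError):
            compute_mcid([5.0])


class TestClassifyImprovement:
    def test_boundary_is_strict(self):
        flags = classify_improvement([0.0], [3.85], mcid=3.85)
        assert flags.iloc[0] == False  # noqa: E712  (exactly MCID: not improved)

    def test_zero_mcid_any_gain_counts(self):
        flags = classify_improvement([30.0], [30.01], mcid=0.0)
        assert flags.iloc[0] == True  # noqa: E712

    def test_six_pair_fixture(self):
        pre = [30.0, 40.0, 25.0, 50.0, 35.0, 45.0]
        post = [36.0, 41.0, 24.0, 53.9, 39.0, 45.0]
        flags = classify_improvement(pre, post, mcid=3.85)
        # hand evaluation: +6.0 yes, +1.0 no, -1.0 no, +3.9 yes, +4.0 yes? ->
        # +4.0 > 3.85 yes; recount: improvements are rows 0, 3, 4
        assert flags.tolist() == [True, False, False, True, True, False]

    def test_missing_scores_excluded(self):
        flags = classify_improvement([30.0, np.nan], [40.0, 50.0], mcid=1.0)
        assert flags.iloc[0] == True  # noqa: E712
        assert pd.isna(flags.iloc[1])


class TestMcNemar:
    def test_equal_discordants_hand_value(self):
        t = [True] * 10 + [False] * 10
        c = [False] * 10 + [True] * 10
        chi2, p, b, c_ = mcnemar(t, c)
        assert (b, c_) == (10, 10)
        assert math.isclose(chi2, 1 / 20)

    def test_unequal_discordants_hand_value(self):
        t = [True] * 10 + [False] * 2
        c = [False] * 10 + [True] * 2
        chi2, _, b, c_ = mcnemar(t, c)
        assert (b, c_) == (10, 2)
        assert math.isclose(chi2, 49 / 12)

    def test_no_discordant_pairs(self):
        chi2, p, b, c = mcnemar([True, False], [True, False])
        assert p == 1.0 and (b, c) == (0, 0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        t = [True] * 30 + [False] * 12 + [True] * 5 + [False] * 3
        c = [False] * 30 + [True] * 12 + [True] * 5 + [False] * 3
        chi2, p, b, c_ = mcnemar(t, c)
        table = [[5, 30], [12, 3]]
        ref = sm_mcnemar(table, exact=False, correction=True)
        assert math.isclose(chi2, ref.statistic)
        assert math.isclose(p, ref.pvalue)

    # b == c is excluded: there the corrected statistic is 1/(b+c) by
    # construction while the exact binomial p is 1
    @pytest.mark.parametrize("b,c", [(13, 12), (20, 8), (26, 24), (40, 15),
                                     (30, 0), (18, 9)])
    def test_near_exact_binomial_oracle(self, b, c):
        """Continuity-corrected chi-square p within 0.02 of the exact
        binomial(b+c, 1/2) two-sided p for b+c >= 25."""
        assert b + c >= 25
        t = [True] * b + [False] * c
        cc = [False] * b + [True] * c
        _, p, *_ = mcnemar(t, cc)
        exact = binomtest(b, b + c, 0.5).pvalue
        assert abs(p - exact) < 0.02


class TestEffectSizeChain:
    def test_equal_proportions_zero(self):
        assert cohen_d_from_proportions(0.4, 0.4) == 0.0

    def test_physical_improvement_d(self):
        d = cohen_d_from_proportions(226 / 359, 197 / 359)
        assert round(d, 2) == 0.16

    def test_mental_improvement_d_magnitude(self):
        d = cohen_d_from_proportions(83 / 359, 93 / 359)
        assert round(abs(d), 2) == 0.06

    def test_degenerate_proportions_nan(self):
        assert math.isnan(cohen_d_from_proportions(0.0, 1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(PreconditionError):
            cohen_d_from_proportions(1.2, 0.5)

    def test_nnt_limits(self):
        assert math.isclose(nnt_from_d(10.0), 1.0, abs_tol=1e-9)
        assert math.isinf(nnt_from_d(0.0))

    def test_nnt_from_printed_proportions(self):
        d_phys = cohen_d_from_proportions(226 / 359, 197 / 359)
        assert round(nnt_from_d(d_phys), 1) == pytest.approx(10.8, abs=0.11)
        d_ment = cohen_d_from_proportions(83 / 359, 93 / 359)
        assert round(nnt_from_d(d_ment), 1) == pytest.approx(27.4, abs=0.2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.01, 5.0), st.floats(0.001, 1.0))
    def test_nnt_strictly_decreasing_in_magnitude(self, d, eps):
        assert nnt_from_d(d + eps) < nnt_from_d(d)
        assert nnt_from_d(d) >= 1.0
        assert nnt_from_d(-d) == nnt_from_d(d)


class TestCompareOutcomes:
    def _matched_frame(self, shift=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        pre = rng.uniform(25, 45, 2 * n)
        post = pre + rng.normal(8, 4, 2 * n)
        post[:n] += shift
        df = pd.DataFrame({
            "patient_id": [f"T{i}" for i in range(n)] + [f"C{i}" for i in range(n)],
            "sf12_physical_pre": pre, "sf12_physical_3m": post,
            "sf12_mental_pre": pre, "sf12_mental_3m": post,
        })
        pairs = [(f"T{i}", f"C{i}") for i in range(n)]
        return df, pairs

    def test_identical_groups_null_result(self):
        df, pairs = self._matched_frame()
        # make control block an exact copy of the treated block
        n = len(pairs)
        for col in ["sf12_physical_pre", "sf12_physical_3m",
                    "sf12_mental_pre", "sf12_mental_3m"]:
            df.loc[n:, col] = df.loc[:n - 1, col].to_numpy()
        res = compare_outcomes(df, pairs)
        for comp in res.values():
            assert comp.rbc == 0.0
            assert comp.mw_p == 1.0 or comp.mw_p > 0.99
            assert comp.cohen_d == 0.0
            assert comp.mcnemar_p == 1.0

    def test_positive_effect_detected_at_large_n(self):
        df, pairs = self._matched_frame(shift=4.0, n=800, seed=7)
        res = compare_outcomes(df, pairs)
        comp = res["sf12_physical"]
        assert comp.rbc > 0
        assert comp.prop_t > comp.prop_c
        assert comp.nnt_favors == "treated"
        assert comp.mw_p < 0.01

    def test_mcid_override_used(self):
        df, pairs = self._matched_frame(n=30, seed=3)
        res = compare_outcomes(df, pairs, mcid_values={
            "sf12_physical": 2.0, "sf12_mental": 2.0})
        assert res["sf12_physical"].mcid == 2.0

    def test_invariants_on_default_run(self, default_pipeline_result):
        for comp in default_pipeline_result.outcomes.values():
            assert 0 <= comp.mw_u <= comp.n_t * comp.n_c
            assert -1 <= comp.rbc <= 1
            assert 0 <= comp.prop_t <= 1 and 0 <= comp.prop_c <= 1
            if math.isfinite(comp.nnt):
                assert comp.nnt >= 1
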