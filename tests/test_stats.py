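import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselrep import (
    PairedSample,
    bland_altman,
    describe,
    normality_screen,
    normalized_loa_pct,
    paired_wilcoxon,
    permutation_variance_test,
)
from vesselrep.exceptions import InsufficientDataError, InvalidParameterError
from vesselrep.stats import tukey_hinges


def brute_force_resplit_p(g, u):
    """Independent oracle: enumerate every split of the pooled differences."""
    pool = np.concatenate([g, u])
    n = len(g)
    r_obs = np.var(g, ddof=1) / np.var(u, ddof=1)
    count = total = 0
    for comb in itertools.combinations(range(len(pool)), n):
        rest = [i for i in range(len(pool)) if i not in comb]
        r = np.var(pool[list(comb)], ddof=1) / np.var(pool[rest], ddof=1)
        count += r >= r_obs - 1e-12 * max(1.0, abs(r_obs))
        total += 1
    return count / total


class TestDescribe:
    def test_tukey_hinges_small_sample(self):
        assert describe([1, 2, 3, 4, 5]) == {"median": 3.0, "iqr": 2.0, "n": 5}
        assert tukey_hinges([1, 2, 3, 4, 5]) == (2.0, 4.0)

    def test_constant_and_singleton(self):
        assert describe([4.0, 4.0, 4.0])["iqr"] == 0.0
        assert describe([7.0]) == {"median": 7.0, "iqr": 0.0, "n": 1}

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            describe([])


class TestNormalityScreen:
    def test_calibration_on_normal_samples(self):
        rng = np.random.default_rng(0)
        passes = sum(
            normality_screen(rng.standard_normal(50))["p"] > 0.05 for _ in range(100)
        )
        assert passes >= 90

    def test_power_on_lognormal_samples(self):
        rng = np.random.default_rng(1)
        rejects = sum(
            normality_screen(np.exp(rng.standard_normal(50)))["p"] < 0.05
            for _ in range(100)
        )
        assert rejects >= 90

    def test_constant_vector_not_applicable(self):
        res = normality_screen([2.0, 2.0, 2.0, 2.0])
        assert res["applicable"] is False and math.isnan(res["p"])


class TestPairedWilcoxon:
    def test_identical_vectors_degenerate(self):
        x = np.arange(8.0)
        assert paired_wilcoxon(x, x)["p"] == 1.0

    def test_extreme_shift_reaches_exact_floor(self):
        x = np.arange(1.0, 14.0)
        res = paired_wilcoxon(x, x + 10.0)
        assert res["p"] == pytest.approx(2.0 / 2**13, rel=1e-9)

    def test_balanced_antisymmetric_differences(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        y = np.array([-3.0, 3.0, -2.0, 2.0, -1.0, 1.0])
        assert paired_wilcoxon(x, y)["p"] == 1.0


class TestBlandAltman:
    def _sample(self, r1, r2):
        return PairedSample("m", tuple(r1), tuple(r2))

    def test_identical_repeats(self):
        s = self._sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = bland_altman(s)
        assert res.bias == 0.0 and res.loa_range == 0.0

    def test_alternating_differences(self):
        r2 = [5.0, 5.0, 5.0, 5.0]
        r1 = [6.0, 4.0, 6.0, 4.0]
        res = bland_altman(self._sample(r1, r2))
        assert res.bias == pytest.approx(0.0)
        assert res.loa_range == pytest.approx(2 * 1.96 * 1.1547005, abs=1e-4)

    def test_published_percentage_arithmetic(self):
        assert normalized_loa_pct(6.7, 12.8) == pytest.approx(52.34375, rel=1e-12)

    def test_bias_sign_convention_is_repeat1_minus_repeat2(self):
        res = bland_altman(self._sample([2.0, 2.0, 2.0], [1.0, 1.0, 1.0]))
        assert res.bias == pytest.approx(1.0)

    def test_loa_invariant_to_common_offset(self):
        r1 = [3.0, 5.0, 4.0, 6.0]
        r2 = [2.5, 5.5, 3.5, 6.5]
        a = bland_altman(self._sample(r1, r2))
        b = bland_altman(self._sample([v + 10 for v in r1], [v + 10 for v in r2]))
        assert a.loa_range == pytest.approx(b.loa_range, rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(InvalidParameterError):
            PairedSample("m", (1.0, 2.0, 3.0), (1.0, 2.0))


class TestPermutationVarianceTest:
    def test_identical_vectors_match_enumeration(self):
        d = np.array([0.3, -1.2, 0.9])
        res = permutation_variance_test(d, d, n_perm=50000, seed=0)
        assert res.exact and res.n_permutations == 20
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_value == pytest.approx(brute_force_resplit_p(d, d), abs=1e-12)

    def test_extreme_ratio_hits_minimal_p(self):
        g = np.array([10.0, -10.0, 10.0, -10.0])
        u = np.array([1.0, -1.0, 1.0, -1.0])
        res = permutation_variance_test(g, u, n_perm=50000, seed=0)
        assert res.exact and res.n_permutations == 70
        assert res.r_obs == pytest.approx(100.0)
        assert res.p_value == pytest.approx(1.0 / 70.0, abs=1e-12)
        assert res.p_value == pytest.approx(brute_force_resplit_p(g, u), abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4])
    def test_exact_path_equals_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            g = rng.standard_normal(n)
            u = rng.standard_normal(n)
            res = permutation_variance_test(g, u, n_perm=10**6, seed=1)
            assert res.exact
            assert res.p_value == pytest.approx(brute_force_resplit_p(g, u), abs=1e-12)

    def test_sampling_path_at_n13_uses_unique_partitions(self):
        rng = np.random.default_rng(9)
        res = permutation_variance_test(
            rng.standard_normal(13), rng.standard_normal(13), n_perm=50000, seed=3
        )
        # C(26, 13) = 10,400,600 distinct splits exceed the budget
        assert not res.exact and res.n_permutations == 50000
        assert 0 < res.p_value <= 1

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        g, u = rng.standard_normal(13), rng.standard_normal(13)
        a = permutation_variance_test(g, u, n_perm=2000, seed=11)
        b = permutation_variance_test(g, u, n_perm=2000, seed=11)
        assert a.p_value == b.p_value and a.r_obs == b.r_obs

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(1e-3, 1e3))
    def test_scale_invariance(self, c):
        g = np.array([1.4, -0.2, 0.7, -1.1])
        u = np.array([0.3, 0.8, -0.6, 0.1])
        a = permutation_variance_test(g, u, n_perm=10**5, seed=4)
        b = permutation_variance_test(c * g, c * u, n_perm=10**5, seed=4)
        assert b.r_obs == pytest.approx(a.r_obs, rel=1e-9)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_zero_ungated_variance_gives_smallest_p(self):
        g = np.array([1.0, 2.0, 3.0])
        u = np.array([5.0, 5.0, 5.0])
        res = permutation_variance_test(g, u, n_perm=50000, seed=0)
        assert math.isinf(res.r_obs)
        assert 0 < res.p_value < 0.5

    def test_both_zero_variances_not_applicable(self):
        z = np.zeros(4)
        res = permutation_variance_test(z, z, n_perm=100, seed=0)
        assert not res.applicable and math.isnan(res.p_value)

    def test_within_pair_swap_scheme_exact(self):
        g = np.array([2.0, -2.5, 1.5, -1.0])
        u = np.array([0.5, 0.2, -0.3, 0.4])
        res = permutation_variance_test(g, u, n_perm=50000, scheme="within-pair-swap", seed=0)
        assert res.exact and res.n_permutations == 16
        # brute force over all sign-assignment swaps
        r_obs = np.var(g, ddof=1) / np.var(u, ddof=1)
        count = 0
        for bits in itertools.product([0, 1], repeat=4):
            gg = np.where(bits, u, g)
            uu = np.where(bits, g, u)
            count += np.var(gg, ddof=1) / np.var(uu, ddof=1) >= r_obs - 1e-12 * r_obs
        assert res.p_value == pytest.approx(count / 16.0, abs=1e-12)
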