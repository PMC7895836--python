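import numpy as np
import pandas as pd
import pytest

from ectfield import (
    DesignSpec,
    Grid,
    PermutationPlan,
    SubjectFieldStack,
    TFCEParams,
    glm_permutation_test,
    sign_flip_test,
)
from oracle_helpers import exhaustive_sign_flip_p, exhaustive_y_permutation_p


def _diff_stack(data, shape=(3, 3, 3), mask=None):
    grid = Grid(shape=shape, affine=np.eye(4))
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    ids = [f"s{i}" for i in range(data.shape[0])]
    return SubjectFieldStack(grid, ids, data, mask, allow_negative=True)


class TestSignFlip:
    def test_all_zero_differences_give_p_one(self):
        stack = _diff_stack(np.zeros((5, 27)))
        res = sign_flip_test(stack, plan=PermutationPlan(n_permutations=100, seed=0))
        for d in ("positive", "negative"):
            assert np.all(res.p_corrected[d].values == 1.0)

    def test_exhaustive_n4_matches_enumeration_oracle(self, rng):
        """All 2^4 sign patterns: corrected p equals exact enumeration."""
        shape = (3, 3, 1)
        mask = np.zeros(shape, dtype=bool)
        mask[0, 0, 0] = mask[2, 2, 0] = True  # 2-voxel mask
        data = np.array([[3.0, 1.0], [2.5, -0.5], [4.0, 0.75], [2.0, 0.25]])
        stack = _diff_stack(data, shape=shape, mask=mask)
        plan = PermutationPlan(scheme="sign_flip", n_permutations=100, seed=0)
        with pytest.warns(UserWarning, match="minimum attainable"):
            res = sign_flip_test(stack, plan=plan)  # 2^4 patterns: min p 1/16
        assert res.exhaustive and res.n_permutations == 15
        oracle = exhaustive_sign_flip_p(data, mask)
        for d in ("positive", "negative"):
            np.testing.assert_array_equal(res.p_corrected[d].values, oracle[d])

    @pytest.mark.parametrize("n", [5, 6])
    def test_exhaustive_small_n_random_data(self, n, rng):
        shape = (4, 4, 3)
        mask = np.ones(shape, dtype=bool)
        data = rng.normal(0.4, 1.0, size=(n, mask.sum()))
        stack = _diff_stack(data, shape=shape, mask=mask)
        plan = PermutationPlan(scheme="sign_flip", n_permutations=2**n, seed=0)
        res = sign_flip_test(stack, plan=plan)
        oracle = exhaustive_sign_flip_p(data, mask)
        for d in ("positive", "negative"):
            np.testing.assert_array_equal(res.p_corrected[d].values, oracle[d])

    def test_monte_carlo_consistent_with_exhaustive_at_n10(self, rng):
        """5000 random flips agree with the exact test within 3 binomial SE."""
        shape = (3, 3, 2)
        mask = np.ones(shape, dtype=bool)
        data = rng.normal(0.5, 1.0, size=(10, mask.sum()))
        stack = _diff_stack(data, shape=shape, mask=mask)
        exact = sign_flip_test(
            stack, plan=PermutationPlan(scheme="sign_flip", n_permutations=2**10, seed=0)
        )
        mc = sign_flip_test(
            stack,
            plan=PermutationPlan(scheme="sign_flip", n_permutations=5000, seed=3,
                                 exhaustive=False),
        )
        for d in ("positive", "negative"):
            p_ex = exact.p_corrected[d].values
            p_mc = mc.p_corrected[d].values
            se = np.sqrt(p_ex * (1 - p_ex) / 5000)
            assert np.all(np.abs(p_mc - p_ex) <= 3 * se + 2 / 5000)

    def test_zero_variance_voxels_get_t_zero(self):
        data = np.column_stack([np.full(6, 2.0), np.random.default_rng(0).normal(size=6)])
        shape = (2, 1, 1)
        stack = _diff_stack(data, shape=shape)
        res = sign_flip_test(stack, plan=PermutationPlan(n_permutations=50, seed=0))
        # first voxel: all differences equal -> sd 0 handled as t = 0? no:
        # constant nonzero differences have sd = 0; t defined as 0
        assert res.observed_t.values[0] == 0.0

    def test_min_p_warning_for_tiny_n(self):
        data = np.random.default_rng(1).normal(size=(3, 27))
        stack = _diff_stack(data)
        with pytest.warns(UserWarning, match="minimum attainable"):
            sign_flip_test(
                stack, plan=PermutationPlan(n_permutations=7, alpha=0.05, seed=0,
                                            exhaustive=True)
            )


class TestGLMPermutation:
    def _stack_cohort(self, rng, n=12, shape=(3, 3, 3)):
        grid = Grid(shape=shape, affine=np.eye(4))
        mask = np.ones(shape, dtype=bool)
        data = rng.lognormal(4.0, 0.3, size=(n, mask.sum()))
        ids = [f"s{i}" for i in range(n)]
        stack = SubjectFieldStack(grid, ids, data, mask)
        cohort = pd.DataFrame({
            "end_madrs": rng.normal(12, 8, n),
            "age": rng.normal(58, 15, n),
            "sex": rng.integers(0, 2, n),
        })
        return stack, cohort

    def test_constant_outcome_gives_all_p_one(self, rng):
        stack, cohort = self._stack_cohort(rng)
        cohort["end_madrs"] = 7.0
        res = glm_permutation_test(
            stack, cohort, DesignSpec(covariates=("age",)),
            plan=PermutationPlan(scheme="unrestricted_y", n_permutations=60, seed=0),
        )
        assert np.all(res.observed_t.values == 0)
        for d in ("positive", "negative"):
            assert np.all(res.p_corrected[d].values == 1.0)

    def test_exhaustive_n6_matches_enumeration_oracle(self, rng):
        """All 6! outcome orders, intercept+field design: exact agreement."""
        n = 6
        grid = Grid(shape=(3, 3, 1), affine=np.eye(4))
        mask = np.ones((3, 3, 1), dtype=bool)
        data = rng.lognormal(4.0, 0.4, size=(n, 9))
        stack = SubjectFieldStack(grid, [f"s{i}" for i in range(n)], data, mask)
        y = rng.normal(10, 5, n)
        cohort = pd.DataFrame({"end_madrs": y})
        plan = PermutationPlan(scheme="unrestricted_y", n_permutations=720, seed=0)
        res = glm_permutation_test(stack, cohort, DesignSpec(covariates=()), plan=plan)
        assert res.exhaustive and res.n_permutations == 719
        oracle = exhaustive_y_permutation_p(data, y, mask)
        for d in ("positive", "negative"):
            np.testing.assert_array_equal(res.p_corrected[d].values, oracle[d])

    def test_freedman_lane_null_uniformity(self, rng):
        """Corrected p at the max-t voxel is not systematically small under
        the null (smoke-level calibration; the full FWER study lives in the
        acceptance suite)."""
        pvals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            stack, cohort = self._stack_cohort(r, n=20)
            res = glm_permutation_test(
                stack, cohort, DesignSpec(covariates=("age", "sex")),
                plan=PermutationPlan(scheme="freedman_lane", n_permutations=99,
                                     seed=seed, directions=("positive",)),
            )
            pvals.append(res.p_corrected["positive"].values.min())
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.25

    def test_schemes_require_matching_function(self, rng):
        stack, cohort = self._stack_cohort(rng)
        with pytest.raises(ValueError):
            glm_permutation_test(stack, cohort,
                                 plan=PermutationPlan(scheme="sign_flip"))
        with pytest.raises(ValueError):
            sign_flip_test(_diff_stack(np.zeros((4, 27))),
                           plan=PermutationPlan(scheme="freedman_lane"))


class TestDeterminismAndDuality:
    def test_identical_seed_identical_result(self, rng):
        data = rng.normal(0.3, 1.0, size=(8, 27))
        stack = _diff_stack(data)
        plan = PermutationPlan(n_permutations=200, seed=9, exhaustive=False)
        r1 = sign_flip_test(stack, plan=plan)
        r2 = sign_flip_test(stack, plan=plan)
        for d in ("positive", "negative"):
            np.testing.assert_array_equal(r1.p_corrected[d].values,
                                          r2.p_corrected[d].values)
            np.testing.assert_array_equal(r1.max_null[d], r2.max_null[d])

    def test_worker_count_does_not_change_result(self, rng):
        data = rng.normal(0.3, 1.0, size=(8, 27))
        stack = _diff_stack(data)
        serial = sign_flip_test(
            stack, plan=PermutationPlan(n_permutations=64, seed=5, exhaustive=False,
                                        n_jobs=1))
        parallel = sign_flip_test(
            stack, plan=PermutationPlan(n_permutations=64, seed=5, exhaustive=False,
                                        n_jobs=2))
        for d in ("positive", "negative"):
            np.testing.assert_array_equal(serial.max_null[d], parallel.max_null[d])
            np.testing.assert_array_equal(serial.p_corrected[d].values,
                                          parallel.p_corrected[d].values)

    def test_monotone_alpha_duality(self, rng):
        data = rng.normal(0.8, 1.0, size=(9, 27))
        stack = _diff_stack(data)
        res = sign_flip_test(stack, plan=PermutationPlan(n_permutations=300, seed=2,
                                                         exhaustive=False))
        sig_05 = res.significant_mask("positive", alpha=0.05)
        sig_10 = res.significant_mask("positive", alpha=0.10)
        assert np.all(sig_10[sig_05])

    def test_min_attainable_p_is_one_over_nplus1(self, rng):
        data = rng.normal(2.0, 0.2, size=(10, 27))  # strong effect
        stack = _diff_stack(data)
        res = sign_flip_test(stack, plan=PermutationPlan(n_permutations=99, seed=0,
                                                         exhaustive=False))
        assert res.p_corrected["positive"].values.min() >= 1 / 100
        assert np.all(res.p_corrected["positive"].values > 0)
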