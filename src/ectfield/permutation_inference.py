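"""Max-TFCE-statistic permutation inference with FWER control.

Two schemes cover the package's analyses:

* **sign flipping** for the paired BL−RUL field comparison: under the null
  the paired differences are symmetric about zero, so each subject's
  difference map is multiplied by an independent ±1 and the one-sample t map
  recomputed;
* **outcome permutation** for the inverse GLM: Freedman–Lane (permute the
  residuals of the nuisance-only fit and add the nuisance fit back) or plain
  permutation of the outcome vector.

Every permutation's t map is TFCE-enhanced and its image-wide maximum
recorded; the corrected p-value at voxel v is

    p(v) = (1 + #{null maxima >= observed TFCE(v)}) / (1 + n_permutations)

so that p can never reach 0 and the observed (identity) arrangement always
counts once.  For small samples the scheme switches to exhaustive
enumeration of the whole group (all 2^n sign patterns / all n! orders,
identity excluded from the null), which makes the test exact.  Per-
permutation RNG streams are derived from (seed, permutation index), so
results are identical for any worker count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .inverse_glm import DesignSpec, GLMEngine
from .tfce import TFCEParams, tfce_max, tfce_transform
from .volume_io import StatMap, SubjectFieldStack

__all__ = [
    "PermutationPlan",
    "PermutationResult",
    "sign_flip_test",
    "glm_permutation_test",
]

DIRECTIONS = ("positive", "negative")


@dataclass(frozen=True)
class PermutationPlan:
    """How to build the permutation null.

    ``n_permutations`` defaults differ by scheme at the CLI level (5000 for
    sign flipping, 20 000 for the GLM); here it is explicit.
    ``exhaustive='auto'`` enumerates the whole group whenever it is no larger
    than ``n_permutations`` (+1 for the identity).
    """

    scheme: str = "sign_flip"
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    exhaustive: str | bool = "auto"
    directions: tuple[str, ...] = DIRECTIONS
    dh_policy: str = "per_permutation"  # or "fixed" (dh from the observed map)
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.scheme not in ("sign_flip", "freedman_lane", "unrestricted_y"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.dh_policy not in ("per_permutation", "fixed"):
            raise ValueError("dh_policy must be 'per_permutation' or 'fixed'")
        bad = set(self.directions) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"unknown directions {sorted(bad)}")


@dataclass
class PermutationResult:
    """Observed maps, max-statistic nulls and corrected p per direction."""

    observed_t: StatMap
    observed_tfce: dict[str, StatMap]
    max_null: dict[str, np.ndarray]
    p_corrected: dict[str, StatMap]
    n_permutations: int
    scheme: str
    seed: int
    alpha: float
    exhaustive: bool

    def significant_mask(self, direction: str = "positive", alpha: float | None = None) -> np.ndarray:
        """Boolean volume of voxels with corrected p < alpha in a direction."""
        alpha = self.alpha if alpha is None else alpha
        pmap = self.p_corrected[direction]
        vol = np.zeros(pmap.grid.shape, dtype=bool)
        vol[pmap.mask] = pmap.values < alpha
        return vol


def _corrected_p(observed: np.ndarray, max_null: np.ndarray, n_perm: int) -> np.ndarray:
    """(1 + #{null >= obs}) / (1 + n_perm) per voxel, via a sorted null."""
    null_sorted = np.sort(max_null)
    n_lt = np.searchsorted(null_sorted, observed, side="left")
    n_ge = max_null.size - n_lt
    return (1.0 + n_ge) / (1.0 + n_perm)


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    """One-sample t per column: mean / (sd/sqrt(n)); 0 at zero-variance voxels."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / math.sqrt(n))
    return t


def _signed_t(sumsq: np.ndarray, signs: np.ndarray, data: np.ndarray) -> np.ndarray:
    """One-sample t after sign flips, using the flip-invariant sum of squares."""
    n = data.shape[0]
    mean = (signs @ data) / n
    var = np.maximum((sumsq - n * mean**2) / (n - 1), 0.0)
    t = np.zeros_like(mean)
    ok = var > 0
    t[ok] = mean[ok] / np.sqrt(var[ok] / n)
    return t


def _max_tfce_by_direction(
    t_vol: np.ndarray,
    directions: tuple[str, ...],
    params: TFCEParams,
    dh: dict[str, float | None],
) -> dict[str, float]:
    out = {}
    for d in directions:
        vol = t_vol if d == "positive" else -t_vol
        out[d] = tfce_max(vol, params, dh=dh[d])
    return out


def _finalize(
    stack_like: SubjectFieldStack,
    t_obs: np.ndarray,
    maxima: dict[str, np.ndarray],
    obs_tfce: dict[str, StatMap],
    plan: PermutationPlan,
    n_perm: int,
    exhaustive: bool,
) -> PermutationResult:
    p_corr = {
        d: stack_like.map_from(
            _corrected_p(obs_tfce[d].values, maxima[d], n_perm), name=f"p_{d}"
        )
        for d in plan.directions
    }
    if 1.0 / (1.0 + n_perm) > plan.alpha:
        warnings.warn(
            f"minimum attainable corrected p = {1.0/(1.0+n_perm):.3g} exceeds "
            f"alpha = {plan.alpha}: no voxel can be significant",
            stacklevel=3,
        )
    return PermutationResult(
        observed_t=stack_like.map_from(t_obs, name="t"),
        observed_tfce=obs_tfce,
        max_null={d: maxima[d] for d in plan.directions},
        p_corrected=p_corr,
        n_permutations=n_perm,
        scheme=plan.scheme,
        seed=plan.seed,
        alpha=plan.alpha,
        exhaustive=exhaustive,
    )


def _observed_tfce(
    stack_like: SubjectFieldStack, t_obs: np.ndarray, plan: PermutationPlan,
    params: TFCEParams,
) -> tuple[dict[str, StatMap], dict[str, float | None]]:
    """Observed TFCE maps per direction, plus the dh used per direction."""
    mask = stack_like.mask
    t_vol = np.zeros(stack_like.grid.shape)
    t_vol[mask] = t_obs
    obs, dh = {}, {}
    for d in plan.directions:
        vol = t_vol if d == "positive" else -t_vol
        enhanced = tfce_transform(vol, params)
        obs[d] = StatMap.from_volume(enhanced, stack_like.grid, mask, name=f"tfce_{d}")
        if plan.dh_policy == "fixed":
            vmax = float(np.max(vol))
            dh[d] = vmax / params.n_steps if vmax > 0 else None
        else:
            dh[d] = None
    return obs, dh


def _chunks(seq: np.ndarray, n_chunks: int) -> list[np.ndarray]:
    return [c for c in np.array_split(seq, n_chunks) if c.size]


def _collect_maxima(
    plan: PermutationPlan,
    indices: np.ndarray,
    worker,
) -> dict[str, np.ndarray]:
    """Run ``worker(chunk) -> {direction: maxima}`` over permutation indices."""
    n_jobs = max(1, plan.n_jobs)
    if n_jobs == 1:
        parts = [worker(indices)]
    else:
        parts = Parallel(n_jobs=n_jobs)(
            delayed(worker)(chunk) for chunk in _chunks(indices, 4 * n_jobs)
        )
    return {
        d: np.concatenate([p[d] for p in parts]) for d in plan.directions
    }


def sign_flip_test(
    diff_stack: SubjectFieldStack,
    params: TFCEParams | None = None,
    plan: PermutationPlan | None = None,
) -> PermutationResult:
    """Paired one-sample test of a difference stack by sign flipping.

    The observed statistic is the voxel-wise one-sample t of the differences;
    the null flips each subject's whole difference map by an independent ±1.
    """
    params = params or TFCEParams()
    plan = plan or PermutationPlan(scheme="sign_flip")
    if plan.scheme != "sign_flip":
        raise ValueError("sign_flip_test requires plan.scheme = 'sign_flip'")
    n = diff_stack.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects")

    data = diff_stack.data
    sumsq = np.einsum("ij,ij->j", data, data)
    t_obs = _one_sample_t(data)
    obs_tfce, dh = _observed_tfce(diff_stack, t_obs, plan, params)

    exhaustive = plan.exhaustive is True or (
        plan.exhaustive == "auto" and 2**n - 1 <= plan.n_permutations
    )
    grid_shape = diff_stack.grid.shape
    mask = diff_stack.mask
    t_vol = np.zeros(grid_shape)

    if exhaustive:
        n_perm = 2**n - 1

        def worker(idx: np.ndarray) -> dict[str, np.ndarray]:
            out = {d: np.empty(idx.size) for d in plan.directions}
            vol = np.zeros(grid_shape)
            for j, code in enumerate(idx):
                # code in 1..2^n-1; bit b set -> flip subject b (0 = identity)
                signs = 1.0 - 2.0 * ((code >> np.arange(n)) & 1)
                vol[mask] = _signed_t(sumsq, signs, data)
                for d, m in _max_tfce_by_direction(vol, plan.directions, params, dh).items():
                    out[d][j] = m
            return out

        indices = np.arange(1, 2**n, dtype=np.int64)
    else:
        n_perm = plan.n_permutations

        def worker(idx: np.ndarray) -> dict[str, np.ndarray]:
            out = {d: np.empty(idx.size) for d in plan.directions}
            vol = np.zeros(grid_shape)
            for j, i in enumerate(idx):
                rng = np.random.default_rng(
                    np.random.SeedSequence(plan.seed, spawn_key=(int(i),))
                )
                signs = rng.choice([-1.0, 1.0], size=n)
                vol[mask] = _signed_t(sumsq, signs, data)
                for d, m in _max_tfce_by_direction(vol, plan.directions, params, dh).items():
                    out[d][j] = m
            return out

        indices = np.arange(1, n_perm + 1, dtype=np.int64)

    maxima = _collect_maxima(plan, indices, worker)
    return _finalize(diff_stack, t_obs, maxima, obs_tfce, plan, n_perm, exhaustive)


def glm_permutation_test(
    stack: SubjectFieldStack,
    cohort: pd.DataFrame,
    design: DesignSpec | None = None,
    params: TFCEParams | None = None,
    plan: PermutationPlan | None = None,
) -> PermutationResult:
    """Permutation test of the inverse GLM's field regressor.

    ``freedman_lane``: the outcome is regressed on the nuisance covariates
    once; permuted outcomes are the nuisance fit plus permuted reduced-model
    residuals.  ``unrestricted_y``: the outcome vector itself is permuted.
    """
    design = design or DesignSpec()
    params = params or TFCEParams()
    plan = plan or PermutationPlan(scheme="freedman_lane", n_permutations=20000)
    if plan.scheme not in ("freedman_lane", "unrestricted_y"):
        raise ValueError("glm_permutation_test requires a GLM permutation scheme")

    eng = GLMEngine(stack, cohort, design)
    n = stack.n_subjects
    t_obs = eng.t_stats(eng.y)
    obs_tfce, dh = _observed_tfce(stack, t_obs, plan, params)

    if plan.scheme == "freedman_lane":
        # reduced-model residuals; nuisance fit is re-added implicitly since
        # the t statistic only sees the nuisance-residualised outcome
        base = eng.y - eng.Q @ (eng.Q.T @ eng.y) if eng.Q.shape[1] else eng.y.copy()
    else:
        base = eng.y.copy()

    exhaustive = plan.exhaustive is True or (
        plan.exhaustive == "auto" and math.factorial(n) - 1 <= plan.n_permutations
    )
    grid_shape = stack.grid.shape
    mask = stack.mask

    if exhaustive:
        n_perm = math.factorial(n) - 1
        all_orders = np.array(list(iter_permutations(range(n))), dtype=np.intp)[1:]

        def worker(idx: np.ndarray) -> dict[str, np.ndarray]:
            out = {d: np.empty(idx.size) for d in plan.directions}
            vol = np.zeros(grid_shape)
            for j, i in enumerate(idx):
                vol[mask] = eng.t_stats(base[all_orders[i]])
                for d, m in _max_tfce_by_direction(vol, plan.directions, params, dh).items():
                    out[d][j] = m
            return out

        indices = np.arange(n_perm, dtype=np.int64)
    else:
        n_perm = plan.n_permutations

        def worker(idx: np.ndarray) -> dict[str, np.ndarray]:
            out = {d: np.empty(idx.size) for d in plan.directions}
            vol = np.zeros(grid_shape)
            for j, i in enumerate(idx):
                rng = np.random.default_rng(
                    np.random.SeedSequence(plan.seed, spawn_key=(int(i),))
                )
                vol[mask] = eng.t_stats(base[rng.permutation(n)])
                for d, m in _max_tfce_by_direction(vol, plan.directions, params, dh).items():
                    out[d][j] = m
            return out

        indices = np.arange(1, n_perm + 1, dtype=np.int64)

    maxima = _collect_maxima(plan, indices, worker)
    return _finalize(stack, t_obs, maxima, obs_tfce, plan, n_perm, exhaustive)
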