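"""Voxel-wise "inverse" GLM: field strength predicts clinical outcome.

Conventional neuroimaging GLMs put the image on the left-hand side; here the
regression is reversed — at every voxel the outcome (end-of-course MADRS, or
binary response as a linear probability model) is regressed on that voxel's
electric-field magnitude plus a fixed set of clinical covariates.  Only the
field column differs between voxels, so the covariate block is orthogonalised
once (Frisch-Waugh-Lovell) and each voxel reduces to a univariate solve; the
result is numerically identical to an independent per-voxel pseudoinverse fit.

Outputs per voxel: the field regressor's t statistic, its slope, full-model
R², and the field's semi-partial R² (the share of outcome variance uniquely
attributable to the field after the covariates),

    sp_R² = t² · (1 − R²_full) / df_resid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .volume_io import StatMap, SubjectFieldStack

__all__ = [
    "DesignSpec",
    "VoxelFitResult",
    "build_design",
    "fit_voxelwise",
    "residualize_pair",
    "DEFAULT_COVARIATES",
]

#: Covariate set of the bilateral-placement end-MADRS analysis.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "baseline_madrs",
    "total_sessions",
    "mean_seizure_threshold",
    "switched",
)

_ALLOWED_OUTCOMES = ("end_madrs", "responder")


@dataclass(frozen=True)
class DesignSpec:
    """Outcome + ordered covariate list for the voxel-wise regression."""

    outcome: str = "end_madrs"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in _ALLOWED_OUTCOMES:
            raise ValueError(f"outcome must be one of {_ALLOWED_OUTCOMES}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def n_columns(self) -> int:
        """Columns of the full per-voxel design: intercept + field + covariates."""
        return len(self.covariates) + 1 + int(self.include_intercept)


@dataclass
class VoxelFitResult:
    t_map: StatMap
    beta_map: StatMap
    r2_full_map: StatMap
    sp_r2_map: StatMap
    df_resid: int
    constant_field: np.ndarray = dc_field(repr=False, default=None)  # flagged voxels


def build_design(cohort: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Extract (outcome vector y, nuisance matrix Z) from the cohort table.

    Z holds the intercept (if any) and the covariates — everything except the
    per-voxel field column.  Baseline imputation must already have been
    applied; missing values here are an error.
    """
    missing = [c for c in (design.outcome, *design.covariates) if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    y = cohort[design.outcome].to_numpy(dtype=float)
    cols = [cohort[c].to_numpy(dtype=float) for c in design.covariates]
    if design.include_intercept:
        cols.insert(0, np.ones(len(cohort)))
    Z = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(Z)):
        raise ValueError(
            "design contains missing/non-finite values; apply impute_baseline first"
        )
    for name, col in zip(design.covariates, Z.T[int(design.include_intercept) :]):
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
    n, q = Z.shape
    if n <= q + 2:
        raise ValueError(f"need n > n_columns + 1 subjects (n={n}, columns={q + 1})")
    return y, Z


def _nuisance_basis(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of the nuisance column space (empty-safe)."""
    if Z.shape[1] == 0:
        return np.empty((Z.shape[0], 0))
    Q, R = np.linalg.qr(Z)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    if not np.all(keep):
        raise ValueError("nuisance design is rank deficient")
    return Q


def _residualize(v: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if Q.shape[1] == 0:
        return v
    return v - Q @ (Q.T @ v)


def _t_from_residualized(
    Fres: np.ndarray, ssf: np.ndarray, yres: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (t, beta, RSS) from covariate-residualised field and outcome."""
    b = Fres.T @ yres
    ok = ssf > 0
    beta = np.zeros_like(b)
    beta[ok] = b[ok] / ssf[ok]
    rss = np.maximum(yres @ yres - beta * b, 0.0)
    t = np.zeros_like(b)
    denom = np.sqrt(ssf * rss / df, where=ok & (rss > 0), out=np.zeros_like(b))
    good = denom > 0
    t[good] = b[good] / denom[good]
    return t, beta, rss


class GLMEngine:
    """Precomputed pieces of the voxel-wise fit, reused across permutations."""

    def __init__(self, stack: SubjectFieldStack, cohort: pd.DataFrame, design: DesignSpec):
        if len(cohort) != stack.n_subjects:
            raise ValueError("cohort rows do not match stack subjects")
        if "subject_id" in cohort.columns:
            ids = tuple(str(s) for s in cohort["subject_id"])
            if ids != stack.subject_ids:
                raise ValueError("cohort subject order does not match the stack")
        self.stack = stack
        self.design = design
        self.y, self.Z = build_design(cohort, design)
        self.Q = _nuisance_basis(self.Z)
        self.Fres = _residualize(stack.data.copy(), self.Q)  # (n, V) residual fields
        self.Fres = np.ascontiguousarray(self.Fres)
        self.ssf = np.einsum("ij,ij->j", self.Fres, self.Fres)
        # guard against catastrophic cancellation at constant-field voxels
        scale = np.einsum("ij,ij->j", stack.data, stack.data)
        self.constant_field = self.ssf <= 1e-12 * np.maximum(scale, 1.0)
        self.ssf = np.where(self.constant_field, 0.0, self.ssf)
        self.df_resid = stack.n_subjects - design.n_columns
        if self.df_resid < 1:
            raise ValueError("no residual degrees of freedom")

    def t_stats(self, y: np.ndarray) -> np.ndarray:
        """t map of the field regressor for outcome vector ``y``."""
        yres = _residualize(y, self.Q)
        if self._outcome_degenerate(y, yres):
            return np.zeros(self.Fres.shape[1])
        t, _, _ = _t_from_residualized(self.Fres, self.ssf, yres, self.df_resid)
        return t

    @staticmethod
    def _outcome_degenerate(y: np.ndarray, yres: np.ndarray) -> bool:
        """Outcome fully explained by the nuisance block (e.g. constant y):
        the leftover is projection round-off, not signal."""
        return float(yres @ yres) <= 1e-20 * max(1.0, float(y @ y))


def fit_voxelwise(
    stack: SubjectFieldStack, cohort: pd.DataFrame, design: DesignSpec | None = None
) -> VoxelFitResult:
    """Fit the inverse GLM at every masked voxel.

    Voxels whose field is constant across subjects are flagged and score
    t = 0, sp_R² = 0 (they stay in the map so cluster geometry is intact).
    """
    design = design or DesignSpec()
    eng = GLMEngine(stack, cohort, design)
    yres = _residualize(eng.y, eng.Q)
    if eng._outcome_degenerate(eng.y, yres):
        yres = np.zeros_like(yres)
    t, beta, rss = _t_from_residualized(eng.Fres, eng.ssf, yres, eng.df_resid)

    if design.include_intercept:
        tss = float(np.sum((eng.y - eng.y.mean()) ** 2))
    else:
        tss = float(eng.y @ eng.y)
    if tss > 0:
        r2_full = 1.0 - rss / tss
    else:
        r2_full = np.zeros_like(rss)
    r2_full = np.clip(r2_full, 0.0, 1.0)
    sp_r2 = t**2 * (1.0 - r2_full) / eng.df_resid
    sp_r2 = np.where(eng.constant_field, 0.0, sp_r2)

    return VoxelFitResult(
        t_map=stack.map_from(t, name="t"),
        beta_map=stack.map_from(beta, name="beta"),
        r2_full_map=stack.map_from(r2_full, name="r2_full"),
        sp_r2_map=stack.map_from(sp_r2, name="sp_r2"),
        df_resid=eng.df_resid,
        constant_field=eng.constant_field,
    )


def residualize_pair(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Residualise two per-subject scalars on [1, covariates].

    Produces the covariate-adjusted scatter pairs (e.g. cluster-mean field vs
    end-MADRS) used for visualisation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariates do not match the number of subjects")
        Z = np.column_stack([np.ones(n), covariates])
    Q = _nuisance_basis(Z)
    return _residualize(x, Q), _residualize(y, Q)
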