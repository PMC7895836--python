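"""Field post-processing: device scaling, magnitudes, group maps, pairing.

Finite-element solves are run at a unit electrode current (1 mA); a modern
constant-current ECT device delivers 0.8-0.9 A, so magnitudes are scaled
linearly by the current ratio (900 for a 0.9 A device).  The isotropic
tissue conductivities used by the solves are recorded here as provenance
metadata only — no solving happens in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import StatMap, SubjectFieldStack

__all__ = [
    "ScalingSpec",
    "CONDUCTIVITY_S_PER_M",
    "magnitude",
    "group_maps",
    "paired_difference",
]

#: Isotropic tissue conductivities (S/m) of the upstream head-model solves.
CONDUCTIVITY_S_PER_M: dict[str, float] = {
    "white_matter": 0.126,
    "gray_matter": 0.275,
    "csf": 1.654,
    "bone": 0.01,
    "scalp": 0.465,
    "eyes": 0.5,
}


@dataclass(frozen=True)
class ScalingSpec:
    """Linear current scaling from the unit solve to the device output.

    Defaults correspond to a 1 mA solve scaled to a 0.9 A (900 mA)
    constant-current device, i.e. a factor of 900.
    """

    solve_current_mA: float = 1.0
    device_current_mA: float = 900.0

    def __post_init__(self) -> None:
        if self.solve_current_mA <= 0 or self.device_current_mA <= 0:
            raise ValueError("currents must be positive")

    @property
    def scale_factor(self) -> float:
        return self.device_current_mA / self.solve_current_mA


def magnitude(vector_field: np.ndarray, scaling: ScalingSpec | None = None) -> np.ndarray:
    """Per-voxel Euclidean norm of a 3-component field, times the current scale.

    ``vector_field`` has shape (nx, ny, nz, 3) in V/m per solve current; the
    result is a (nx, ny, nz) magnitude volume in V/m at device current.
    """
    scaling = scaling or ScalingSpec()
    vec = np.asarray(vector_field, dtype=float)
    if vec.ndim != 4 or vec.shape[-1] != 3:
        raise ValueError(f"expected shape (nx, ny, nz, 3), got {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("vector field contains non-finite components")
    return np.linalg.norm(vec, axis=-1) * scaling.scale_factor


def group_maps(stack: SubjectFieldStack) -> tuple[StatMap, StatMap]:
    """Voxel-wise group mean and sample SD (n-1 denominator) maps."""
    if stack.n_subjects < 2:
        raise ValueError("group maps need at least 2 subjects")
    mean = stack.data.mean(axis=0)
    sd = stack.data.std(axis=0, ddof=1)
    return stack.map_from(mean, name="mean"), stack.map_from(sd, name="sd")


def paired_difference(
    stack_bl: SubjectFieldStack, stack_rul: SubjectFieldStack
) -> SubjectFieldStack:
    """Within-subject BL minus RUL field stack (positive where BL is larger).

    Subjects must be identical and in the same order; both stacks must share
    the grid and mask.
    """
    if stack_bl.subject_ids != stack_rul.subject_ids:
        raise ValueError("paired stacks must contain the same subjects in the same order")
    stack_bl.grid.require_match(stack_rul.grid, what="paired stack")
    if not np.array_equal(stack_bl.mask, stack_rul.mask):
        raise ValueError("paired stacks must share one analysis mask")
    return SubjectFieldStack(
        grid=stack_bl.grid,
        subject_ids=stack_bl.subject_ids,
        data=stack_bl.data - stack_rul.data,
        mask=stack_bl.mask,
        allow_negative=True,
    )
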