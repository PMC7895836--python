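"""Significant-cluster extraction and effect-size reporting.

Connected components of the FWER-corrected significance mask are reported
the way clinical field-dosimetry tables are laid out: size in mm³, peak
world (MNI) coordinate, corrected p at the peak, and mean effect sizes over
member voxels.  Effect sizes averaged over voxels *selected by* the
significance procedure are optimistically biased towards that selection;
every record carries a ``selection_biased`` flag as a standing caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .inverse_glm import DesignSpec, VoxelFitResult, build_design, residualize_pair
from .permutation_inference import PermutationResult
from .volume_io import Grid, SubjectFieldStack

__all__ = [
    "ClusterRecord",
    "extract_clusters",
    "cluster_effect_summary",
    "clusters_to_table",
    "cluster_label_map",
]


@dataclass
class ClusterRecord:
    cluster_id: int
    n_voxels: int
    size_mm3: float
    peak_voxel: tuple[int, int, int]
    peak_world: tuple[float, float, float]
    peak_p_corrected: float
    peak_t: float
    mean_sp_r2: float
    mean_r2_full: float
    label: str = ""  # free-text anatomical label; no atlas lookup here
    selection_biased: bool = True
    member_voxels: np.ndarray = dc_field(default=None, repr=False)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def extract_clusters(
    result: PermutationResult,
    fit: VoxelFitResult,
    grid: Grid,
    connectivity: int = 26,
    direction: str = "positive",
    alpha: float | None = None,
) -> list[ClusterRecord]:
    """Connected components of the corrected-significance mask, largest first.

    The peak of a cluster is its member voxel with minimal corrected p,
    tie-broken by larger |t|, then by lexicographic (i, j, k).
    """
    sig = result.significant_mask(direction, alpha)
    if not sig.any():
        return []

    p_vol = result.p_corrected[direction].to_volume(fill=1.0)
    t_vol = fit.t_map.to_volume(fill=0.0)
    sp_vol = fit.sp_r2_map.to_volume(fill=0.0)
    r2_vol = fit.r2_full_map.to_volume(fill=0.0)

    labels, n_comp = ndimage.label(sig, structure=_structure(connectivity))
    records: list[ClusterRecord] = []
    for comp in range(1, n_comp + 1):
        members = np.argwhere(labels == comp)  # lexicographic (i, j, k)
        pvals = p_vol[tuple(members.T)]
        tvals = t_vol[tuple(members.T)]
        # lexicographic argsort on (p, -|t|, i, j, k); first row wins
        order = np.lexsort(
            (members[:, 2], members[:, 1], members[:, 0], -np.abs(tvals), pvals)
        )
        peak = members[order[0]]
        records.append(
            ClusterRecord(
                cluster_id=0,  # assigned after sorting by size
                n_voxels=len(members),
                size_mm3=len(members) * grid.voxel_volume,
                peak_voxel=tuple(int(v) for v in peak),
                peak_world=tuple(float(x) for x in grid.voxel_to_world(peak)),
                peak_p_corrected=float(p_vol[tuple(peak)]),
                peak_t=float(t_vol[tuple(peak)]),
                mean_sp_r2=float(sp_vol[tuple(members.T)].mean()),
                mean_r2_full=float(r2_vol[tuple(members.T)].mean()),
                member_voxels=members,
            )
        )
    records.sort(key=lambda r: (-r.n_voxels, r.peak_p_corrected))
    for i, rec in enumerate(records, start=1):
        rec.cluster_id = i
    return records


def cluster_mean_field(record: ClusterRecord, stack: SubjectFieldStack) -> np.ndarray:
    """Per-subject mean field magnitude over the cluster's member voxels."""
    member_mask = np.zeros(stack.grid.shape, dtype=bool)
    member_mask[tuple(record.member_voxels.T)] = True
    cols = member_mask[stack.mask]
    if not cols.any():
        raise ValueError("cluster has no voxels inside the stack mask")
    return stack.data[:, cols].mean(axis=1)


def cluster_effect_summary(
    record: ClusterRecord,
    stack: SubjectFieldStack,
    cohort: pd.DataFrame,
    design: DesignSpec | None = None,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """(mean sp_R², mean full R², covariate-adjusted scatter pairs).

    The scatter pairs are the cluster-mean field and the outcome, each
    residualised on [1, covariates] — the visualisation convention for
    covariate-corrected cluster plots.
    """
    design = design or DesignSpec()
    y, Z = build_design(cohort, design)
    x = cluster_mean_field(record, stack)
    covars = Z[:, 1:] if design.include_intercept else Z
    pairs = residualize_pair(x, y, covars if covars.shape[1] else None)
    return record.mean_sp_r2, record.mean_r2_full, pairs


def clusters_to_table(records: list[ClusterRecord]) -> pd.DataFrame:
    """One row per cluster, mirroring a clinical cluster-report table."""
    rows = []
    for r in records:
        rows.append(
            {
                "cluster_id": r.cluster_id,
                "n_voxels": r.n_voxels,
                "size_mm3": r.size_mm3,
                "peak_x_mm": r.peak_world[0],
                "peak_y_mm": r.peak_world[1],
                "peak_z_mm": r.peak_world[2],
                "peak_p_corrected": r.peak_p_corrected,
                "peak_t": r.peak_t,
                "mean_sp_r2": r.mean_sp_r2,
                "mean_r2_full": r.mean_r2_full,
                "label": r.label,
                "selection_biased": r.selection_biased,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_voxels", "size_mm3", "peak_x_mm", "peak_y_mm",
            "peak_z_mm", "peak_p_corrected", "peak_t", "mean_sp_r2",
            "mean_r2_full", "label", "selection_biased",
        ],
    )


def write_cluster_table(records: list[ClusterRecord], path: str | Path) -> None:
    table = clusters_to_table(records)
    with open(path, "w") as fh:
        fh.write(
            "# Effect sizes are averaged over voxels selected by the "
            "significance procedure and are optimistically biased.\n"
        )
        table.to_csv(fh, sep="\t", index=False)


def cluster_label_map(records: list[ClusterRecord], grid: Grid) -> np.ndarray:
    """Integer-coded volume: voxel value = cluster_id, 0 = background."""
    vol = np.zeros(grid.shape, dtype=np.int32)
    for r in records:
        vol[tuple(r.member_voxels.T)] = r.cluster_id
    return vol
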