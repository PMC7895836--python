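"""Threshold-free cluster enhancement (TFCE) of 3D statistic volumes.

For a statistic image ``s``, the enhanced score at voxel v is the discrete
integral

    TFCE(v) = sum over h in {dh, 2*dh, ..., h_max} of  e(v, h)^E * h^H * dh

where ``e(v, h)`` is the size (voxel count) of the connected component
containing v in the supra-threshold set {s >= h}.  Defaults H = 2, E = 0.5,
dh = h_max / 100 and 26-connectivity follow the canonical volumetric TFCE
formulation.  Voxels with s <= 0 always score 0; the negative direction is
enhanced by a separate pass on the negated map.

The engine inserts voxels in descending value order into a union-find
structure, so component sizes at every threshold are maintained
incrementally; it is compiled with numba because permutation inference
evaluates the transform tens of thousands of times.  A ``max_only`` fast
path accumulates scores only at regional maxima: for any voxel with a
strictly greater neighbour, that neighbour shares its component at every
threshold the voxel survives, hence scores at least as high — the image-wide
maximum therefore always sits on a regional maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .volume_io import StatMap

__all__ = ["TFCEParams", "tfce_enhance", "tfce_transform", "tfce_max"]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE parameters: height power H, extent power E, steps, connectivity."""

    height_power: float = 2.0
    extent_power: float = 0.5
    n_steps: int = 100
    connectivity: int = 26
    direction: str = "positive"

    def __post_init__(self) -> None:
        if self.height_power < 0 or self.extent_power < 0:
            raise ValueError("powers must be nonnegative")
        if self.n_steps < 10:
            raise ValueError("n_steps must be at least 10")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((di, dj, dk))
    return np.asarray(offs, dtype=np.int64)


@njit(cache=True)
def _find(parent: np.ndarray, v: int) -> int:
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:  # path compression
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=True)
def _tfce_kernel(
    vals: np.ndarray,  # flat float64, C order
    order: np.ndarray,  # positive-voxel flat indices, value-descending
    offsets: np.ndarray,  # (m, 3) neighbour offsets
    nx: int,
    ny: int,
    nz: int,
    n_levels: int,
    thresholds: np.ndarray,  # ascending, thresholds[k-1] is level k
    dh: float,  # integration weight per level
    extent_power: float,
    height_power: float,
    cand_order: np.ndarray,  # voxels whose score is accumulated, value-descending
    out: np.ndarray,  # flat float64, zero-initialised
) -> None:
    n = vals.size
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    ptr = 0
    cptr = 0
    n_active = order.size
    n_cand = cand_order.size
    for level in range(n_levels, 0, -1):
        h = thresholds[level - 1]
        # grow the supra-threshold set {vals >= h}
        while ptr < n_active and vals[order[ptr]] >= h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            i = v // (ny * nz)
            rem = v - i * ny * nz
            j = rem // nz
            k = rem - j * nz
            for m in range(offsets.shape[0]):
                ii = i + offsets[m, 0]
                jj = j + offsets[m, 1]
                kk = k + offsets[m, 2]
                if ii < 0 or ii >= nx or jj < 0 or jj >= ny or kk < 0 or kk >= nz:
                    continue
                w = (ii * ny + jj) * nz + kk
                if parent[w] == -1:
                    continue
                rv = _find(parent, v)
                rw = _find(parent, w)
                if rv != rw:  # union by size
                    if size[rv] < size[rw]:
                        rv, rw = rw, rv
                    parent[rw] = rv
                    size[rv] += size[rw]
        while cptr < n_cand and vals[cand_order[cptr]] >= h:
            cptr += 1
        hterm = (h**height_power) * dh
        for t in range(cptr):
            v = cand_order[t]
            r = _find(parent, v)
            out[v] += (float(size[r]) ** extent_power) * hterm


@njit(cache=True)
def _tfce_max_kernel(
    vals: np.ndarray,
    order: np.ndarray,
    offsets: np.ndarray,
    nx: int,
    ny: int,
    nz: int,
    n_levels: int,
    thresholds: np.ndarray,
    dh: float,
    extent_power: float,
    height_power: float,
) -> float:
    """Maximum TFCE score, accumulating only at regional maxima.

    A voxel has a strictly greater neighbour iff, at its insertion (value-
    descending order), some already-active neighbour carries a larger value;
    such voxels can never host the image-wide TFCE maximum.
    """
    n = vals.size
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    n_active = order.size
    cand = np.empty(n_active, dtype=np.int64)  # regional maxima, value-descending
    score = np.zeros(n_active, dtype=np.float64)
    n_cand = 0
    ptr = 0
    cptr = 0
    for level in range(n_levels, 0, -1):
        h = thresholds[level - 1]
        while ptr < n_active and vals[order[ptr]] >= h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            i = v // (ny * nz)
            rem = v - i * ny * nz
            j = rem // nz
            k = rem - j * nz
            is_max = True
            for m in range(offsets.shape[0]):
                ii = i + offsets[m, 0]
                jj = j + offsets[m, 1]
                kk = k + offsets[m, 2]
                if ii < 0 or ii >= nx or jj < 0 or jj >= ny or kk < 0 or kk >= nz:
                    continue
                w = (ii * ny + jj) * nz + kk
                if parent[w] == -1:
                    continue
                if vals[w] > vals[v]:
                    is_max = False
                rv = _find(parent, v)
                rw = _find(parent, w)
                if rv != rw:
                    if size[rv] < size[rw]:
                        rv, rw = rw, rv
                    parent[rw] = rv
                    size[rv] += size[rw]
            if is_max:
                cand[n_cand] = v
                n_cand += 1
        while cptr < n_cand and vals[cand[cptr]] >= h:
            cptr += 1
        hterm = (h**height_power) * dh
        for t in range(cptr):
            r = _find(parent, cand[t])
            score[t] += (float(size[r]) ** extent_power) * hterm
    best = 0.0
    for t in range(n_cand):
        if score[t] > best:
            best = score[t]
    return best


def _prepare(volume: np.ndarray, params: TFCEParams, dh: float | None):
    """Threshold ladder + voxel processing order for one volume.

    By default the ladder is anchored to the maximum, h_k = vmax * (k / n),
    so the top level equals the maximum bitwise (the supra-threshold set is
    never empty at the top step); the integration weight is dh = vmax / n.
    An explicit ``dh`` gives the fixed ladder h_k = dh * k up to vmax.
    """
    vol = np.ascontiguousarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("TFCE operates on 3D volumes")
    if not np.all(np.isfinite(vol)):
        raise ValueError("statistic volume contains non-finite values")
    flat = vol.ravel()
    vmax = flat.max() if flat.size else 0.0
    if vmax <= 0:
        return vol, flat, None, None, 0.0, 0
    if dh is None:
        n_levels = params.n_steps
        step = vmax / n_levels
        thresholds = vmax * (np.arange(1, n_levels + 1) / n_levels)
    else:
        if dh <= 0:
            raise ValueError("dh must be positive")
        step = float(dh)
        n_levels = int(np.floor(vmax / step + 1e-12))
        if n_levels < 1:
            return vol, flat, None, None, step, 0
        thresholds = step * np.arange(1, n_levels + 1)
    pos = np.flatnonzero(flat > 0)
    order = pos[np.argsort(flat[pos], kind="stable")[::-1]]
    return vol, flat, order, thresholds, step, n_levels


def tfce_transform(
    volume: np.ndarray, params: TFCEParams | None = None, dh: float | None = None
) -> np.ndarray:
    """Full TFCE map of a (positively signed) 3D statistic volume.

    ``dh`` fixes the threshold step; by default it is the volume's maximum
    divided by ``params.n_steps``.
    """
    params = params or TFCEParams()
    vol, flat, order, thresholds, step, n_levels = _prepare(volume, params, dh)
    out = np.zeros_like(flat)
    if n_levels > 0:
        _tfce_kernel(
            flat,
            order,
            _neighbor_offsets(params.connectivity),
            *vol.shape,
            n_levels,
            thresholds,
            step,
            params.extent_power,
            params.height_power,
            order,  # accumulate at every supra-threshold voxel
            out,
        )
    return out.reshape(vol.shape)


def tfce_max(
    volume: np.ndarray, params: TFCEParams | None = None, dh: float | None = None
) -> float:
    """Image-wide maximum of the TFCE map, via the regional-maxima fast path."""
    params = params or TFCEParams()
    vol, flat, order, thresholds, step, n_levels = _prepare(volume, params, dh)
    if n_levels == 0:
        return 0.0
    return float(
        _tfce_max_kernel(
            flat,
            order,
            _neighbor_offsets(params.connectivity),
            *vol.shape,
            n_levels,
            thresholds,
            step,
            params.extent_power,
            params.height_power,
        )
    )


def tfce_enhance(
    stat: StatMap, params: TFCEParams | None = None, dh: float | None = None
) -> StatMap:
    """TFCE-enhance a stat map; ``params.direction='negative'`` negates first."""
    params = params or TFCEParams()
    vol = stat.to_volume(fill=0.0)
    if params.direction == "negative":
        vol = -vol
    enhanced = tfce_transform(vol, params, dh=dh)
    return StatMap.from_volume(
        enhanced, stat.grid, stat.mask, name=f"tfce_{params.direction}"
    )
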