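"""Tractogram-derived anatomical connectivity priors.

For a seed voxel (or parcel), the prior is the population probability that a
streamline connects the seed to each brain voxel: per subject, streamlines
intersecting the seed are selected, the voxels they visit are binarised, and
the binary maps are averaged across subjects. Stored values are therefore
exact fractions k/n for n subjects.

Streamline–voxel intersection uses exact Amanatides–Woo voxel traversal by
default, so the contract "every voxel the polyline passes through" holds even
for grazing corner clips; a segment-resampling backend (step =
min(voxel_size)/4, the discretisation typical of streamline-density tools) is
available for cross-checking.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Union

import numpy as np

from .core import (
    Mask,
    Parcellation,
    PriorsStore,
    ProbabilityMap,
    StreamlineSet,
    VoxelGrid,
)

__all__ = ["rasterize_streamline", "visitation_map", "build_priors"]


def _round_to_voxels(vox_coords: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-integer voxel membership; rows outside the grid are dropped."""
    idx = np.floor(vox_coords + 0.5).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    return idx[inside]


def _resample_raster(line: np.ndarray, grid: VoxelGrid, step_mm: float) -> set:
    vox = grid.world_to_voxel(line)
    pieces = [vox[:1]]
    for a, b in zip(vox[:-1], vox[1:]):
        seg_mm = np.linalg.norm(grid.voxel_to_world(b) - grid.voxel_to_world(a))
        n = max(1, int(math.ceil(seg_mm / step_mm)))
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pieces.append(a[None, :] * (1 - t) + b[None, :] * t)
    samples = np.vstack(pieces)
    idx = _round_to_voxels(samples, grid.shape)
    return set(map(tuple, idx.tolist()))


def _traverse_segment(p: np.ndarray, q: np.ndarray) -> Iterable[tuple]:
    """Amanatides–Woo traversal of unit cells [i, i+1)^3 crossed by p→q."""
    d = q - p
    cell = np.floor(p).astype(np.int64)
    end = np.floor(q).astype(np.int64)
    yield tuple(cell)
    if np.all(cell == end):
        return
    step = np.sign(d).astype(np.int64)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] > 0:
            t_max[ax] = (cell[ax] + 1 - p[ax]) / d[ax]
            t_delta[ax] = 1.0 / d[ax]
        elif d[ax] < 0:
            t_max[ax] = (cell[ax] - p[ax]) / d[ax]
            t_delta[ax] = -1.0 / d[ax]
    while True:
        ax = int(np.argmin(t_max))
        if t_max[ax] > 1.0:
            return
        cell = cell.copy()
        cell[ax] += step[ax]
        t_max[ax] += t_delta[ax]
        yield tuple(cell)
        if np.all(cell == end):
            return


def _traversal_raster(line: np.ndarray, grid: VoxelGrid) -> set:
    # shift by +0.5 so voxel boxes [i-0.5, i+0.5) become unit cells [i, i+1)
    vox = grid.world_to_voxel(line) + 0.5
    out: set = set()
    shape = np.array(grid.shape)
    for a, b in zip(vox[:-1], vox[1:]):
        for cell in _traverse_segment(a, b):
            c = np.array(cell)
            if np.all((c >= 0) & (c < shape)):
                out.add(cell)
    return out


def rasterize_streamline(
    line: np.ndarray, grid: VoxelGrid, method: str = "exact"
) -> set:
    """Voxels (index triples) crossed by a world-mm polyline.

    ``method="exact"`` (default) walks the voxel boxes with Amanatides–Woo
    traversal; ``"resample"`` samples each segment at steps of
    min(voxel_size)/4 and collects the containing voxels (faster,
    may miss grazing corner clips). Points outside the grid are dropped. A
    degenerate polyline (all points identical) yields its single containing
    voxel.
    """
    line = np.asarray(line, dtype=np.float64)
    if line.ndim != 2 or line.shape[1] != 3 or line.shape[0] < 2:
        raise ValueError("polyline must be an (N>=2, 3) array")
    if method == "exact":
        return _traversal_raster(line, grid)
    if method == "resample":
        step = float(np.min(grid.voxel_size)) / 4.0
        return _resample_raster(line, grid, step)
    raise ValueError(f"unknown rasterisation method {method!r}")


def _seed_voxels(
    seed, parcellation: Parcellation | None
) -> set[tuple[int, int, int]]:
    if isinstance(seed, tuple) and len(seed) == 3:
        return {tuple(int(c) for c in seed)}
    if isinstance(seed, (int, np.integer)):
        if parcellation is None:
            raise ValueError("region-label seed requires a parcellation")
        voxels = parcellation.region_voxels(int(seed))
        if not voxels:
            raise ValueError(f"region {seed} has no voxels in the parcellation")
        return set(voxels)
    raise ValueError(f"seed must be a voxel triple or region label, got {seed!r}")


def visitation_map(
    streamlines: StreamlineSet,
    seed,
    grid: VoxelGrid,
    parcellation: Parcellation | None = None,
    method: str = "exact",
) -> ProbabilityMap:
    """Binary map of voxels visited by streamlines intersecting the seed.

    ``seed`` is a voxel index triple, or an integer parcel label together
    with ``parcellation``. A seed no streamline touches yields an all-zero
    map.
    """
    seeds = _seed_voxels(seed, parcellation)
    shape = np.array(grid.shape)
    for v in seeds:
        if not np.all((np.array(v) >= 0) & (np.array(v) < shape)):
            raise ValueError(f"seed voxel {v} outside grid")
    out = np.zeros(grid.shape, dtype=np.float64)
    for line in streamlines.streamlines:
        visited = rasterize_streamline(line, grid, method=method)
        if visited & seeds:
            for v in visited:
                out[v] = 1.0
    return ProbabilityMap(grid, out)


def build_priors(
    subjects: Sequence[StreamlineSet],
    seeds: Union[Mask, Parcellation],
    grid: VoxelGrid,
    method: str = "exact",
) -> PriorsStore:
    """Average per-subject binary visitation maps into probability priors.

    ``seeds`` as a Mask yields a voxel-wise store (one entry per mask voxel);
    as a Parcellation, a region-wise store (one entry per nonzero label).
    Every stored value is k/n with k the number of subjects in which the
    voxel is visited from the seed. Seeds with no streamlines in any subject
    keep an all-zero entry.
    """
    if len(subjects) == 0:
        raise ValueError("at least one subject is required")
    if isinstance(seeds, Mask):
        mode = "voxel"
        seed_items = [(v, {v}) for v in seeds.sorted_voxels()]
    elif isinstance(seeds, Parcellation):
        mode = "region"
        seed_items = [
            (lab, set(seeds.region_voxels(lab))) for lab in seeds.region_labels()
        ]
    else:
        raise TypeError("seeds must be a Mask or a Parcellation")
    if not seed_items:
        raise ValueError("seeds are empty")

    n = len(subjects)
    sums = {key: np.zeros(grid.shape, dtype=np.float64) for key, _ in seed_items}
    for sset in subjects:
        rasters = [
            rasterize_streamline(line, grid, method=method)
            for line in sset.streamlines
        ]
        # inverted index: voxel -> streamline ids crossing it
        index: dict[tuple[int, int, int], list[int]] = {}
        for i, r in enumerate(rasters):
            for v in r:
                index.setdefault(v, []).append(i)
        for key, seed_vox in seed_items:
            selected: set[int] = set()
            for v in seed_vox:
                selected.update(index.get(v, ()))
            if not selected:
                continue
            visited: set = set()
            for i in selected:
                visited |= rasters[i]
            arr = sums[key]
            for v in visited:
                arr[v] += 1.0
    entries = {
        key: ProbabilityMap(grid, arr / float(n)) for key, arr in sums.items()
    }
    return PriorsStore(grid, mode, entries)
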