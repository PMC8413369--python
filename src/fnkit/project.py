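"""BOLD projection onto white-matter circuits (the functionnectome transform).

Each output voxel v receives the connectivity-weighted average of the
grey-matter time-series:

    output(v, t) = sum_m P_m(v) * F(m, t) / sum_m P_m(v)

with m ranging over the analysis-mask voxels (voxel-wise) or parcels
(region-wise, where F(m, t) is the parcel-mean series). The division makes
every covered output voxel a convex combination of input series, so the
functionnectome stays on the BOLD scale. Voxels whose probability sum is
zero are set to 0 and reported in the ``uncovered`` mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import (
    FunctionalVolume,
    GridMismatchError,
    Mask,
    Parcellation,
    PriorsStore,
    ProbabilityMap,
    require_same_grid,
)

__all__ = [
    "CoverageMap",
    "ProjectionResult",
    "project_voxelwise",
    "project_regionwise",
    "mask_to_white_matter",
]


class CoverageMap(ProbabilityMap):
    """Per-voxel sum of seed probabilities; non-negative but may exceed 1."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError("data shape does not match grid")
        if self.data.size and self.data.min() < 0:
            raise ValueError("coverage values must be non-negative")


@dataclass
class ProjectionResult:
    """Projection output: the functionnectome, its coverage, and the gaps.

    ``coverage`` holds the per-voxel probability sum (the denominator);
    ``uncovered`` flags voxels where that sum is zero (their time-series is
    identically 0 in ``volume``).
    """

    volume: FunctionalVolume
    coverage: ProbabilityMap
    uncovered: Mask

    def __post_init__(self) -> None:
        require_same_grid(self.volume, self.coverage, "volume and coverage")
        require_same_grid(self.volume, self.uncovered, "volume and uncovered mask")


def _weighted_average(
    weights: np.ndarray,
    series: np.ndarray,
    vol: FunctionalVolume,
    chunk_voxels: int | None,
) -> ProjectionResult:
    """Shared core: weights (n_grid_flat, n_sources), series (n_sources, T)."""
    n_flat = vol.grid.n_voxels
    n_frames = vol.n_frames
    w = sp.csr_matrix(weights)
    denom = np.asarray(w.sum(axis=1)).ravel()

    out_flat = np.zeros((n_flat, n_frames), dtype=np.float64)
    if chunk_voxels is None:
        numer = w @ series
        covered = denom > 0
        out_flat[covered] = numer[covered] / denom[covered, None]
    else:
        for start in range(0, n_flat, chunk_voxels):
            stop = min(start + chunk_voxels, n_flat)
            numer = w[start:stop] @ series
            d = denom[start:stop]
            covered = d > 0
            block = np.zeros((stop - start, n_frames))
            block[covered] = numer[covered] / d[covered, None]
            out_flat[start:stop] = block

    shape = vol.grid.shape
    out = FunctionalVolume(vol.grid, out_flat.reshape(shape + (n_frames,)), tr=vol.tr)
    cov_arr = denom.reshape(shape)
    coverage = CoverageMap(vol.grid, cov_arr)
    uncovered = Mask.from_array(vol.grid, cov_arr == 0)
    return ProjectionResult(out, coverage, uncovered)


def project_voxelwise(
    f: FunctionalVolume,
    m: Mask,
    priors: PriorsStore,
    chunk_voxels: int | None = None,
) -> ProjectionResult:
    """Project masked BOLD onto the grid using voxel-wise priors.

    Every mask voxel must have a priors entry; missing seeds raise with the
    offending list. ``chunk_voxels`` splits the output into slabs of that
    many voxels (bit-identical to the all-in-memory path).
    """
    if priors.mode != "voxel":
        raise ValueError("project_voxelwise requires voxel-wise priors")
    require_same_grid(f, m, "BOLD and mask")
    require_same_grid(f, priors, "BOLD and priors")
    mask_vox = m.sorted_voxels()
    if not mask_vox:
        raise ValueError("analysis mask is empty")
    missing = [v for v in mask_vox if v not in priors]
    if missing:
        raise KeyError(
            f"{len(missing)} mask voxel(s) missing from priors, e.g. {missing[:5]}"
        )

    n_flat = f.grid.n_voxels
    cols, rows, vals = [], [], []
    for j, v in enumerate(mask_vox):
        flat = priors[v].data.ravel(order="C")
        nz = np.flatnonzero(flat)
        rows.append(nz)
        cols.append(np.full(nz.size, j, dtype=np.int64))
        vals.append(flat[nz])
    w = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_flat, len(mask_vox)),
    )
    series = np.stack([f.data[v] for v in mask_vox])  # (n_mask, T)
    return _weighted_average(w, series, f, chunk_voxels)


def project_regionwise(
    f: FunctionalVolume,
    parc: Parcellation,
    priors: PriorsStore,
    chunk_voxels: int | None = None,
) -> ProjectionResult:
    """Project parcel-mean BOLD onto the grid using region-wise priors.

    Each nonzero parcel contributes its mean time-series over the parcel's
    voxels, weighted by the parcel's probability map.
    """
    if priors.mode != "region":
        raise ValueError("project_regionwise requires region-wise priors")
    require_same_grid(f, parc, "BOLD and parcellation")
    require_same_grid(f, priors, "BOLD and priors")
    labels = parc.region_labels()
    if not labels:
        raise ValueError("parcellation has no nonzero regions")
    missing = [lab for lab in labels if lab not in priors]
    if missing:
        raise KeyError(f"region label(s) missing from priors: {missing}")

    n_flat = f.grid.n_voxels
    cols, rows, vals = [], [], []
    series_rows = []
    for j, lab in enumerate(labels):
        flat = priors[lab].data.ravel(order="C")
        nz = np.flatnonzero(flat)
        rows.append(nz)
        cols.append(np.full(nz.size, j, dtype=np.int64))
        vals.append(flat[nz])
        region = parc.labels == lab
        series_rows.append(f.data[region].mean(axis=0))
    w = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_flat, len(labels)),
    )
    series = np.stack(series_rows)
    return _weighted_average(w, series, f, chunk_voxels)


def mask_to_white_matter(result, wm: Mask):
    """Zero values outside the white-matter mask (for reporting only).

    Accepts a ProjectionResult, FunctionalVolume, ProbabilityMap, or a
    stat-map-like object with ``grid`` and 3D ``beta``/``t``/``z`` arrays;
    returns the same type with values outside ``wm`` set to 0.
    """
    from .glm import StatMap  # local import to avoid a cycle

    keep = wm.to_array(bool)
    if isinstance(result, ProjectionResult):
        require_same_grid(result.volume, wm, "result and white-matter mask")
        vol = FunctionalVolume(
            result.volume.grid,
            result.volume.data * keep[..., None],
            tr=result.volume.tr,
        )
        cov = CoverageMap(result.coverage.grid, result.coverage.data * keep)
        return ProjectionResult(vol, cov, result.uncovered)
    if isinstance(result, FunctionalVolume):
        require_same_grid(result, wm, "volume and white-matter mask")
        return FunctionalVolume(result.grid, result.data * keep[..., None], tr=result.tr)
    if isinstance(result, ProbabilityMap):
        require_same_grid(result, wm, "map and white-matter mask")
        return ProbabilityMap(result.grid, result.data * keep)
    if isinstance(result, StatMap):
        require_same_grid(result, wm, "stat map and white-matter mask")
        return StatMap(
            grid=result.grid,
            beta=result.beta * keep,
            t=result.t * keep,
            z=result.z * keep,
            dof=result.dof,
            mask=Mask.from_array(result.grid, result.mask.to_array(bool) & keep),
        )
    raise TypeError(f"cannot mask object of type {type(result).__name__}")
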