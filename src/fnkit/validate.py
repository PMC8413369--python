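"""Spatial map comparison: reproducibility correlations and cross-correlation.

Reproducibility is quantified as the Pearson correlation between the group
z-maps of two independent acquisitions of the same paradigm, computed over
an in-brain mask. Cross-correlation matrices compare two sets of spatial
maps (e.g. connectivity components against resting-state networks), with the
best match per row recovered by argmax.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import Mask, require_same_grid

__all__ = ["pearson_spatial", "crosscorr_matrix", "reproducibility_report"]


def _map_values(m, mask_arr: np.ndarray) -> np.ndarray:
    data = m.z if hasattr(m, "z") else m.data
    return np.asarray(data, dtype=np.float64)[mask_arr]


def _map_array(m) -> np.ndarray:
    return np.asarray(m.z if hasattr(m, "z") else m.data, dtype=np.float64)


def _default_mask(a, b) -> Mask:
    arr = (_map_array(a) != 0) | (_map_array(b) != 0)
    return Mask.from_array(a.grid, arr)


def pearson_spatial(a, b, mask: Mask | None = None) -> float:
    """Pearson r between two spatial maps over the voxels of ``mask``.

    Accepts stat maps (their z field is used) or probability maps. With no
    mask, the union of nonzero voxels of both maps is used, operationalising
    "excluding voxels outside the brain". Raises if either map has zero
    variance on the mask or the mask holds fewer than 3 voxels.
    """
    require_same_grid(a, b, "maps")
    if mask is None:
        mask = _default_mask(a, b)
    require_same_grid(a, mask, "maps and mask")
    keep = mask.to_array(bool)
    if keep.sum() < 3:
        raise ValueError("mask must contain at least 3 voxels")
    va = _map_values(a, keep)
    vb = _map_values(b, keep)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("zero variance inside the mask")
    r, _ = stats.pearsonr(va, vb)
    return float(r)


def crosscorr_matrix(
    set_a: list,
    set_b: list,
    mask: Mask | None = None,
    zero_negative: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """|A|×|B| matrix of spatial Pearson r, plus the argmax match per row.

    ``zero_negative`` (default) clips negative map values to 0 before
    correlating, as done when matching signed component maps.
    """
    from .core import ProbabilityMap
    from .project import CoverageMap

    if not set_a or not set_b:
        raise ValueError("both map sets must be non-empty")
    grid = set_a[0].grid
    for m in list(set_a) + list(set_b):
        require_same_grid(set_a[0], m, "maps in the two sets")

    def prep(m) -> np.ndarray:
        arr = _map_array(m)
        return np.maximum(arr, 0.0) if zero_negative else arr

    arrs_a = [prep(m) for m in set_a]
    arrs_b = [prep(m) for m in set_b]
    if mask is None:
        union = np.zeros(grid.shape, dtype=bool)
        for arr in arrs_a + arrs_b:
            union |= arr != 0
        mask = Mask.from_array(grid, union)
    keep = mask.to_array(bool)

    r = np.empty((len(arrs_a), len(arrs_b)))
    for i, va in enumerate(arrs_a):
        for j, vb in enumerate(arrs_b):
            x, y = va[keep], vb[keep]
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError("zero variance inside the mask")
            r[i, j] = stats.pearsonr(x, y)[0]
    return r, r.argmax(axis=1)


def reproducibility_report(
    zmaps_run1: dict[str, object],
    zmaps_run2: dict[str, object],
    mask: Mask | None = None,
) -> pd.DataFrame:
    """Per-task run-1 vs run-2 Pearson r, with mean and sd across tasks.

    ``zmaps_run1`` and ``zmaps_run2`` map task name → group z-map and must
    hold the same tasks. Nested dicts (method → task → map) produce one row
    per method, mirroring a methods × tasks reproducibility table.
    """
    if set(zmaps_run1) != set(zmaps_run2):
        raise ValueError("run-1 and run-2 tasks do not match")
    nested = any(isinstance(v, dict) for v in zmaps_run1.values())
    if nested:
        rows = {}
        for method in zmaps_run1:
            sub = reproducibility_report(zmaps_run1[method], zmaps_run2[method], mask)
            rows[method] = sub.iloc[0]
        return pd.DataFrame(rows).T

    tasks = list(zmaps_run1)
    r_vals = {
        task: pearson_spatial(zmaps_run1[task], zmaps_run2[task], mask)
        for task in tasks
    }
    row = dict(r_vals)
    vals = np.array(list(r_vals.values()))
    row["mean"] = float(vals.mean())
    row["sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return pd.DataFrame([row], index=["r"])


def write_report(report: pd.DataFrame, path) -> None:
    """Write a reproducibility table as TSV."""
    report.to_csv(path, sep="\t", float_format="%.4f")
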