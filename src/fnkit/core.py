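"""Shared data model and I/O.

Defines the voxel-grid geometry every other module relies on, thin dataclass
wrappers around the in-memory objects (4D BOLD volumes, masks, probability
maps, parcellations, streamline sets), NIfTI and TRK/TCK readers/writers, and
the HDF5 archive format used to persist a keyed collection of connectivity
probability maps.

Geometry convention (NIfTI): the continuous voxel coordinate ``(i, j, k)``
maps to world mm via ``affine @ (i, j, k, 1)``; that world point is the
*center* of voxel ``(i, j, k)``, so a world point belongs to the voxel whose
integer coordinates are nearest (half-open boxes ``[i-0.5, i+0.5)`` in voxel
space). Voxel indexing is 0-based throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import nibabel as nib

__all__ = [
    "VoxelGrid",
    "FunctionalVolume",
    "Mask",
    "ProbabilityMap",
    "Parcellation",
    "StreamlineSet",
    "PriorsStore",
    "GridMismatchError",
    "check_same_grid",
    "require_same_grid",
    "read_volume",
    "write_volume",
    "read_streamlines",
    "write_streamlines",
    "save_priors",
    "load_priors",
]

#: absolute tolerance (mm) when comparing affines of two grids
AFFINE_ATOL = 1e-4

#: on-disk volumes are written in this dtype; in-memory arithmetic is float64
DISK_DTYPE = np.float32


class GridMismatchError(ValueError):
    """Raised when two objects expected to share a voxel grid do not."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with a voxel→world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=np.float64)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine's spatial columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel coordinates (centers at integers) to world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk))
        return np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)


def _as_grid(obj) -> VoxelGrid:
    return obj if isinstance(obj, VoxelGrid) else obj.grid


def check_same_grid(a, b) -> bool:
    """True iff the two grid-bearing objects share shape and affine.

    Affines are compared with an absolute tolerance of ``AFFINE_ATOL`` mm.
    Pure predicate: never raises.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    return ga.shape == gb.shape and bool(
        np.allclose(ga.affine, gb.affine, rtol=0.0, atol=AFFINE_ATOL)
    )


def require_same_grid(a, b, what: str = "inputs") -> None:
    if not check_same_grid(a, b):
        raise GridMismatchError(f"{what} are defined on different voxel grids")


@dataclass
class FunctionalVolume:
    """A 4D scalar field ``data[x, y, z, t]`` with repetition time ``tr`` (s)."""

    grid: VoxelGrid
    data: np.ndarray
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ValueError("data must be 4D with at least one frame")
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError("data spatial shape does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class Mask:
    """A set of voxel indices on a grid."""

    grid: VoxelGrid
    voxels: frozenset[tuple[int, int, int]]

    def __post_init__(self) -> None:
        vox = frozenset(tuple(int(c) for c in v) for v in self.voxels)
        shape = self.grid.shape
        for v in vox:
            if not all(0 <= v[d] < shape[d] for d in range(3)):
                raise ValueError(f"voxel {v} outside grid shape {shape}")
        self.voxels = vox

    @classmethod
    def from_array(cls, grid: VoxelGrid, arr: np.ndarray) -> "Mask":
        arr = np.asarray(arr)
        if arr.shape != grid.shape:
            raise ValueError("mask array shape does not match grid")
        idx = np.argwhere(arr > 0)
        return cls(grid, frozenset(map(tuple, idx.tolist())))

    def to_array(self, dtype=bool) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=dtype)
        if self.voxels:
            idx = np.array(sorted(self.voxels))
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return out

    def sorted_voxels(self) -> list[tuple[int, int, int]]:
        return sorted(self.voxels)

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass
class ProbabilityMap:
    """A 3D field of connection probabilities in [0, 1]."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError("data shape does not match grid")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("probability values must lie in [0, 1]")


@dataclass
class Parcellation:
    """An integer-labelled 3D volume; 0 is background."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("labels must be integers")
            labels = rounded.astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels

    def region_labels(self) -> list[int]:
        """Sorted nonzero labels present in the volume."""
        return sorted(int(l) for l in np.unique(self.labels) if l != 0)

    def region_voxels(self, label: int) -> list[tuple[int, int, int]]:
        idx = np.argwhere(self.labels == label)
        return [tuple(v) for v in idx.tolist()]


@dataclass
class StreamlineSet:
    """Polylines in world mm for one subject."""

    streamlines: list[np.ndarray]
    subject_id: str = ""

    def __post_init__(self) -> None:
        lines = []
        for line in self.streamlines:
            arr = np.asarray(line, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError("each streamline must be an (N>=2, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline contains non-finite points")
            lines.append(arr)
        self.streamlines = lines

    def __len__(self) -> int:
        return len(self.streamlines)


SeedKey = Union[tuple[int, int, int], int]


@dataclass
class PriorsStore:
    """Keyed container of connectivity probability maps.

    ``mode`` is ``"voxel"`` (keys are voxel index triples) or ``"region"``
    (keys are integer parcel labels). All entries share ``grid``.
    """

    grid: VoxelGrid
    mode: str
    entries: dict[SeedKey, ProbabilityMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("voxel", "region"):
            raise ValueError("mode must be 'voxel' or 'region'")
        for key, pmap in self.entries.items():
            self._check_key(key)
            if not check_same_grid(self.grid, pmap):
                raise GridMismatchError(f"entry {key} on a different grid")

    def _check_key(self, key: SeedKey) -> None:
        if self.mode == "voxel":
            if not (isinstance(key, tuple) and len(key) == 3):
                raise ValueError(f"voxel-wise key must be an index triple: {key}")
        elif not isinstance(key, (int, np.integer)):
            raise ValueError(f"region-wise key must be an integer label: {key}")

    def __contains__(self, key: SeedKey) -> bool:
        return key in self.entries

    def __getitem__(self, key: SeedKey) -> ProbabilityMap:
        return self.entries[key]

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self):
        return self.entries.keys()


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_img(img) -> VoxelGrid:
    return VoxelGrid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine))


def read_volume(path, role: str = "auto"):
    """Read a NIfTI file as one of the grid-bearing types.

    ``role`` selects the returned type for 3D files: ``"probability"``,
    ``"mask"`` (binarised at > 0), ``"parcellation"``, or ``"functional"``
    (also the only valid role for 4D files). ``"auto"`` returns a
    FunctionalVolume for 4D input and a ProbabilityMap-like raw reading is
    ambiguous for 3D, so 3D auto input is returned as a Mask if binary,
    otherwise an error asks for an explicit role.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D NIfTI, got {data.ndim}D: {path}")
    grid = _grid_from_img(img)

    if data.ndim == 4:
        if role not in ("auto", "functional"):
            raise ValueError(f"4D file cannot be read as {role!r}")
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return FunctionalVolume(grid, data, tr=tr)

    if role == "functional":
        return FunctionalVolume(grid, data[..., np.newaxis], tr=1.0)
    if role == "probability":
        return ProbabilityMap(grid, data)
    if role == "mask":
        return Mask.from_array(grid, data > 0)
    if role == "parcellation":
        return Parcellation(grid, np.rint(data).astype(np.int32))
    if role == "auto":
        uniq = np.unique(data)
        if np.all(np.isin(uniq, (0.0, 1.0))):
            return Mask.from_array(grid, data > 0)
        raise ValueError(
            "3D file with non-binary values: pass role='probability', "
            "'mask' or 'parcellation'"
        )
    raise ValueError(f"unknown role {role!r}")


def write_volume(obj, path) -> None:
    """Write a grid-bearing object to NIfTI (float32 on disk, uint16 labels)."""
    if isinstance(obj, FunctionalVolume):
        img = nib.Nifti1Image(obj.data.astype(DISK_DTYPE), obj.grid.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = obj.tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    elif isinstance(obj, ProbabilityMap):
        img = nib.Nifti1Image(obj.data.astype(DISK_DTYPE), obj.grid.affine)
    elif isinstance(obj, Mask):
        img = nib.Nifti1Image(obj.to_array(np.uint8), obj.grid.affine)
    elif isinstance(obj, Parcellation):
        img = nib.Nifti1Image(obj.labels.astype(np.int32), obj.grid.affine)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# streamline I/O (TRK / TCK via nibabel)
# ---------------------------------------------------------------------------

def read_streamlines(path, subject_id: str | None = None) -> StreamlineSet:
    """Load a TRK or TCK file; polylines are returned in world mm (RAS).

    An empty file yields an empty StreamlineSet with a warning.
    """
    path = Path(path)
    tractogram_file = nib.streamlines.load(str(path))
    lines = [np.asarray(s, dtype=np.float64) for s in tractogram_file.streamlines]
    lines = [l for l in lines if l.shape[0] >= 2]
    if not lines:
        warnings.warn(f"no streamlines found in {path}", stacklevel=2)
        return StreamlineSet([], subject_id=subject_id or path.stem)
    return StreamlineSet(lines, subject_id=subject_id or path.stem)


def write_streamlines(sset: StreamlineSet, path, grid: VoxelGrid | None = None) -> None:
    """Write streamlines to TRK or TCK (chosen by extension), world-mm coords."""
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".trk":
        header = {}
        if grid is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = grid.affine.astype(
                np.float32
            )
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = grid.voxel_size.astype(
                np.float32
            )
            header[nib.streamlines.trk.Field.DIMENSIONS] = np.array(
                grid.shape, dtype=np.int16
            )
        nib.streamlines.save(tractogram, str(path), header=header)
    elif path.suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    else:
        raise ValueError(f"unsupported streamline format: {path.suffix}")


# ---------------------------------------------------------------------------
# priors archive (HDF5)
# ---------------------------------------------------------------------------
# Layout: root attrs {mode, shape, affine}; one group per seed key holding
# sparse nonzero voxels as flat C-order indices ("idx", uint64) and float32
# values ("val"). Voxel keys serialise as "i_j_k", region keys as "r<label>".

def _key_to_name(mode: str, key: SeedKey) -> str:
    if mode == "voxel":
        return "{}_{}_{}".format(*key)
    return f"r{int(key)}"


def _name_to_key(mode: str, name: str) -> SeedKey:
    if mode == "voxel":
        return tuple(int(p) for p in name.split("_"))
    return int(name[1:])


def save_priors(store: PriorsStore, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.attrs["mode"] = store.mode
        f.attrs["shape"] = np.array(store.grid.shape, dtype=np.int64)
        f.attrs["affine"] = store.grid.affine
        for key, pmap in store.entries.items():
            grp = f.create_group(_key_to_name(store.mode, key))
            flat = pmap.data.ravel(order="C")
            idx = np.flatnonzero(flat)
            grp.create_dataset("idx", data=idx.astype(np.uint64))
            grp.create_dataset("val", data=flat[idx].astype(DISK_DTYPE))


def load_priors(path) -> PriorsStore:
    with h5py.File(str(path), "r") as f:
        mode = str(f.attrs["mode"])
        shape = tuple(int(s) for s in f.attrs["shape"])
        grid = VoxelGrid(shape, np.asarray(f.attrs["affine"]))
        entries: dict[SeedKey, ProbabilityMap] = {}
        for name in f:
            idx = np.asarray(f[name]["idx"], dtype=np.int64)
            val = np.asarray(f[name]["val"], dtype=np.float64)
            data = np.zeros(grid.n_voxels, dtype=np.float64)
            data[idx] = val
            entries[_name_to_key(mode, name)] = ProbabilityMap(
                grid, data.reshape(shape)
            )
    return PriorsStore(grid, mode, entries)
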