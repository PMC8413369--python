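"""Synthetic phantom: grid, grey-matter regions, tract, streamlines, BOLD.

The phantom is a small brain-like lattice (default 20x20x20 voxels at 2 mm)
with two grey-matter endpoint regions A and B joined by a straight
white-matter tract, plus an off-circuit control region C. Pseudo-subject
tractograms are jittered polylines along the tract centerline with
distractor streamlines elsewhere in white matter; task BOLD is a baseline of
100 with an HRF-convolved boxcar added in active regions and i.i.d. Gaussian
noise everywhere. Every quantity needed to verify the pipeline (tract
membership, per-seed connection fractions, injected amplitudes) is known by
construction.

Amplitudes are expressed in percent signal change of the 100-unit baseline,
so ``amp_a = 1.0`` injects a unit-peak regressor scaled to 1.0 signal units;
``noise_sd`` uses the same units (1.0 = 1% of baseline). Each subject has
two runs differing only in the noise realisation, emulating a test-retest
acquisition pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FunctionalVolume, Mask, Parcellation, StreamlineSet, VoxelGrid
from .glm import task_regressor

__all__ = [
    "SimulationConfig",
    "Phantom",
    "make_phantom",
    "default_onsets",
    "simulate_streamlines",
    "simulate_bold",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Phantom and simulation parameters (the study conditions)."""

    n_subjects: int = 10
    n_frames: int = 200
    tr: float = 1.0  # s
    amp_a: float = 1.0  # % signal change in region A
    amp_b: float = 1.0  # % signal change in region B
    amp_c: float = 0.0  # % signal change in control region C
    noise_sd: float = 1.0  # baseline units (1.0 = 1% of baseline)
    noise_ar1: float = 0.0  # lag-1 autocorrelation of the noise
    streamline_jitter: float = 1.0  # mm, per-point positional sd
    seed: int = 42
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 2.0  # mm, isotropic
    region_size: int = 3  # edge length (voxels) of the cubic GM regions
    n_tract_streamlines: int = 20  # per subject
    n_distractor_streamlines: int = 10  # per subject
    tract_absent_subjects: tuple[int, ...] = ()  # subjects with no tract bundle

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.region_size < 1 or self.region_size % 2 == 0:
            raise ValueError("region_size must be odd and >= 1")


@dataclass
class Phantom:
    """The synthetic anatomy; all voxel sets are disjoint by construction."""

    grid: VoxelGrid
    gm_regions: dict[str, frozenset[tuple[int, int, int]]]
    tract: list[tuple[int, int, int]]  # ordered path joining A and B
    wm_mask: Mask
    centerline: list[tuple[int, int, int]]  # A-center ... tract ... B-center

    @property
    def gm_mask(self) -> Mask:
        allv: set = set()
        for vox in self.gm_regions.values():
            allv |= vox
        return Mask(self.grid, frozenset(allv))

    @property
    def tract_mask(self) -> Mask:
        return Mask(self.grid, frozenset(self.tract))

    def parcellation(self) -> Parcellation:
        """Labelled regions: A = 1, B = 2, C = 3."""
        labels = np.zeros(self.grid.shape, dtype=np.int32)
        for value, name in enumerate(("A", "B", "C"), start=1):
            for v in self.gm_regions.get(name, ()):
                labels[v] = value
        return Parcellation(self.grid, labels)


def _cube(center: tuple[int, int, int], half: int) -> frozenset:
    cx, cy, cz = center
    return frozenset(
        (x, y, z)
        for x in range(cx - half, cx + half + 1)
        for y in range(cy - half, cy + half + 1)
        for z in range(cz - half, cz + half + 1)
    )


def make_phantom(cfg: SimulationConfig) -> Phantom:
    """Build the deterministic phantom anatomy for a configuration.

    Regions scale with the grid: A and B sit at 20% and 80% of the x extent
    on the central y/z axis, C is displaced in +y off the circuit, and the
    tract is the straight voxel path between the faces of A and B. The
    white-matter mask is a slab around the tract, disjoint from grey matter.
    """
    nx, ny, nz = cfg.grid_shape
    half = cfg.region_size // 2
    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    grid = VoxelGrid((nx, ny, nz), affine)

    cy, cz = ny // 2, nz // 2
    ax = max(half + 1, round(0.2 * nx))
    bx = nx - 1 - ax
    a = _cube((ax, cy, cz), half)
    b = _cube((bx, cy, cz), half)
    c = _cube((nx // 2, min(ny - 1 - half, cy + round(0.3 * ny)), cz), half)

    tract = [(x, cy, cz) for x in range(ax + half + 1, bx - half)]
    if not tract:
        raise ValueError("grid too small to hold regions and a tract")
    centerline = [(x, cy, cz) for x in range(ax, bx + 1)]

    wm_pad = 2
    wm_vox = frozenset(
        (x, y, z)
        for x in range(ax + half + 1, bx - half)
        for y in range(cy - wm_pad, cy + wm_pad + 1)
        for z in range(cz - wm_pad, cz + wm_pad + 1)
    )
    assert not (wm_vox & (a | b | c)), "white matter overlaps grey matter"
    return Phantom(
        grid=grid,
        gm_regions={"A": a, "B": b, "C": c},
        tract=tract,
        wm_mask=Mask(grid, wm_vox),
        centerline=centerline,
    )


def default_onsets(cfg: SimulationConfig) -> list[tuple[float, float]]:
    """Alternating 20 s off / 20 s on blocks filling the run."""
    duration = cfg.n_frames * cfg.tr
    block = 20.0
    onsets = []
    t = block
    while t + block <= duration + 1e-9:
        onsets.append((t, block))
        t += 2 * block
    return onsets


def _subject_rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def simulate_streamlines(ph: Phantom, cfg: SimulationConfig) -> list[StreamlineSet]:
    """Per-subject tractograms: jittered tract bundle plus distractors.

    Tract streamlines follow the voxel-center polyline from the center of A
    to the center of B with i.i.d. Gaussian positional jitter (sd =
    ``streamline_jitter`` mm) on every point; subjects listed in
    ``tract_absent_subjects`` receive no tract bundle. Distractor
    streamlines run across the white-matter slab two voxels below the tract
    plane, touching neither the tract nor grey matter at zero jitter.
    """
    center_world = ph.grid.voxel_to_world(np.array(ph.centerline, dtype=float))
    xs = sorted({v[0] for v in ph.tract})
    cy = ph.tract[0][1]
    cz = ph.tract[0][2]

    out = []
    for subj in range(cfg.n_subjects):
        rng = _subject_rng(cfg, 1, subj)
        lines = []
        if subj not in cfg.tract_absent_subjects:
            for _ in range(cfg.n_tract_streamlines):
                jitter = rng.normal(0.0, cfg.streamline_jitter, center_world.shape)
                lines.append(center_world + jitter)
        for k in range(cfg.n_distractor_streamlines):
            x = xs[k % len(xs)]
            path = np.array(
                [(x, y, cz - 2) for y in range(cy - 2, cy + 3)], dtype=float
            )
            world = ph.grid.voxel_to_world(path)
            jitter = rng.normal(0.0, cfg.streamline_jitter, world.shape)
            lines.append(world + jitter)
        out.append(StreamlineSet(lines, subject_id=f"sub-{subj:02d}"))
    return out


def _region_amplitudes(cfg: SimulationConfig) -> dict[str, float]:
    return {"A": cfg.amp_a, "B": cfg.amp_b, "C": cfg.amp_c}


def simulate_bold(
    ph: Phantom,
    cfg: SimulationConfig,
    onsets: list[tuple[float, float]] | None = None,
) -> list[tuple[FunctionalVolume, FunctionalVolume]]:
    """Two task BOLD runs per subject with independent noise realisations.

    Signal model per voxel: 100 + amp * r(t) + noise, where r is the
    unit-peak HRF-convolved boxcar and amp is the region's percent signal
    change (0 outside A/B/C). Noise is Gaussian with sd ``noise_sd``; a
    nonzero ``noise_ar1`` gives an AR(1) process with the same stationary
    sd.
    """
    if onsets is None:
        onsets = default_onsets(cfg)
    reg = task_regressor(onsets, cfg.n_frames, cfg.tr)
    baseline = 100.0
    signal = np.zeros(ph.grid.shape + (cfg.n_frames,))
    for name, amp in _region_amplitudes(cfg).items():
        if amp == 0:
            continue
        for v in ph.gm_regions[name]:
            signal[v] = amp * reg

    runs = []
    for subj in range(cfg.n_subjects):
        pair = []
        for run in (1, 2):
            rng = _subject_rng(cfg, 2, subj, run)
            noise = rng.normal(0.0, 1.0, ph.grid.shape + (cfg.n_frames,))
            if cfg.noise_ar1 != 0.0:
                rho = cfg.noise_ar1
                for t in range(1, cfg.n_frames):
                    noise[..., t] = rho * noise[..., t - 1] + np.sqrt(
                        1 - rho**2
                    ) * noise[..., t]
            data = baseline + signal + cfg.noise_sd * noise
            pair.append(FunctionalVolume(ph.grid, data, tr=cfg.tr))
        runs.append((pair[0], pair[1]))
    return runs
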