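"""Activation statistics: HRF design, first-level OLS, group z-maps, smoothing.

A deliberately compact first/second-level pipeline: the task boxcar is
convolved with a canonical double-gamma HRF on a fine time grid and sampled
at frame times; each voxel is fit by ordinary least squares (optionally with
one round of Cochrane–Orcutt AR(1) prewhitening); t statistics are mapped to
z through the Student-t survival function with symmetric tail handling; the
group map is a one-sample t on first-level contrast estimates. Classical
(non-projected) BOLD additionally gets Gaussian spatial smoothing; projected
volumes never do, since the projection already pools signal along circuits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import FunctionalVolume, Mask, VoxelGrid, require_same_grid

__all__ = [
    "DesignMatrix",
    "StatMap",
    "hrf_double_gamma",
    "task_regressor",
    "make_design",
    "fit_first_level",
    "fit_group",
    "smooth_volume",
    "z_from_t",
]

#: |z| cap; beyond this the normal quantile is not representable in float64
Z_CAP = 38.0

#: HRF shape: response peak and undershoot delays (s), undershoot ratio
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0  # s

#: fine-grid oversampling factor for boxcar/HRF convolution
OVERSAMPLE = 50


@dataclass
class DesignMatrix:
    """T×K regressor matrix with a contrast over its columns."""

    regressors: np.ndarray
    names: list[str]
    tr: float
    contrast: np.ndarray | None
    collinear: bool = False

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=np.float64)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a T x K matrix")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("regressors must be finite")
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("one name per regressor column required")
        if self.contrast is not None:
            self.contrast = np.asarray(self.contrast, dtype=np.float64)
            if self.contrast.shape != (self.regressors.shape[1],):
                raise ValueError("contrast length must equal number of columns")

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]


@dataclass
class StatMap:
    """Voxel-wise effect size and test statistics on a mask."""

    grid: VoxelGrid
    beta: np.ndarray
    t: np.ndarray
    z: np.ndarray
    dof: int
    mask: Mask

    def __post_init__(self) -> None:
        for name in ("beta", "t", "z"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            setattr(self, name, arr)
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        inmask = self.mask.to_array(bool)
        if not np.all(np.isfinite(self.z[inmask])):
            raise ValueError("non-finite statistics inside the mask")


def hrf_double_gamma(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (s), peak scaled to 1.

    Difference of two gamma densities (shape = delay / dispersion with unit
    dispersion): a positive response peaking near 5-6 s and an undershoot
    near 16 s at 1/6 amplitude.
    """
    t = np.asarray(t, dtype=np.float64)
    peak = stats.gamma.pdf(t, HRF_PEAK_DELAY, scale=1.0)
    under = stats.gamma.pdf(t, HRF_UNDERSHOOT_DELAY, scale=1.0)
    h = peak - under / HRF_RATIO
    m = h.max()
    return h / m if m > 0 else h


def task_regressor(
    onsets: list[tuple[float, float]], n_frames: int, tr: float
) -> np.ndarray:
    """HRF-convolved boxcar sampled at frame times, scaled to unit peak.

    The same regressor is used to build designs and to inject activation in
    the synthetic BOLD generator, so a noise-free recovery returns the
    injected amplitude exactly.
    """
    if n_frames < 1 or tr <= 0:
        raise ValueError("n_frames must be >= 1 and tr > 0")
    duration_s = n_frames * tr
    for onset, dur in onsets:
        if dur < 0:
            raise ValueError(f"negative event duration: {dur}")
        if onset < 0 or onset > duration_s:
            raise ValueError(f"event onset {onset}s outside the run")
    dt = tr / OVERSAMPLE
    n_fine = n_frames * OVERSAMPLE
    box = np.zeros(n_fine)
    for onset, dur in onsets:
        i0 = int(round(onset / dt))
        i1 = min(n_fine, int(round((onset + dur) / dt)))
        box[i0:i1] = 1.0
    h = hrf_double_gamma(np.arange(0.0, HRF_LENGTH, dt))
    fine = np.convolve(box, h)[:n_fine] * dt
    reg = fine[::OVERSAMPLE][:n_frames]
    m = np.abs(reg).max()
    return reg / m if m > 0 else reg


def make_design(
    onsets: list[tuple[float, float]], n_frames: int, tr: float
) -> DesignMatrix:
    """Build a task + intercept design with contrast on the task column.

    The task regressor is the HRF-convolved boxcar, mean-centred so the
    intercept carries the baseline. With no events the design is intercept
    only and has no valid contrast; a regressor that is constant over the
    run centres to (near) zero and is flagged collinear.
    """
    if not onsets:
        return DesignMatrix(
            regressors=np.ones((n_frames, 1)),
            names=["intercept"],
            tr=tr,
            contrast=None,
        )
    reg = task_regressor(onsets, n_frames, tr)
    centred = reg - reg.mean()
    collinear = float(np.abs(centred).max()) < 1e-8
    x = np.column_stack([centred, np.ones(n_frames)])
    return DesignMatrix(
        regressors=x,
        names=["task", "intercept"],
        tr=tr,
        contrast=np.array([1.0, 0.0]),
        collinear=collinear,
    )


def z_from_t(t: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to z scores via matched tail probabilities.

    Uses the survival function on |t| for numerical stability in the tails;
    results are capped at ±Z_CAP (beyond which the quantile overflows).
    """
    t = np.asarray(t, dtype=np.float64)
    p = stats.t.sf(np.abs(t), dof)
    z = stats.norm.isf(p)
    z = np.clip(z, -Z_CAP, Z_CAP)
    return np.sign(t) * z


def _stat_map_from_flat(
    grid: VoxelGrid,
    mask: Mask,
    vox: list[tuple[int, int, int]],
    beta: np.ndarray,
    tstat: np.ndarray,
    dof: int,
) -> StatMap:
    b3 = np.zeros(grid.shape)
    t3 = np.zeros(grid.shape)
    z3 = np.zeros(grid.shape)
    zstat = z_from_t(tstat, dof)
    for i, v in enumerate(vox):
        b3[v] = beta[i]
        t3[v] = tstat[i]
        z3[v] = zstat[i]
    return StatMap(grid=grid, beta=b3, t=t3, z=z3, dof=dof, mask=mask)


def _ols_contrast(
    y: np.ndarray, x: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS contrast estimate and t per column of y (T, n); dof = T - K."""
    n_frames, k = x.shape
    dof = n_frames - k
    if dof < 1:
        raise ValueError("not enough frames for the design")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta_hat = xtx_inv @ x.T @ y  # (K, n)
    resid = y - x @ beta_hat
    sigma2 = (resid**2).sum(axis=0) / dof
    eff = c @ beta_hat
    var = sigma2 * float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(var > 0, eff / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    # exact fits (zero residual, nonzero effect) get the capped statistic
    exact = (var <= 0) & (np.abs(eff) > 0)
    with np.errstate(invalid="ignore"):
        tstat = np.where(exact, np.sign(eff) * np.inf, tstat)
    return eff, tstat, dof


def fit_first_level(
    f: FunctionalVolume,
    design: DesignMatrix,
    mask: Mask,
    ar1: bool = False,
) -> StatMap:
    """Per-voxel OLS fit of the design; returns contrast beta, t and z maps.

    ``ar1=True`` adds one Cochrane–Orcutt round: the lag-1 residual
    autocorrelation is estimated per voxel, data and design are quasi-
    differenced, and the model is refit on the transformed series.
    """
    require_same_grid(f, mask, "BOLD and mask")
    if design.n_frames != f.n_frames:
        raise ValueError(
            f"design has {design.n_frames} frames, data has {f.n_frames}"
        )
    if design.contrast is None:
        raise ValueError("design has no contrast to test")
    if design.collinear:
        raise ValueError("task regressor is collinear with the intercept")
    x = design.regressors
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    vox = mask.sorted_voxels()
    if not vox:
        raise ValueError("mask is empty")
    y = np.stack([f.data[v] for v in vox], axis=1)  # (T, n)
    c = design.contrast

    if ar1:
        xtx_inv = np.linalg.inv(x.T @ x)
        resid = y - x @ (xtx_inv @ x.T @ y)
        num = (resid[1:] * resid[:-1]).sum(axis=0)
        den = (resid[:-1] ** 2).sum(axis=0)
        rho = np.where(den > 0, num / den, 0.0).clip(-0.99, 0.99)
        eff = np.empty(y.shape[1])
        tstat = np.empty(y.shape[1])
        dof = (f.n_frames - 1) - x.shape[1]
        for i in range(y.shape[1]):
            ys = (y[1:, i] - rho[i] * y[:-1, i])[:, None]
            xs = x[1:] - rho[i] * x[:-1]
            e, t_, dof = _ols_contrast(ys, xs, c)
            eff[i], tstat[i] = e[0], t_[0]
    else:
        eff, tstat, dof = _ols_contrast(y, x, c)

    tstat = np.clip(tstat, -1e300, 1e300)
    return _stat_map_from_flat(f.grid, mask, vox, eff, tstat, dof)


def fit_group(maps: list[StatMap]) -> StatMap:
    """One-sample t over subjects' first-level contrast estimates.

    Per voxel: t = mean(beta) / sqrt(var / n) with the sample variance
    floored at 1e-12 (identical betas give the capped z rather than NaN);
    dof = n - 1.
    """
    if len(maps) < 3:
        raise ValueError("group analysis requires at least 3 subjects")
    first = maps[0]
    for m in maps[1:]:
        require_same_grid(first, m, "group input maps")
    n = len(maps)
    betas = np.stack([m.beta for m in maps], axis=-1)  # (x,y,z,n)
    mean = betas.mean(axis=-1)
    var = betas.var(axis=-1, ddof=1)
    tstat = mean / np.sqrt(np.maximum(var, 1e-12) / n)
    # a degenerate sample (identical nonzero betas) gets the capped statistic
    with np.errstate(invalid="ignore"):
        tstat = np.where(
            (var <= 1e-12) & (np.abs(mean) > 0), np.sign(mean) * np.inf, tstat
        )
    dof = n - 1

    mask_arr = np.ones(first.grid.shape, dtype=bool)
    for m in maps:
        mask_arr &= m.mask.to_array(bool)
    mask = Mask.from_array(first.grid, mask_arr)
    z = z_from_t(tstat, dof)
    tstat = np.clip(tstat, -1e300, 1e300)
    keep = mask_arr.astype(float)
    return StatMap(
        grid=first.grid,
        beta=mean * keep,
        t=tstat * keep,
        z=z * keep,
        dof=dof,
        mask=mask,
    )


def smooth_volume(f: FunctionalVolume, fwhm: float) -> FunctionalVolume:
    """Per-frame 3D Gaussian smoothing with the kernel width given in mm.

    sigma (voxels) = fwhm / (2 sqrt(2 ln 2)) / voxel_size, per axis, so
    anisotropic grids smooth isotropically in mm. ``fwhm=0`` is the
    identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return FunctionalVolume(f.grid, f.data.copy(), tr=f.tr)
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / f.grid.voxel_size
    out = np.empty_like(f.data)
    for frame in range(f.n_frames):
        out[..., frame] = ndimage.gaussian_filter(
            f.data[..., frame], sigma=sigma_vox, mode="reflect"
        )
    return FunctionalVolume(f.grid, out, tr=f.tr)
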