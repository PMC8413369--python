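# Methods

This note documents the models, conventions and design decisions behind
`fnkit`, in the spirit of the methods documentation of established
neuroimaging packages.

## Geometry and data model

All volumes live on a `VoxelGrid`: a 3D shape plus a 4×4 voxel→world affine
in mm. Following the NIfTI convention, the continuous voxel coordinate
`(i, j, k)` maps through the affine to the *center* of voxel `(i, j, k)`;
a world point therefore belongs to the voxel with the nearest integer
coordinates (half-open boxes `[i−0.5, i+0.5)` in voxel space). Indexing is
0-based. Two grids are considered identical when shapes match and affines
agree within 1e-4 mm absolute; every cross-input operation enforces this and
refuses mismatched grids. Internal arithmetic is float64; volumes are
written to disk as float32 (labels as int32).

Streamlines are polylines in world mm, read and written through nibabel's
TRK/TCK support, which normalises the on-disk coordinate conventions to
RAS mm.

## Connectivity priors

For a seed voxel s (or parcel R), the prior is built per subject by
selecting the streamlines whose voxel traversal intersects s (any voxel of
R), marking every voxel those streamlines visit with 1, and averaging the
binary maps across subjects. Values are exact fractions k/n; no
thresholding or normalisation is applied afterwards. Seeds that no
streamline touches keep an all-zero map so that downstream projection can
report the resulting coverage gap explicitly.

Streamline–voxel intersection defaults to exact Amanatides–Woo voxel
traversal. The operation's contract is "every voxel the polyline passes
through", and a sampling-based rasteriser provably misses voxels clipped
near corners over chords shorter than its step; the exact walk has no such
failure mode and is cheap at the segment counts involved. A resampling
backend (step = min(voxel size)/4, the discretisation typical of
streamline-density tools) is provided and is cross-checked in the tests as
a subset of the exact traversal.

Priors are persisted as a single HDF5 archive: root attributes `mode`
(`voxel` or `region`), `shape` and `affine`; one group per seed holding the
nonzero voxels as flat C-order indices plus float32 values. This keeps a
many-thousand-map collection in one file with sparse storage.

## The projection

With analysis mask M, priors {P_m} and BOLD F, each output voxel receives
`Σ_m P_m(v)·F(m,t) / Σ_m P_m(v)`. The denominator is the raw probability
sum (a `CoverageMap`; it exceeds 1 wherever many seeds connect). Implemented
as one sparse weight matrix (grid voxels × seeds) applied to the seed × time
series matrix, which makes the weighted average exact to machine precision
and independent of seed iteration order; an optional output-slab chunking
path is bit-identical to the in-memory path. Region-wise projection is the
same contract with parcel-mean time series and per-parcel priors.

Conventions at the edges:

- Voxels with zero probability sum are set to 0 at all time points and
  returned in an `uncovered` mask, rather than NaN, keeping downstream GLMs
  finite while preserving the information.
- Every mask voxel must have a priors entry; missing entries are an error
  that lists the offenders, since silently dropping seeds would change the
  weighted average.
- The analysis mask is caller-supplied (in practice a "good voxels"
  grey-matter mask); no coefficient-of-variation screening is performed by
  the package.
- Projected volumes are never spatially smoothed: the projection already
  pools signal along anatomically connected voxels, which is its analogue
  of smoothing's SNR gain.
- White-matter masking of outputs is a reporting step only and is never
  applied before statistics.

Because every covered output value is a convex combination of mask-voxel
values, the projected signal is bounded by the min and max of the
contributing BOLD series — it stays on the BOLD scale; this convexity, the
transform's linearity in F, and order invariance are asserted as property
tests.

## Activation statistics

The GLM layer is a deliberately simplified stand-in for a full FSL-style
pipeline that preserves the method's logic:

- **Design.** Task boxcar convolved with a double-gamma HRF on a tr/50
  micro-time grid, sampled at frame times and scaled to unit peak. HRF
  parameters are the conventional SPM/FSL defaults: response gamma with
  shape 6, undershoot with shape 16, unit dispersion, undershoot ratio 1/6,
  32 s support (peak ≈ 5 s). The task regressor is mean-centred and an
  intercept appended; an events-free design has no contrast and a
  constant-after-centring regressor is flagged collinear.
- **First level.** Per-voxel OLS; contrast t with dof = T − K; optional
  single-round Cochrane–Orcutt AR(1) prewhitening (per-voxel lag-1 residual
  autocorrelation, quasi-differencing, refit), off by default because the
  phantom's noise is white by default.
- **t→z.** Matched tail probabilities via the Student survival function,
  symmetric in the sign of t and capped at |z| = 38, beyond which the
  normal quantile is not representable in double precision. Exact fits
  (zero residual with nonzero effect) and zero-variance group samples
  receive the capped value rather than NaN.
- **Group level.** One-sample t over per-subject contrast estimates,
  dof = n − 1, sample variance floored at 1e-12.
- **Smoothing** (classical arm only, 4 mm FWHM by default): per-frame 3D
  Gaussian with σ = FWHM/(2√(2 ln 2)) converted to voxels per axis, so
  anisotropic grids smooth isotropically in mm; reflective boundaries keep
  the DC gain at 1.

Multiple-comparison correction is out of scope; comparisons on the phantom
use ranks and effect contrasts rather than a fixed threshold.

## Map comparison

Spatial Pearson r is computed over a caller-supplied in-brain mask
(default: union of the nonzero voxels of the two maps), requiring at least
3 voxels and nonzero variance in both maps. Cross-correlation matrices
between two sets of maps zero the negative values by default (the usual
convention when matching signed component maps) and report the argmax match
per row. Reproducibility tables hold one row per method and one column per
task plus mean and sd, written as TSV.

## The phantom

The synthetic phantom emulates the full data constellation at desk scale:

- **Grid**: 20×20×20 voxels, 2 mm isotropic (diagonal affine).
- **Anatomy**: two 3×3×3 grey-matter regions A and B at 20% and 80% of the
  x-extent on the central axis, joined by a straight 8-voxel tract; a third
  region C displaced in +y serves as an off-circuit control; the
  white-matter mask is a 5×5 slab around the tract, disjoint from grey
  matter. Region size and grid shape are configurable and the geometry
  scales with them.
- **Tractograms**: per subject, 20 streamlines along the A-center→B-center
  polyline with i.i.d. Gaussian positional jitter (default sd 1 mm, half a
  voxel — enough to make priors non-trivial fractions without dissolving
  the bundle), plus 10 distractor streamlines crossing the white-matter
  slab two voxels below the tract plane. Specific subjects can be
  configured to lack the tract bundle entirely, giving exactly-known
  connection fractions.
- **BOLD**: baseline 100; active regions add amplitude × unit-peak
  HRF-convolved boxcar, with amplitude in percent signal change (default
  1%); i.i.d. Gaussian noise everywhere (default sd 1% of baseline), with
  an optional AR(1) mode to exercise prewhitening. Default paradigm:
  alternating 20 s off/on blocks over 200 frames at TR 1 s. Each subject
  gets two runs differing only in the noise realisation, emulating a
  test–retest acquisition pair. All randomness flows from one integer seed
  through per-(subject, run) child generators, so outputs are fully
  deterministic.

The default experiment (10 subjects, normative priors built from all
subjects' tractograms, first-level on the grey ∪ white mask, group
one-sample t per run) runs in a few seconds on one CPU; those sizes were
chosen so the whole validation suite stays interactive.

What the phantom does *not* model: hemodynamic variability across regions,
motion, distortion, physiological noise, registration error, and realistic
tract geometry (crossing, fanning). Passing tests therefore demonstrate the
correctness and internal logic of the pipeline — exact priors fractions,
the convex weighted average, calibrated null statistics, and the
directional claims (circuit detection when both endpoints activate, the
unilateral-activation penalty, higher test–retest reproducibility of the
projected arm) — not performance on real acquisitions.

## Known limitations

- Voxel-wise priors at full brain scale (hundreds of thousands of seeds)
  would need out-of-core accumulation; the in-memory builder targets masks
  up to a few thousand seeds.
- The GLM is OLS-based; FSL's FILM prewhitening and FLAME mixed-effects
  variance modelling are intentionally not replicated.
- No surface (GIFTI/CIFTI) support and no resampling between grids; inputs
  must already share a grid.
- ICA decomposition is out of scope; the comparison tools accept component
  maps produced elsewhere.
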