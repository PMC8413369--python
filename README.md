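# fnkit — projecting task fMRI onto white-matter circuits

Classical task-fMRI analysis stops at the grey matter: a voxel-wise GLM on
the BOLD signal reveals which cortical and subcortical regions activate, but
says nothing about the white-matter circuits that connect them. `fnkit`
implements a projection method that re-expresses grey-matter BOLD on the
white matter using anatomical connectivity priors derived from streamline
tractography, so that standard activation statistics can be run on brain
circuits instead of isolated regions. It is aimed at neuroimaging
researchers who have task fMRI and (their own or normative) whole-brain
tractograms, and at methodologists who want a small, fully testable
implementation of the approach.

## The method

**Connectivity priors.** For each seed (a voxel, or a parcel of an atlas),
the prior `P_seed` is a 3D map of the probability that a streamline connects
the seed to every other voxel. It is built from per-subject tractograms: the
streamlines crossing the seed are selected, the set of voxels they visit is
binarised, and the binary maps are averaged across subjects — so each value
is an exact fraction k/n of subjects showing the connection.

**The projection.** Given a 4D BOLD volume `F`, an analysis mask `M` of
grey-matter voxels, and the priors, the projected signal at voxel `v` and
time `t` is the connectivity-weighted average

```
out(v, t) = Σ_{m ∈ M} P_m(v) · F(m, t)  /  Σ_{m ∈ M} P_m(v)
```

The division by the probability sum makes every covered output voxel a
convex combination of grey-matter time series, so the projected volume stays
on the BOLD scale. Voxels with zero probability sum are reported as
uncovered. A region-wise variant uses parcel-mean time series and per-parcel
priors for a much cheaper analysis.

**Statistics.** The projected 4D volume is analysed exactly like BOLD: a
double-gamma HRF design, per-voxel OLS (optional AR(1) prewhitening),
t→z conversion, and a one-sample group t over subjects. No spatial smoothing
is applied to projected volumes — the projection already pools signal along
circuits — while the classical comparison arm is smoothed (4 mm FWHM).
Because a circuit's signal mixes both of its endpoints, a circuit only
activates strongly when both endpoint regions do; unilateral activation is
penalised.

**Validation tooling.** Spatial Pearson correlation between z-maps
quantifies test–retest reproducibility; cross-correlation matrices with
argmax matching compare sets of spatial maps. A synthetic phantom (two
grey-matter regions joined by a white-matter tract, jittered streamlines,
HRF-convolved block-design BOLD with Gaussian noise) provides known ground
truth for every stage, with no data download.

## Worked example

Run the full phantom comparison — priors from 10 simulated subjects'
tractograms, voxel-wise projection, first-level and group GLM in both arms:

```python
from fnkit import SimulationConfig, run_phantom_experiment, pearson_spatial
from fnkit.pipeline import tract_vs_wm_summary

exp = run_phantom_experiment(SimulationConfig(seed=42))
for arm in ("projected", "classical"):
    s = tract_vs_wm_summary(exp, arm)
    print(f"{arm:>9}: tract mean z = {s['tract_mean_z']:.2f}, "
          f"white-matter 95th pct z = {s['wm_q95_z']:.2f}")
mask = exp.analysis_mask
for arm in ("projected", "classical"):
    r = pearson_spatial(exp.group[arm]["run1"], exp.group[arm]["run2"], mask)
    print(f"{arm:>9}: run1 vs run2 r = {r:.3f}")
```

prints

```
projected: tract mean z = 8.08, white-matter 95th pct z = 7.89
classical: tract mean z = 1.48, white-matter 95th pct z = 5.16
projected: run1 vs run2 r = 0.999
classical: run1 vs run2 r = 0.920
```

With both endpoint regions active at 1% signal change, the projected arm
raises the tract's mean group z above the 95th percentile of the remaining
white matter, while the classical smoothed GLM shows no tract effect (its
white-matter tail comes from smoothing bleed near the active grey matter,
not from the tract). The projected group maps are also markedly more
reproducible across the two noise realisations.

The same pipeline is available from the shell:

```sh
fnkit synth --out data/ --seed 42
fnkit build-priors --tractograms data/ --seeds data/gm_mask.nii.gz \
      --grid-from data/gm_mask.nii.gz --out data/priors.h5
fnkit project --bold data/sub-00_run-1_bold.nii.gz --mask data/gm_mask.nii.gz \
      --priors data/priors.h5 --out data/sub-00_fn.nii.gz
fnkit glm --bold4d data/sub-00_fn.nii.gz --events data/events.tsv \
      --mask data/wm_mask.nii.gz --out data/sub-00_zmap.nii.gz
```

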