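import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnkit import (
    FunctionalVolume,
    GridMismatchError,
    Mask,
    Parcellation,
    PriorsStore,
    ProbabilityMap,
    StatMap,
    VoxelGrid,
    mask_to_white_matter,
    project_regionwise,
    project_voxelwise,
)
from tests.conftest import delta_priors, random_sparse_priors, random_volume


def naive_voxelwise_oracle(f, mask_voxels, priors):
    """Quadruple-loop reference implementation of the weighted average."""
    shape = f.grid.shape
    n_t = f.n_frames
    out = np.zeros(shape + (n_t,))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                num = np.zeros(n_t)
                den = 0.0
                for m in mask_voxels:
                    p = priors[m].data[x, y, z]
                    num += p * f.data[m]
                    den += p
                if den > 0:
                    out[x, y, z] = num / den
    return out


def naive_regionwise_oracle(f, parc, priors):
    shape = f.grid.shape
    n_t = f.n_frames
    out = np.zeros(shape + (n_t,))
    labels = parc.region_labels()
    means = {
        lab: f.data[parc.labels == lab].mean(axis=0) for lab in labels
    }
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                num = np.zeros(n_t)
                den = 0.0
                for lab in labels:
                    p = priors[lab].data[x, y, z]
                    num += p * means[lab]
                    den += p
                if den > 0:
                    out[x, y, z] = num / den
    return out


class TestVoxelwiseProjection:
    def test_delta_priors_identity(self, unit_grid, rng):
        f = random_volume(unit_grid, 6, rng)
        mask = Mask.from_array(unit_grid, np.ones(unit_grid.shape))
        result = project_voxelwise(f, mask, delta_priors(unit_grid, mask))
        assert np.array_equal(result.volume.data, f.data)  # bit-for-bit
        assert len(result.uncovered) == 0

    def test_delta_priors_partial_mask(self, unit_grid, rng):
        f = random_volume(unit_grid, 4, rng)
        arr = np.zeros(unit_grid.shape)
        arr[:2] = 1
        mask = Mask.from_array(unit_grid, arr)
        result = project_voxelwise(f, mask, delta_priors(unit_grid, mask))
        assert np.array_equal(result.volume.data[:2], f.data[:2])
        assert np.all(result.volume.data[2:] == 0)
        # uncovered is exactly the mask complement
        assert result.uncovered.to_array() .sum() == 32
        assert not (set(result.uncovered.voxels) & set(mask.voxels))

    def test_equal_weight_mean(self, unit_grid):
        data = np.zeros((4, 4, 4, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[1, 0, 0] = [3, 2, 1]
        f = FunctionalVolume(unit_grid, data)
        mask = Mask(unit_grid, frozenset({(0, 0, 0), (1, 0, 0)}))
        target = (2, 2, 2)
        entries = {}
        for v in mask.sorted_voxels():
            p = np.zeros((4, 4, 4))
            p[target] = 0.5
            entries[v] = ProbabilityMap(unit_grid, p)
        priors = PriorsStore(unit_grid, "voxel", entries)
        result = project_voxelwise(f, mask, priors)
        assert np.allclose(result.volume.data[target], [2, 2, 2])

    def test_matches_naive_loop_oracle(self, unit_grid, rng):
        f = random_volume(unit_grid, 6, rng)
        arr = np.zeros(unit_grid.shape)
        arr.flat[rng.choice(64, 10, replace=False)] = 1
        mask = Mask.from_array(unit_grid, arr)
        priors = random_sparse_priors(unit_grid, mask, rng, density=0.3)
        result = project_voxelwise(f, mask, priors)
        expected = naive_voxelwise_oracle(f, mask.sorted_voxels(), priors)
        assert np.max(np.abs(result.volume.data - expected)) < 1e-10

    def test_chunked_bit_compatible(self, unit_grid, rng):
        f = random_volume(unit_grid, 6, rng)
        mask = Mask.from_array(unit_grid, np.ones(unit_grid.shape))
        priors = random_sparse_priors(unit_grid, mask, rng, density=0.2)
        full = project_voxelwise(f, mask, priors)
        chunked = project_voxelwise(f, mask, priors, chunk_voxels=7)
        assert np.max(np.abs(full.volume.data - chunked.volume.data)) < 1e-12

    def test_convexity_over_random_instances(self, unit_grid):
        # every covered output value lies within [min, max] of the
        # contributing input values (the output stays on the BOLD scale)
        rng = np.random.default_rng(99)
        for _ in range(20):
            f = random_volume(unit_grid, 4, rng, baseline=100.0)
            arr = np.zeros(unit_grid.shape)
            arr.flat[rng.choice(64, 8, replace=False)] = 1
            mask = Mask.from_array(unit_grid, arr)
            priors = random_sparse_priors(unit_grid, mask, rng, density=0.3)
            result = project_voxelwise(f, mask, priors)
            mask_vox = mask.sorted_voxels()
            weights = np.stack([priors[v].data for v in mask_vox], axis=-1)
            series = np.stack([f.data[v] for v in mask_vox])  # (n_mask, T)
            covered = result.coverage.data > 0
            for idx in np.argwhere(covered):
                v = tuple(idx)
                contrib = weights[v] > 0
                lo = series[contrib].min(axis=0) - 1e-12
                hi = series[contrib].max(axis=0) + 1e-12
                assert np.all(result.volume.data[v] >= lo)
                assert np.all(result.volume.data[v] <= hi)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
    )
    def test_linearity_property(self, a, b):
        grid = VoxelGrid((3, 3, 3), np.eye(4))
        rng = np.random.default_rng(1234)
        mask = Mask.from_array(grid, np.ones(grid.shape))
        priors = random_sparse_priors(grid, mask, rng, density=0.3)
        f1 = random_volume(grid, 3, rng)
        f2 = random_volume(grid, 3, rng)
        combo = FunctionalVolume(grid, a * f1.data + b * f2.data)
        lhs = project_voxelwise(combo, mask, priors).volume.data
        rhs = (
            a * project_voxelwise(f1, mask, priors).volume.data
            + b * project_voxelwise(f2, mask, priors).volume.data
        )
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_linearity(self, unit_grid, rng):
        mask = Mask.from_array(unit_grid, np.ones(unit_grid.shape))
        priors = random_sparse_priors(unit_grid, mask, rng, density=0.2)
        f1 = random_volume(unit_grid, 5, rng)
        f2 = random_volume(unit_grid, 5, rng)
        a, b = 2.5, -1.25
        combo = FunctionalVolume(unit_grid, a * f1.data + b * f2.data)
        lhs = project_voxelwise(combo, mask, priors).volume.data
        rhs = (
            a * project_voxelwise(f1, mask, priors).volume.data
            + b * project_voxelwise(f2, mask, priors).volume.data
        )
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_invariant_to_priors_entry_order(self, unit_grid, rng):
        f = random_volume(unit_grid, 4, rng)
        mask = Mask.from_array(unit_grid, np.ones(unit_grid.shape))
        priors = random_sparse_priors(unit_grid, mask, rng, density=0.2)
        reversed_entries = dict(reversed(list(priors.entries.items())))
        shuffled = PriorsStore(unit_grid, "voxel", reversed_entries)
        a = project_voxelwise(f, mask, priors).volume.data
        b = project_voxelwise(f, mask, shuffled).volume.data
        assert np.array_equal(a, b)

    def test_coverage_partitions_grid(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        arr = np.zeros(unit_grid.shape)
        arr[0, 0, 0] = 1
        mask = Mask.from_array(unit_grid, arr)
        priors = random_sparse_priors(unit_grid, mask, rng, density=0.2)
        result = project_voxelwise(f, mask, priors)
        covered = result.coverage.data > 0
        uncovered = result.uncovered.to_array(bool)
        assert np.all(covered ^ uncovered)

    def test_empty_mask_rejected(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        mask = Mask(unit_grid, frozenset())
        with pytest.raises(ValueError, match="empty"):
            project_voxelwise(f, mask, PriorsStore(unit_grid, "voxel", {}))

    def test_missing_priors_entry_listed(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        mask = Mask(unit_grid, frozenset({(0, 0, 0), (1, 1, 1)}))
        partial = delta_priors(unit_grid, Mask(unit_grid, frozenset({(0, 0, 0)})))
        with pytest.raises(KeyError, match=r"\(1, 1, 1\)"):
            project_voxelwise(f, mask, partial)

    def test_grid_mismatch_rejected(self, unit_grid, mm2_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        mask = Mask(mm2_grid, frozenset({(0, 0, 0)}))
        with pytest.raises(GridMismatchError):
            project_voxelwise(f, mask, PriorsStore(mm2_grid, "voxel", {}))

    def test_regionwise_priors_rejected(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        mask = Mask(unit_grid, frozenset({(0, 0, 0)}))
        with pytest.raises(ValueError, match="voxel-wise"):
            project_voxelwise(f, mask, PriorsStore(unit_grid, "region", {}))


class TestRegionwiseProjection:
    def test_singleton_regions_equal_voxelwise(self, unit_grid, rng):
        f = random_volume(unit_grid, 5, rng)
        voxels = [(0, 0, 0), (1, 2, 3), (3, 3, 0)]
        labels = np.zeros(unit_grid.shape, dtype=np.int32)
        vox_entries, reg_entries = {}, {}
        for i, v in enumerate(voxels, start=1):
            labels[v] = i
            p = rng.uniform(0, 1, unit_grid.shape)
            p[rng.uniform(size=unit_grid.shape) > 0.3] = 0
            vox_entries[v] = ProbabilityMap(unit_grid, p)
            reg_entries[i] = ProbabilityMap(unit_grid, p)
        parc = Parcellation(unit_grid, labels)
        mask = Mask(unit_grid, frozenset(voxels))
        out_vox = project_voxelwise(
            f, mask, PriorsStore(unit_grid, "voxel", vox_entries)
        )
        out_reg = project_regionwise(
            f, parc, PriorsStore(unit_grid, "region", reg_entries)
        )
        assert np.allclose(out_vox.volume.data, out_reg.volume.data, atol=1e-12)

    def test_region_mean_series(self, unit_grid):
        data = np.zeros((4, 4, 4, 2))
        data[0, 0, 0] = [0, 2]
        data[0, 0, 1] = [2, 0]
        f = FunctionalVolume(unit_grid, data)
        labels = np.zeros(unit_grid.shape, dtype=np.int32)
        labels[0, 0, 0] = labels[0, 0, 1] = 1
        parc = Parcellation(unit_grid, labels)
        target = (2, 2, 2)
        p = np.zeros(unit_grid.shape)
        p[target] = 1.0
        priors = PriorsStore(unit_grid, "region", {1: ProbabilityMap(unit_grid, p)})
        result = project_regionwise(f, parc, priors)
        assert np.allclose(result.volume.data[target], [1, 1])

    def test_matches_naive_loop_oracle(self, unit_grid, rng):
        f = random_volume(unit_grid, 6, rng)
        labels = np.zeros(unit_grid.shape, dtype=np.int32)
        labels[:2, :2, :2] = 1
        labels[2:, 2:, 2:] = 2
        parc = Parcellation(unit_grid, labels)
        entries = {}
        for lab in (1, 2):
            p = rng.uniform(0, 1, unit_grid.shape)
            p[rng.uniform(size=unit_grid.shape) > 0.4] = 0
            entries[lab] = ProbabilityMap(unit_grid, p)
        priors = PriorsStore(unit_grid, "region", entries)
        result = project_regionwise(f, parc, priors)
        expected = naive_regionwise_oracle(f, parc, priors)
        assert np.max(np.abs(result.volume.data - expected)) < 1e-10

    def test_missing_region_entry(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        labels = np.zeros(unit_grid.shape, dtype=np.int32)
        labels[0, 0, 0] = 5
        parc = Parcellation(unit_grid, labels)
        with pytest.raises(KeyError, match="5"):
            project_regionwise(f, parc, PriorsStore(unit_grid, "region", {}))


class TestWhiteMatterMasking:
    def test_full_mask_is_identity(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        wm = Mask.from_array(unit_grid, np.ones(unit_grid.shape))
        out = mask_to_white_matter(f, wm)
        assert np.array_equal(out.data, f.data)

    def test_empty_mask_zeroes_everything(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng)
        wm = Mask(unit_grid, frozenset())
        assert np.all(mask_to_white_matter(f, wm).data == 0)

    def test_support_inside_mask(self, unit_grid, rng):
        f = random_volume(unit_grid, 3, rng, baseline=5.0)
        arr = np.zeros(unit_grid.shape)
        arr[1:3, 1:3, 1:3] = 1
        wm = Mask.from_array(unit_grid, arr)
        out = mask_to_white_matter(f, wm)
        support = np.any(out.data != 0, axis=-1)
        assert np.all(arr[support] == 1)

    def test_stat_map_masking(self, unit_grid, rng):
        full = Mask.from_array(unit_grid, np.ones(unit_grid.shape))
        sm = StatMap(
            grid=unit_grid,
            beta=rng.normal(size=unit_grid.shape),
            t=rng.normal(size=unit_grid.shape),
            z=rng.normal(size=unit_grid.shape),
            dof=10,
            mask=full,
        )
        arr = np.zeros(unit_grid.shape)
        arr[0] = 1
        wm = Mask.from_array(unit_grid, arr)
        out = mask_to_white_matter(sm, wm)
        assert np.all(out.z[1:] == 0)
        assert np.array_equal(out.z[0], sm.z[0])
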