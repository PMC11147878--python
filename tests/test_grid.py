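"""Volume geometry, I/O round trips, smoothing, clustering, peaks, hemispheres."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from replocal.grid import (
    ClusterLabels,
    GridMismatchError,
    MaskVolume,
    StatMap,
    SubjectBetaSet,
    VolumeGrid,
    average_presentations,
    centered_grid,
    fwhm_to_sigma,
    gaussian_smooth,
    hemisphere_counts,
    label_clusters,
    local_extrema,
    read_beta_set,
    write_beta_set,
    write_stimulus_table,
)


def small_mask(n=5, voxel=3.0):
    grid = centered_grid((n, n, n), voxel)
    return MaskVolume(grid, np.ones(grid.dims, bool))


class TestVolumeGrid:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VolumeGrid((0, 3, 3), np.eye(4))
        with pytest.raises(ValueError):
            VolumeGrid((3, 3, 3), np.zeros((4, 4)))

    def test_voxel_size_and_world_mapping(self):
        grid = centered_grid((5, 5, 5), 3.0)
        assert np.allclose(grid.voxel_size, 3.0)
        assert np.allclose(grid.voxel_to_world([[2, 2, 2]]), 0.0)
        assert grid.voxel_volume_mm3 == pytest.approx(27.0)


class TestBetaIO:
    def _write_bundle(self, tmp_path, n_stim=4, dims=(3, 3, 3), n_mask=10, seed=0):
        rng = np.random.default_rng(seed)
        grid = centered_grid(dims, 3.0)
        flat = np.zeros(int(np.prod(dims)), bool)
        flat[rng.choice(flat.size, n_mask, replace=False)] = True
        mask = MaskVolume(grid, flat.reshape(dims))
        beta = rng.standard_normal((n_stim, n_mask))
        sids = np.array([f"s{i}" for i in range(n_stim)])
        betas = SubjectBetaSet("sub-00", mask, beta, sids)
        table = pd.DataFrame(dict(stimulus_id=sids, word=sids, transcription="K AE T",
                                  word_id=sids))
        from replocal.grid import write_mask
        write_beta_set(betas, tmp_path / "b.nii.gz")
        write_mask(mask, tmp_path / "m.nii.gz")
        write_stimulus_table(table, tmp_path / "t.tsv")
        return betas, table

    def test_shape_contract(self, tmp_path):
        self._write_bundle(tmp_path)
        loaded = read_beta_set(tmp_path / "b.nii.gz", tmp_path / "m.nii.gz",
                               tmp_path / "t.tsv")
        assert loaded.beta.shape == (4, 10)

    def test_frame_count_mismatch_is_explicit(self, tmp_path):
        self._write_bundle(tmp_path)
        table = pd.read_csv(tmp_path / "t.tsv", sep="\t")
        extra = pd.concat([table, table.iloc[[0]].assign(stimulus_id="s99")])
        write_stimulus_table(extra, tmp_path / "t5.tsv")
        with pytest.raises(ValueError, match="4 frames.*5 rows"):
            read_beta_set(tmp_path / "b.nii.gz", tmp_path / "m.nii.gz",
                          tmp_path / "t5.tsv")

    def test_round_trip_preserves_values(self, tmp_path):
        betas, _ = self._write_bundle(tmp_path, seed=3)
        loaded = read_beta_set(tmp_path / "b.nii.gz", tmp_path / "m.nii.gz",
                               tmp_path / "t.tsv")
        # volumes are stored as float32
        assert np.allclose(loaded.beta, betas.beta, atol=1e-6)


class TestAveragePresentations:
    def test_identical_rows_are_preserved(self):
        mask = small_mask(3)
        row = np.arange(27.0)
        betas = SubjectBetaSet("s", mask, np.tile(row, (3, 1)),
                               ["a_1", "a_2", "a_3"])
        out = average_presentations(betas, {"a_1": "a", "a_2": "a", "a_3": "a"})
        assert out.n_stimuli == 1
        assert np.allclose(out.beta[0], row)

    def test_matches_groupby_mean_oracle(self, rng):
        mask = small_mask(3)
        beta = rng.standard_normal((6, 27))
        sids = [f"w{i % 2}_p{i // 2}" for i in range(6)]
        rep = {s: s.split("_")[0] for s in sids}
        out = average_presentations(SubjectBetaSet("s", mask, beta, sids), rep)
        oracle = pd.DataFrame(beta).groupby([rep[s] for s in sids]).mean()
        assert list(out.stimulus_ids) == ["w0", "w1"]
        assert np.allclose(out.beta, oracle.loc[["w0", "w1"]].to_numpy())

    def test_missing_mapping_raises(self):
        mask = small_mask(3)
        betas = SubjectBetaSet("s", mask, np.random.default_rng(0).normal(size=(2, 27)),
                               ["a", "b"])
        with pytest.raises(KeyError, match="'b'"):
            average_presentations(betas, {"a": "a"})


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        mask = small_mask(5)
        m = StatMap(mask, rng.standard_normal(mask.n_voxels))
        assert np.array_equal(gaussian_smooth(m, 0.0).values, m.values)

    def test_negative_fwhm_rejected(self):
        mask = small_mask(3)
        with pytest.raises(ValueError):
            gaussian_smooth(StatMap(mask, np.zeros(27)), -1.0)

    def test_constant_map_preserved_exactly(self):
        grid = centered_grid((7, 7, 7), 3.0)
        blob = np.zeros(grid.dims, bool)
        blob[1:6, 1:6, 2:5] = True
        mask = MaskVolume(grid, blob)
        m = StatMap(mask, np.full(mask.n_voxels, 3.25))
        out = gaussian_smooth(m, 5.0)
        assert np.allclose(out.values, 3.25, atol=1e-12)

    def test_impulse_matches_dense_convolution_oracle(self):
        mask = small_mask(9)
        vals = np.zeros(mask.n_voxels)
        center = mask.n_voxels // 2
        vals[center] = 1.0
        fwhm = 6.0
        out = gaussian_smooth(StatMap(mask, vals), fwhm, mask_normalize=False)
        sigma = fwhm_to_sigma(fwhm) / 3.0
        radius = int(4.0 * sigma + 0.5)
        ax = np.arange(-radius, radius + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        oracle = ndimage.convolve(mask.embed(vals), kernel, mode="constant")
        assert np.allclose(out.to_volume(), oracle, atol=1e-10)

    def test_interior_mean_approximately_preserved(self, rng):
        mask = small_mask(11)
        m = StatMap(mask, rng.standard_normal(mask.n_voxels))
        out = gaussian_smooth(m, 5.0)
        assert abs(out.values.mean() - m.values.mean()) < 1e-6


def _flood_fill_labels(binary, offsets):
    """Independent BFS connected-components oracle."""
    from collections import deque

    labels = np.zeros(binary.shape, int)
    nxt = 0
    dims = binary.shape
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            p = q.popleft()
            for off in offsets:
                nb = tuple(np.add(p, off))
                if all(0 <= nb[i] < dims[i] for i in range(3)):
                    if binary[nb] and not labels[nb]:
                        labels[nb] = nxt
                        q.append(nb)
    return labels


class TestClusterLabeling:
    def test_face_and_corner_connectivity(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[0, 0, 0] = vol[0, 0, 1] = True  # share a face
        assert label_clusters(vol, connectivity=6).n_clusters == 1
        vol = np.zeros((4, 4, 4), bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True  # share only a corner
        assert label_clusters(vol, connectivity=6).n_clusters == 2
        assert label_clusters(vol, connectivity=26).n_clusters == 1

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_clusters(np.ones((2, 2, 2), bool), connectivity=10)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        vol = rng.random((10, 10, 10)) < 0.25
        got = label_clusters(vol, connectivity=connectivity)
        r = {6: 1, 18: 2, 26: 3}[connectivity]
        offs = [
            (i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
            and {6: abs(i) + abs(j) + abs(k) <= 1,
                 18: abs(i) + abs(j) + abs(k) <= 2,
                 26: True}[connectivity]
        ]
        oracle = _flood_fill_labels(vol, offs)
        # identical partitions up to label permutation
        pair = {}
        for a, b in zip(got.labels.ravel(), oracle.ravel()):
            if a:
                assert pair.setdefault(a, b) == b
        assert got.n_clusters == oracle.max()
        assert got.sizes_vox.sum() == vol.sum()

    def test_sizes_in_mm3(self):
        grid = centered_grid((4, 4, 4), 3.0)
        vol = np.zeros(grid.dims, bool)
        vol[0, 0, :3] = True
        c = label_clusters(vol, grid=grid)
        assert c.sizes_mm3[0] == pytest.approx(3 * 27.0)


def _greedy_peaks_oracle(values, coords, min_sep):
    order = sorted(range(len(values)), key=lambda i: (-abs(values[i]), i))
    acc = []
    for i in order:
        if all(np.linalg.norm(coords[i] - coords[j]) >= min_sep for j in acc):
            acc.append(i)
    return sorted(acc)


class TestLocalExtrema:
    def test_single_voxel_cluster(self):
        mask = small_mask(5)
        vals = np.zeros(mask.n_voxels)
        vals[17] = 2.0
        clusters = label_clusters(mask.embed(vals) > 1, mask.grid)
        peaks = local_extrema(StatMap(mask, vals), clusters, 11.0)
        assert len(peaks) == 1
        assert peaks.iloc[0]["value"] == 2.0

    def test_close_secondary_maximum_suppressed(self):
        grid = centered_grid((7, 1, 1), 3.0)  # voxels 3 mm apart along x
        mask = MaskVolume(grid, np.ones(grid.dims, bool))
        vals = np.array([0, 1.0, 0.4, 0.5, 0, 0, 0])  # one cluster, peaks 6 mm apart
        clusters = label_clusters(mask.embed(vals) > 0.1, mask.grid)
        peaks = local_extrema(StatMap(mask, vals), clusters, 11.0)
        assert len(peaks) == 1 and peaks.iloc[0]["value"] == 1.0

    def test_matches_exhaustive_greedy_oracle(self, rng):
        mask = small_mask(6)
        vals = rng.standard_normal(mask.n_voxels)
        clusters = label_clusters(mask.data, mask.grid)  # one big cluster
        peaks = local_extrema(StatMap(mask, vals), clusters, 11.0)
        oracle = _greedy_peaks_oracle(vals, mask.world_coords(), 11.0)
        assert sorted(peaks["value"]) == pytest.approx(sorted(vals[oracle]))
        assert len(peaks) == len(oracle)


class TestHemispheres:
    def test_symmetric_mask_balances(self):
        mask = small_mask(5)  # centered grid, symmetric about x=0
        left, right, mid = hemisphere_counts(mask)
        assert left == right == 50 and mid == 25

    def test_all_right(self):
        grid = VolumeGrid((3, 3, 3), np.diag([3.0, 3.0, 3.0, 1.0]) + 0)
        aff = grid.affine.copy()
        aff[0, 3] = 3.0  # all x > 0
        mask = MaskVolume(VolumeGrid((3, 3, 3), aff), np.ones((3, 3, 3), bool))
        assert hemisphere_counts(mask) == (0, 27, 0)

    def test_reflection_swaps_counts(self, rng):
        grid = centered_grid((6, 5, 5), 3.0)
        data = rng.random(grid.dims) < 0.5
        data.flat[0] = True
        mask = MaskVolume(grid, data)
        refl_aff = np.diag([-1.0, 1, 1, 1]) @ grid.affine
        refl = MaskVolume(VolumeGrid(grid.dims, refl_aff), data)
        l1, r1, m1 = hemisphere_counts(mask)
        l2, r2, m2 = hemisphere_counts(refl)
        assert (l1, r1, m1) == (r2, l2, m2)

    def test_counts_match_per_voxel_oracle(self, rng):
        grid = centered_grid((6, 4, 4), 2.0)
        data = rng.random(grid.dims) < 0.6
        data.flat[0] = True
        mask = MaskVolume(grid, data)
        left = right = mid = 0
        for ijk in mask.ijk:
            x = (grid.affine @ np.r_[ijk, 1.0])[0]
            if abs(x) <= 1e-6:
                mid += 1
            elif x < 0:
                left += 1
            else:
                right += 1
        assert hemisphere_counts(mask) == (left, right, mid)
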