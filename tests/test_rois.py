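"""Cluster extraction, hMT+/MST/V5-MT assignment, Fourier retinotopy."""

import numpy as np
import pytest

from corticomap import errors
from corticomap.core import TimeSeriesVolume, VertexMask, Volume, VoxelMask
from corticomap.rois import (
    ClusterConfig,
    define_hmt,
    define_mst,
    define_v5mt,
    extract_clusters,
    fourier_retinotopy,
    group_mask,
    project_voxel_mask,
)


def _zvol(data):
    data = np.asarray(data, float)
    return Volume(data, (1, 1, 1), np.eye(4))


def _flood_fill_oracle(binary, connectivity):
    """Brute-force connected components by BFS over explicit offsets."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    shape = binary.shape
    for idx in np.argwhere(binary):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack = [idx]
        seen[idx] = True
        comp = []
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, shape)):
                    continue
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(frozenset(np.ravel_multi_index(tuple(zip(*comp)), shape)))
    return set(comps)


class TestExtractClusters:
    def test_single_blob_survives(self):
        data = np.zeros((8, 8, 8))
        data[2:4, 2:4, 2:4] = 5.0  # 8 voxels... make it 10
        data[4, 2, 2] = 5.0
        data[4, 3, 2] = 5.0
        cfg = ClusterConfig(min_extent=5, connectivity=6)
        clusters = extract_clusters(_zvol(data), cfg)
        assert len(clusters) == 1
        assert len(clusters[0]) == 10

    def test_small_blob_filtered(self):
        data = np.zeros((8, 8, 8))
        data[1, 1, 1:4] = 5.0
        cfg = ClusterConfig(min_extent=5, connectivity=6)
        assert extract_clusters(_zvol(data), cfg) == []

    def test_corner_touching_connectivity(self):
        data = np.zeros((6, 6, 6))
        data[1:3, 1:3, 1] = 5.0
        data[3:5, 3:5, 2] = 5.0  # touches the first blob only at a corner
        lo = ClusterConfig(min_extent=0, connectivity=6)
        hi = ClusterConfig(min_extent=0, connectivity=26)
        assert len(extract_clusters(_zvol(data), lo)) == 2
        assert len(extract_clusters(_zvol(data), hi)) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        cfg = ClusterConfig(min_extent=0, connectivity=connectivity)
        for _ in range(30):
            data = (rng.random((16, 16, 16)) < 0.25) * 5.0
            clusters = extract_clusters(_zvol(data), cfg)
            got = {frozenset(c.indices.tolist()) for c in clusters}
            expected = _flood_fill_oracle(data > 2.3, connectivity)
            assert got == expected

    def test_permutation_extent_filters_noise(self, rng):
        # pure N(0,1) noise: with the permutation criterion, surviving
        # clusters are rare by construction (alpha = 0.05)
        survivors = 0
        for seed in range(10):
            data = np.random.default_rng(seed).standard_normal((14, 14, 14))
            cfg = ClusterConfig(min_extent="permutation", n_perm=200,
                                seed=seed)
            survivors += len(extract_clusters(_zvol(data), cfg)) > 0
        assert survivors <= 3


class TestDefineHmt:
    def test_proximity_beats_size(self):
        data = np.zeros((20, 8, 8))
        data[1:5, 1:5, 1:5] = 4.0     # large cluster near origin
        data[15:17, 1:3, 1:3] = 5.0   # small cluster far away
        cfg = ClusterConfig(min_extent=0, connectivity=6)
        hmt = define_hmt(_zvol(data), cfg, anchor=(16.0, 2.0, 2.0))
        assert len(hmt) == 8  # the small cluster wins on proximity

    def test_no_cluster_raises(self):
        cfg = ClusterConfig(min_extent=0)
        with pytest.raises(errors.NoClusterError):
            define_hmt(_zvol(np.zeros((5, 5, 5))), cfg, anchor=(0, 0, 0))


class TestDefineMst:
    def _masks(self, shape=(40, 1, 1)):
        return shape

    def test_intersecting_cluster_included_in_full(self):
        shape = (40, 1, 1)
        hmt = VoxelMask(np.arange(1, 21), "v", shape)
        ipsi = np.zeros(shape)
        ipsi[15:26, 0, 0] = 5.0
        cfg = ClusterConfig(min_extent=0, connectivity=6)
        mst = define_mst(hmt, Volume(ipsi, (1, 1, 1), np.eye(4),
                                     space_tag="v"), cfg)
        assert mst.as_set() == set(range(15, 26))

    def test_disjoint_cluster_excluded(self):
        shape = (40, 1, 1)
        hmt = VoxelMask(np.arange(1, 10), "v", shape)
        ipsi = np.zeros(shape)
        ipsi[20:25, 0, 0] = 5.0
        cfg = ClusterConfig(min_extent=0, connectivity=6)
        mst = define_mst(hmt, Volume(ipsi, (1, 1, 1), np.eye(4),
                                     space_tag="v"), cfg)
        assert len(mst) == 0

    def test_only_intersecting_of_two_clusters(self):
        shape = (40, 1, 1)
        hmt = VoxelMask(np.arange(1, 10), "v", shape)
        ipsi = np.zeros(shape)
        ipsi[5:12, 0, 0] = 5.0   # intersects
        ipsi[25:30, 0, 0] = 5.0  # does not
        cfg = ClusterConfig(min_extent=0, connectivity=6)
        mst = define_mst(hmt, Volume(ipsi, (1, 1, 1), np.eye(4),
                                     space_tag="v"), cfg)
        assert mst.as_set() == set(range(5, 12))


def _pure_tone_ts(phases, n=64, dt=1.0, period=16.0, amp=1.0, noise=0.0,
                  rng=None):
    """1-voxel-per-phase time-series volume."""
    phases = np.atleast_1d(phases)
    t = np.arange(n) * dt
    data = amp * np.cos(2 * np.pi * t[None, :] / period - phases[:, None])
    if noise > 0:
        data = data + rng.normal(0, noise, data.shape)
    return TimeSeriesVolume(data[:, None, None, :], (1, 1, 1), np.eye(4),
                            frame_interval=dt, space_tag="v")


class TestFourierRetinotopy:
    def test_noiseless_phase_and_coherence(self):
        ts = _pure_tone_ts([1.0])
        res = fourier_retinotopy(ts, 16.0)
        assert res.phase[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert res.coherence[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_quarter_period_phase_shift(self):
        res = fourier_retinotopy(_pure_tone_ts([np.pi / 2]), 16.0)
        assert res.phase[0, 0, 0] == pytest.approx(np.pi / 2, abs=1e-6)

    def test_off_bin_period_rejected(self):
        with pytest.raises(errors.FrequencyBinError):
            fourier_retinotopy(_pure_tone_ts([0.0], n=64), 15.0)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(errors.ConfigError):
            fourier_retinotopy(_pure_tone_ts([0.0], n=16, period=16.0), 16.0)

    def test_noise_null_matches_monte_carlo(self, rng):
        # fraction of pure-noise voxels passing coherence > 0.25 vs. a
        # direct Monte-Carlo estimate of the same null
        n_frames, n_vox = 64, 10_000
        data = rng.standard_normal((n_vox, 1, 1, n_frames))
        ts = TimeSeriesVolume(data, (1, 1, 1), np.eye(4))
        res = fourier_retinotopy(ts, 16.0)
        frac = (res.coherence > 0.25).mean()
        mc = rng.standard_normal((1000, n_frames))
        spec = np.abs(np.fft.rfft(mc, axis=1))
        # same coherence definition: stimulus bin over non-DC, non-drift bins
        coh = spec[:, 4] / np.sqrt((spec[:, 3:] ** 2).sum(axis=1))
        mc_frac = (coh > 0.25).mean()
        assert abs(frac - mc_frac) < 0.02

    def test_repeat_averaging_improves_coherence(self, rng):
        phases = rng.uniform(0, 2 * np.pi, 100)
        runs = [_pure_tone_ts(phases, amp=1.0, noise=1.0, rng=rng)
                for _ in range(2)]
        single = fourier_retinotopy(runs[0], 16.0)
        combined = fourier_retinotopy(runs[0], 16.0, repeats=[runs[1]])
        better = (combined.coherence >= single.coherence).mean()
        assert better >= 0.95

    def test_phase_recovery_at_snr_two(self, rng):
        phases = rng.uniform(0, 2 * np.pi, 100)
        ts = _pure_tone_ts(phases, n=128, amp=1.0, noise=0.5, rng=rng)
        res = fourier_retinotopy(ts, 16.0)
        err = np.angle(np.exp(1j * (res.phase[:, 0, 0] - phases)))
        assert np.abs(err).mean() < 0.1


class TestDefineV5mt:
    def _retino(self, coh_indices, shape=(40, 1, 1)):
        coh = np.zeros(shape)
        coh.flat[list(coh_indices)] = 0.9
        from corticomap.rois import RetinotopyResult

        return RetinotopyResult(phase=np.zeros(shape), amplitude=coh.copy(),
                                coherence=coh, stimulus_bin=4,
                                parent_ref="v", grid_shape=shape)

    def test_retinotopic_minus_mst(self):
        shape = (40, 1, 1)
        hmt = VoxelMask(np.arange(5, 31), "v", shape)
        retino = self._retino(range(10, 31), shape)
        mst = VoxelMask(np.arange(25, 36), "v", shape)
        v5 = define_v5mt(retino, 0.25, hmt, mst)
        assert v5.as_set() == set(range(10, 25))

    def test_no_coherent_voxels_empty(self):
        shape = (40, 1, 1)
        hmt = VoxelMask(np.arange(5, 31), "v", shape)
        retino = self._retino([], shape)
        mst = VoxelMask([], "v", shape)
        assert len(define_v5mt(retino, 0.25, hmt, mst)) == 0

    def test_empty_mst_keeps_all_retinotopic(self):
        shape = (40, 1, 1)
        hmt = VoxelMask(np.arange(5, 31), "v", shape)
        retino = self._retino(range(10, 20), shape)
        mst = VoxelMask([], "v", shape)
        v5 = define_v5mt(retino, 0.25, hmt, mst)
        assert v5.as_set() == set(range(10, 20))

    def test_v5_and_mst_disjoint_by_construction(self, rng):
        shape = (60, 1, 1)
        for _ in range(20):
            hmt = VoxelMask(rng.choice(60, 30, replace=False), "v", shape)
            retino = self._retino(rng.choice(60, 25, replace=False), shape)
            mst = VoxelMask(rng.choice(60, 15, replace=False), "v", shape)
            v5 = define_v5mt(retino, 0.25, hmt, mst)
            assert v5.as_set().isdisjoint(mst.as_set())
            assert v5.as_set() <= hmt.as_set()


class TestGroupMask:
    def _masks(self, membership, n=20):
        return [VertexMask(m, "s", n) for m in membership]

    def test_half_boundary_included(self):
        masks = self._masks([[3]] * 4 + [[7]] * 4)
        gm = group_mask(masks, 0.5)
        assert 3 in gm and 7 in gm

    def test_three_of_eight_excluded(self):
        masks = self._masks([[3]] * 3 + [[7]] * 5)
        gm = group_mask(masks, 0.5)
        assert 3 not in gm and 7 in gm

    def test_full_fraction_is_intersection(self):
        masks = self._masks([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert group_mask(masks, 1.0).as_set() == {3}

    def test_monotone_in_fraction(self, rng):
        masks = self._masks([rng.choice(20, 8, replace=False)
                             for _ in range(6)])
        prev = None
        for frac in (0.2, 0.4, 0.6, 0.8, 1.0):
            cur = group_mask(masks, frac).as_set()
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestProjectVoxelMask:
    def test_mid_depth_projection(self):
        # volume with a marked column; strip surface sampling at mid-depth
        data = np.zeros((12, 4, 6))
        vol = Volume(data, (1, 1, 1), np.eye(4), space_tag="v")
        dense = np.zeros((12, 4, 6), bool)
        dense[3, :, :] = True
        mask = VoxelMask.from_dense(dense, "v")
        from test_myelin import _flat_strip

        surf = _flat_strip(n=8, thickness=2.0)
        vm = project_voxel_mask(mask, vol, surf, 0.5)
        got = surf.vertices_white[vm.indices][:, 0]
        assert np.all(got == 3.0)  # exactly the x = 3 column of vertices
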