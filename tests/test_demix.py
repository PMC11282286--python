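"""Video-level demixing: reshape, binning, demix_video, rank_scan."""

import numpy as np
import pytest

from fiberdemix.camera import SCMOS, SourceSet, VideoStack, render_video
from fiberdemix.demix import (
    NMFConfig,
    bin_pixels,
    demix_video,
    rank_scan,
    reshape_video,
    unreshape_matrix,
)
from fiberdemix.evaluate import evaluate_demix

from conftest import make_sources


class TestReshape:
    def test_column_is_flattened_frame(self):
        frames = np.array([[[1, 2], [3, 4]], [[5, 6], [7, 8]]], dtype=np.uint16)
        M = reshape_video(VideoStack(frames=frames, bit_depth=16))
        np.testing.assert_array_equal(M[:, 0], [1, 2, 3, 4])
        np.testing.assert_array_equal(M[:, 1], [5, 6, 7, 8])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 1000, (7, 5, 6)).astype(np.uint16)
        M = reshape_video(VideoStack(frames=frames, bit_depth=16))
        assert np.array_equal(unreshape_matrix(M, (5, 6)), frames)

    def test_single_frame_video(self):
        M = reshape_video(VideoStack(frames=np.ones((1, 3, 3))))
        assert M.shape == (9, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reshape_video(VideoStack(frames=np.empty((0, 4, 4))))


class TestBinning:
    def test_mean_of_constant_blocks(self):
        v = VideoStack(frames=np.ones((3, 4, 4)))
        out = bin_pixels(v, 2)
        assert out.frames.shape == (3, 2, 2)
        np.testing.assert_allclose(out.frames, 1.0)

    def test_block_mean_value(self):
        frames = np.zeros((1, 4, 4))
        frames[0, :2, :2] = [[1, 2], [3, 4]]
        out = bin_pixels(VideoStack(frames=frames), 2)
        assert out.frames[0, 0, 0] == pytest.approx(2.5)

    def test_factor_one_identity(self):
        v = VideoStack(frames=np.ones((2, 4, 4)))
        assert bin_pixels(v, 1) is v

    def test_non_divisible_crops_with_warning(self):
        v = VideoStack(frames=np.ones((2, 5, 5)))
        with pytest.warns(UserWarning, match="crop"):
            out = bin_pixels(v, 2)
        assert out.frames.shape == (2, 2, 2)

    def test_invalid_factor(self):
        v = VideoStack(frames=np.ones((2, 4, 4)))
        with pytest.raises(ValueError):
            bin_pixels(v, 0)


class TestDemixVideo:
    def test_rank_one_noiseless_exact_recovery(self):
        sources = make_sources(1, n_frames=120)
        video = render_video(sources, camera=None)
        res = demix_video(video, NMFConfig(rank=1))
        r = np.corrcoef(res.temporal_components[0], sources.traces[0])[0, 1]
        assert r > 0.999

    def test_three_sources_recovered(self, three_source_scene, three_source_video):
        res = demix_video(three_source_video, NMFConfig(rank=3))
        report = evaluate_demix(three_source_scene, res)
        assert (report.diagonal.per_source_diagonals > 0.95).all()

    def test_normalization_preserves_reconstruction(self, three_source_video):
        res = demix_video(three_source_video, NMFConfig(rank=3, max_iter=200))
        W = res.spatial_components.reshape(res.rank, -1)
        assert W.max(axis=1) == pytest.approx(np.ones(res.rank))
        # reconstruction equals an un-normalized reference fit
        from fiberdemix.demix import nmf_fit

        raw = nmf_fit(reshape_video(three_source_video), NMFConfig(rank=3, max_iter=200))
        ref = raw.spatial_components.reshape(3, -1).T @ raw.temporal_components
        recon = W.T @ res.temporal_components
        np.testing.assert_allclose(recon, ref, rtol=1e-10, atol=1e-8)

    def test_binned_run_matches_unbinned_traces(self, three_source_scene, three_source_video):
        # spatially binning the video leaves the retrieved traces intact
        res1 = demix_video(three_source_video, NMFConfig(rank=3))
        res2 = demix_video(three_source_video, NMFConfig(rank=3), bin_factor=2)
        r1 = evaluate_demix(three_source_scene, res1)
        r2 = evaluate_demix(three_source_scene, res2)
        for i in range(3):
            a = res1.temporal_components[r1.assignment[i]]
            b = res2.temporal_components[r2.assignment[i]]
            assert np.corrcoef(a, b)[0, 1] > 0.95


class TestRankScan:
    def test_recovers_true_count_three_sources(self, three_source_video):
        _, estimate = rank_scan(three_source_video, range(1, 7))
        assert estimate == 3

    def test_excess_rank_produces_replicas(self, three_source_video):
        results, _ = rank_scan(three_source_video, [5])
        W = results[5].spatial_components.reshape(5, -1)
        corr = np.corrcoef(W)
        off = corr[~np.eye(5, dtype=bool)]
        assert off.max() > 0.9

    def test_single_source_estimate(self):
        sources = make_sources(1, n_frames=150)
        video = render_video(sources, SCMOS, noise_seed=0)
        _, estimate = rank_scan(video, range(1, 4))
        assert estimate == 1

    def test_empty_range_rejected(self, three_source_video):
        with pytest.raises(ValueError):
            rank_scan(three_source_video, [])
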