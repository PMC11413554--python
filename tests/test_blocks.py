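"""Block layout calculus and block-iterative deconvolution."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rldeconv import (
    DeconvConfig,
    block_rl_deconvolve,
    compute_block_layout,
    crop_merge,
    make_gaussian_psf,
    rl_deconvolve,
    split_extract,
)


def _coverage(layout):
    """How many times each voxel is written by the core regions."""
    counts = np.zeros(layout.volume_shape, np.int32)
    for block in layout.blocks:
        counts[block.core] += 1
    return counts


class TestLayout:
    def test_unlimited_budget_single_unpadded_block(self):
        layout = compute_block_layout((20, 30, 40), (5, 5, 5), 1.2, None)
        assert len(layout) == 1
        block = layout.blocks[0]
        assert block.core == block.padded
        assert block.pads == ((0, 0), (0, 0), (0, 0))
        assert block.padded_shape == (20, 30, 40)

    def test_pad_width_is_padding_fract_times_psf_size(self):
        layout = compute_block_layout((64, 64, 64), (10, 10, 10), 1.2, None)
        assert layout.pad_width == (12, 12, 12)

    def test_remainder_spread_over_earliest_blocks(self):
        # 100-wide axis split in 3: cores {34, 33, 33}, contiguous and disjoint
        layout = compute_block_layout((100, 4, 4), (7, 1, 1), 1.2, 900)
        assert layout.counts == (3, 1, 1)
        z_cores = [(b.core[0].start, b.core[0].stop) for b in layout.blocks]
        assert z_cores == [(0, 34), (34, 67), (67, 100)]

    @pytest.mark.parametrize(
        "shape,budget",
        [((12, 10, 8), None), ((12, 10, 8), 700), ((13, 11, 7), 600),
         ((17, 17, 17), 2000), ((23, 5, 5), 400)],  # prime-sized axes included
    )
    def test_cores_tile_volume_exactly(self, shape, budget):
        layout = compute_block_layout(shape, (3, 3, 3), 1.2, budget)
        assert np.all(_coverage(layout) == 1)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        shape=st.tuples(*[st.integers(4, 24)] * 3),
        psf=st.integers(1, 3),
        budget=st.integers(200, 5000),
    )
    def test_partition_property(self, shape, psf, budget):
        try:
            layout = compute_block_layout(shape, (psf,) * 3, 1.2, budget)
        except ValueError:
            return  # budget too small for this shape: rejection is allowed
        counts = _coverage(layout)
        assert np.all(counts == 1)
        for block in layout.blocks:
            for c, p, size in zip(block.core, block.padded, shape):
                assert p.start <= c.start and c.stop <= p.stop
                assert 0 <= p.start and p.stop <= size

    def test_face_blocks_not_padded_outward(self):
        layout = compute_block_layout((40, 40, 40), (5, 5, 5), 1.2, 12000)
        assert layout.counts[0] >= 2
        first, last = layout.blocks[0], layout.blocks[-1]
        assert first.padded[0].start == first.core[0].start == 0
        assert last.padded[0].stop == last.core[0].stop == 40

    def test_block_count_monotone_in_budget(self):
        budgets = [50000, 20000, 8000, 4000, 2500]
        sizes = [len(compute_block_layout((32, 32, 32), (5, 5, 5), 1.2, b))
                 for b in budgets]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] > sizes[0]

    def test_budget_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            compute_block_layout((32, 32, 32), (9, 9, 9), 1.2, 100)

    def test_psf_larger_than_volume_rejected(self):
        with pytest.raises(ValueError, match="exceeds volume shape"):
            compute_block_layout((8, 8, 8), (9, 3, 3), 1.2, None)


class TestSplitMerge:
    def test_single_block_extract_is_whole_volume(self, rng):
        vol = rng.uniform(size=(10, 11, 12)).astype(np.float32)
        layout = compute_block_layout(vol.shape, (3, 3, 3), 1.2, None)
        np.testing.assert_array_equal(split_extract(vol, layout, 0), vol)

    def test_interior_block_shape_is_core_plus_pads(self):
        layout = compute_block_layout((60, 8, 8), (5, 3, 3), 1.0, 2000)
        assert layout.counts[0] >= 3
        interior = layout.blocks[1]
        (lo, hi), _, _ = interior.pads
        core_z = interior.core[0].stop - interior.core[0].start
        assert interior.padded_shape[0] == core_z + lo + hi
        assert lo == hi == layout.pad_width[0]

    def test_out_of_range_block_id(self, rng):
        vol = rng.uniform(size=(8, 8, 8)).astype(np.float32)
        layout = compute_block_layout(vol.shape, (3, 3, 3), 1.2, None)
        with pytest.raises(IndexError):
            split_extract(vol, layout, 1)

    @pytest.mark.parametrize("budget", [None, 600, 400, 250])
    def test_identity_transform_round_trip(self, rng, budget):
        # splitting then merging with no per-block processing is lossless,
        # for layouts ranging from one to eight blocks
        vol = rng.uniform(size=(12, 10, 8)).astype(np.float32)
        layout = compute_block_layout(vol.shape, (3, 3, 3), 0.4, budget)
        pieces = [split_extract(vol, layout, i) for i in range(len(layout))]
        np.testing.assert_array_equal(crop_merge(pieces, layout), vol)

    def test_round_trip_layouts_cover_multiple_block_counts(self, rng):
        vol = rng.uniform(size=(12, 10, 8)).astype(np.float32)
        sizes = set()
        for budget in [None, 600, 400, 250]:
            layout = compute_block_layout(vol.shape, (3, 3, 3), 0.4, budget)
            sizes.add(len(layout))
        assert len(sizes) >= 3

    def test_constant_volume_stays_constant(self):
        vol = np.full((9, 9, 9), 3.5, np.float32)
        layout = compute_block_layout(vol.shape, (3, 3, 3), 0.4, 500)
        pieces = [split_extract(vol, layout, i) for i in range(len(layout))]
        np.testing.assert_array_equal(crop_merge(pieces, layout), vol)

    def test_shape_mismatch_rejected(self, rng):
        vol = rng.uniform(size=(8, 8, 8)).astype(np.float32)
        layout = compute_block_layout(vol.shape, (3, 3, 3), 1.2, None)
        with pytest.raises(ValueError, match="does not match padded region"):
            crop_merge([vol[:4]], layout)
        with pytest.raises(ValueError, match="block results"):
            crop_merge([], layout)


class TestBlockDeconvolve:
    def test_single_block_bit_identical_to_nonblock(self, rng, gaussian_psf_7):
        mi = rng.uniform(0.1, 1.0, (24, 24, 24)).astype(np.float32)
        cfg = DeconvConfig(iterations=5)
        np.testing.assert_array_equal(
            block_rl_deconvolve(mi, gaussian_psf_7, cfg),
            rl_deconvolve(mi, gaussian_psf_7, cfg),
        )

    def test_zero_iterations_identity_for_multiblock_layout(self, rng):
        mi = rng.uniform(size=(20, 20, 20)).astype(np.float32)
        psf = make_gaussian_psf((3, 3, 3), (1.0, 1.0, 1.0))
        cfg = DeconvConfig(iterations=0, max_block_voxels=2000)
        np.testing.assert_array_equal(block_rl_deconvolve(mi, psf, cfg), mi)

    def test_callback_once_per_block(self, rng):
        mi = rng.uniform(0.1, 1.0, (20, 20, 20)).astype(np.float32)
        psf = make_gaussian_psf((3, 3, 3), (1.0, 1.0, 1.0))
        calls = []
        cfg = DeconvConfig(iterations=2, max_block_voxels=2000,
                           callback=lambda i, n: calls.append((i, n)))
        block_rl_deconvolve(mi, psf, cfg)
        n = calls[0][1]
        assert n > 1
        assert calls == [(i + 1, n) for i in range(n)]

    def test_progress_logged_once_per_block(self, rng, caplog):
        mi = rng.uniform(0.1, 1.0, (20, 20, 20)).astype(np.float32)
        psf = make_gaussian_psf((3, 3, 3), (1.0, 1.0, 1.0))
        cfg = DeconvConfig(iterations=1, max_block_voxels=2000)
        with caplog.at_level(logging.INFO, logger="rldeconv.blocks"):
            block_rl_deconvolve(mi, psf, cfg)
        lines = [r for r in caplog.records if r.name == "rldeconv.blocks"]
        layout = compute_block_layout(mi.shape, psf.shape, 1.2, 2000)
        assert len(lines) == len(layout)
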