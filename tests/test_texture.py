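"""GLCM construction against brute-force enumeration; the nine texture statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasetex import (FEATURE_NAMES, compute_glcm, feature_matrix,
                      haralick_features, sample_rois, standard_offsets)
from phasetex.errors import DomainError, PlacementError
from phasetex.texture import ROI, quantize_levels


def brute_force_glcm(q: np.ndarray, levels: int, offsets, symmetric: bool) -> np.ndarray:
    """Independent oracle: explicit loop over every pixel pair."""
    counts = np.zeros((levels, levels))
    H, W = q.shape
    for dr, dc in offsets:
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W:
                    counts[q[r, c], q[r2, c2]] += 1
                    if symmetric:
                        counts[q[r2, c2], q[r, c]] += 1
    total = counts.sum()
    return counts / total if total else counts


class TestGLCM:
    @pytest.mark.parametrize("offsets", [[(0, 1)], [(1, 0)], [(-1, 1)],
                                         standard_offsets(1)])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_all_3x3_binary_images_match_bruteforce(self, offsets, symmetric):
        for bits in itertools.product([0, 1], repeat=9):
            q = np.array(bits).reshape(3, 3)
            got = compute_glcm(q, levels=2, offsets=offsets, symmetric=symmetric,
                               prequantized=True)
            expect = brute_force_glcm(q, 2, offsets, symmetric)
            assert np.array_equal(got.matrix, expect)

    def test_vertical_pair_matrix_of_striped_image(self):
        """[[0,1],[0,1]] with the same-column offset pairs equal levels only."""
        glcm = compute_glcm(np.array([[0, 1], [0, 1]]), levels=2, offsets=[(1, 0)],
                            symmetric=True, prequantized=True)
        assert np.array_equal(glcm.matrix, np.array([[0.5, 0.0], [0.0, 0.5]]))

    def test_symmetric_matrix_equals_transpose(self):
        rng = np.random.default_rng(0)
        q = rng.integers(0, 8, size=(20, 20))
        glcm = compute_glcm(q, levels=8, symmetric=True, prequantized=True)
        assert np.array_equal(glcm.matrix, glcm.matrix.T)

    def test_empty_offsets_rejected(self):
        with pytest.raises(DomainError):
            compute_glcm(np.zeros((4, 4), dtype=int), levels=2, offsets=[],
                         prequantized=True)

    def test_matches_skimage_graycomatrix(self):
        """Cross-check against the reference co-occurrence implementation."""
        from skimage.feature import graycomatrix
        rng = np.random.default_rng(1)
        q = rng.integers(0, 16, size=(50, 50)).astype(np.uint8)
        # skimage angles 0/90 deg == our offsets (0,1) / (-1,0)
        for angle, off in ((0.0, (0, 1)), (np.pi / 2, (-1, 0))):
            ref = graycomatrix(q, [1], [angle], levels=16, symmetric=True,
                               normed=True)[:, :, 0, 0]
            got = compute_glcm(q, levels=16, offsets=[off], symmetric=True,
                               prequantized=True)
            assert np.allclose(got.matrix, ref, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 16))
    def test_normalization_property(self, seed, levels):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(12, 12))
        glcm = compute_glcm(img, levels=levels)
        assert glcm.matrix.sum() == pytest.approx(1.0)
        assert np.all(glcm.matrix >= 0)

    def test_quantization_bins_full_8bit_range(self):
        q = quantize_levels(np.array([0, 15, 16, 255]), 16)
        assert q.tolist() == [0, 0, 1, 15]
        with pytest.raises(DomainError):
            quantize_levels(np.array([300]), 16)


class TestHaralickFeatures:
    def test_constant_roi_closed_form(self):
        """Single-entry GLCM at level g: T1=1, T2=0, T3=1, T4=0, T6=2g, T7=T8=T9=0."""
        g = 5
        glcm = compute_glcm(np.full((10, 10), g), levels=16, prequantized=True)
        with caplog_degenerate() as records:
            t = haralick_features(glcm)
        assert any("degenerate" in r.getMessage() for r in records)
        assert t[0] == 1.0 and t[1] == 0.0 and t[2] == 1.0 and t[3] == 0.0
        assert t[4] == 0.0  # degenerate correlation reported as 0
        assert t[5] == 2 * g
        assert t[6] == 0.0 and t[7] == 0.0 and t[8] == 0.0

    def test_striped_image_features_hand_computed(self):
        """Full vector for C = [[.5,0],[0,.5]], evaluated by hand:
        T1=.5, T2=0, T3=1, T4=1 bit, T5=1, T6=1, T7=0, T8=1 bit, T9=0."""
        glcm = compute_glcm(np.array([[0, 1], [0, 1]]), levels=2, offsets=[(1, 0)],
                            symmetric=True, prequantized=True)
        t = haralick_features(glcm)
        assert np.allclose(t, [0.5, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0, 1.0, 0.0])

    def test_entropy_bounded_by_support(self):
        rng = np.random.default_rng(2)
        glcm = compute_glcm(rng.integers(0, 256, (30, 30)), levels=8)
        t4 = haralick_features(glcm)[3]
        assert t4 <= np.log2(np.count_nonzero(glcm.matrix)) + 1e-12

    def test_invariance_to_within_bin_shift(self):
        """A gray shift that moves no pixel across a quantization bin boundary
        leaves every feature unchanged."""
        rng = np.random.default_rng(3)
        base = rng.integers(0, 16, size=(40, 40)) * 16  # bin lower edges at K=16
        a = haralick_features(compute_glcm(base, levels=16))
        b = haralick_features(compute_glcm(base + 8, levels=16))
        assert np.allclose(a, b)


import contextlib
import logging


@contextlib.contextmanager
def caplog_degenerate():
    """Capture the degenerate-ROI warning emitted through the package logger."""
    records: list[logging.LogRecord] = []

    class _Handler(logging.Handler):
        def emit(self, record):
            records.append(record)

    logger = logging.getLogger("phasetex.texture")
    handler = _Handler(level=logging.WARNING)
    logger.addHandler(handler)
    try:
        yield records
    finally:
        logger.removeHandler(handler)


class TestROISampling:
    def test_protocol_counts_on_open_mask(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (512, 512)).astype(np.uint8)
        rois = sample_rois(img, np.ones((512, 512), bool), n=20, size=50, seed=0)
        assert len(rois) == 20
        corners = {(r.row, r.col) for r in rois}
        assert len(corners) == 20  # distinct top-left corners
        for r in rois:
            assert r.pixels.shape == (50, 50)
            assert 0 <= r.row <= 462 and 0 <= r.col <= 462

    def test_sampling_is_seeded(self):
        img = np.zeros((128, 128), np.uint8)
        mask = np.ones((128, 128), bool)
        a = sample_rois(img, mask, n=5, size=20, seed=9)
        b = sample_rois(img, mask, n=5, size=20, seed=9)
        assert [(r.row, r.col) for r in a] == [(r.row, r.col) for r in b]

    def test_rois_respect_the_mask(self):
        mask = np.zeros((128, 128), bool)
        mask[10:90, 20:110] = True
        rois = sample_rois(np.zeros((128, 128), np.uint8), mask, n=8, size=30, seed=1)
        for r in rois:
            assert mask[r.row:r.row + 30, r.col:r.col + 30].all()

    def test_insufficient_placements_error_names_deficit(self):
        mask = np.zeros((128, 128), bool)
        mask[0:51, 0:51] = True  # exactly 4 valid 50x50 corners
        with pytest.raises(PlacementError, match="4 ROI placements"):
            sample_rois(np.zeros((128, 128), np.uint8), mask, n=20, size=50, seed=0)


class TestFeatureMatrix:
    def _rois(self, n):
        rng = np.random.default_rng(5)
        return [ROI(rng.integers(0, 256, (50, 50)).astype(np.uint8), "img", i, 0)
                for i in range(n)]

    def test_shape_and_column_order(self):
        fm = feature_matrix(self._rois(20))
        assert fm.shape == (20, 9)
        assert len(FEATURE_NAMES) == 9

    def test_duplicate_rois_give_duplicate_rows(self):
        roi = self._rois(1)[0]
        fm = feature_matrix([roi, roi])
        assert np.array_equal(fm[0], fm[1])

    def test_row_order_tracks_roi_order(self):
        rois = self._rois(5)
        fm = feature_matrix(rois)
        fm_rev = feature_matrix(rois[::-1])
        assert np.allclose(fm[::-1], fm_rev)
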