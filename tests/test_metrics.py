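"""Region and boundary metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from tideseg.errors import ConfigError, InputError, ShapeError
from tideseg.metrics import (
    BoundaryPixelSet,
    ConfusionCounts,
    aggregate,
    bf_score,
    confusion,
    evaluate_pair,
    extract_boundary,
    hausdorff,
    region_metrics,
)
from tideseg.supervision import morphological_gradient


# ---------------------------------------------------------------- oracles
def bf_oracle(bp: set, bg: set, delta: float):
    """Exhaustive pairwise-distance BF-score."""
    if not bp and not bg:
        return 1.0, 1.0, 1.0
    if not bp or not bg:
        return 0.0, 0.0, 0.0
    p = np.array(sorted(bp), dtype=float)
    g = np.array(sorted(bg), dtype=float)
    d = cdist(p, g)
    prec = float((d.min(axis=1) <= delta).mean())
    rec = float((d.min(axis=0) <= delta).mean())
    bf = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, bf


def hd_oracle(bp: set, bg: set):
    if not bp and not bg:
        return 0.0
    if not bp or not bg:
        return float("nan")
    p = np.array(sorted(bp), dtype=float)
    g = np.array(sorted(bg), dtype=float)
    d = cdist(p, g)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def random_mask(seed: int, side: int, density: float) -> np.ndarray:
    return (np.random.default_rng(seed).random((side, side)) < density).astype(np.uint8)


class TestConfusionAndRegion:
    def test_confusion_cases(self):
        a = np.array([[1, 1], [0, 0]])
        b = np.array([[1, 0], [1, 0]])
        c = confusion(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        perfect = confusion(b, b)
        assert perfect.fp == perfect.fn == 0
        all_fp = confusion(np.ones((3, 3), dtype=int), np.zeros((3, 3), dtype=int))
        assert all_fp.fp == 9

    def test_confusion_rejects_bad_input(self):
        with pytest.raises(ShapeError):
            confusion(np.zeros((2, 2), dtype=int), np.zeros((3, 3), dtype=int))
        with pytest.raises(InputError):
            confusion(np.full((2, 2), 2), np.zeros((2, 2), dtype=int))

    def test_region_metrics_derived_example(self):
        miou, f1, prec, rec = region_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=20))
        assert miou == pytest.approx(0.5 * (0.6 + 20 / 22), rel=1e-12)
        assert miou == pytest.approx(0.7545, abs=1e-4)
        assert (prec, rec, f1) == (0.75, 0.75, 0.75)

    def test_perfect_and_absent_class_conventions(self):
        miou, f1, _, _ = region_metrics(ConfusionCounts(5, 0, 0, 20))
        assert miou == 1.0 and f1 == 1.0
        # all-background on all-background: absent foreground contributes IoU=1
        miou_bg, _, _, _ = region_metrics(ConfusionCounts(0, 0, 0, 25))
        assert miou_bg == 1.0

    def test_f1_harmonic_mean_identity(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 50, size=4)
            miou, f1, p, r = region_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            assert 0.0 <= miou <= 1.0
            if p + r > 0:
                assert abs(f1 - 2 * p * r / (p + r)) < 1e-12


class TestBoundaryExtraction:
    def test_extraction_cases(self):
        assert len(extract_boundary(np.zeros((6, 6), dtype=int))) == 0
        single = np.zeros((5, 5), dtype=int)
        single[2, 2] = 1
        assert len(extract_boundary(single)) == 9
        frame = extract_boundary(np.ones((5, 5), dtype=int))
        assert frame.pixels == {(r, c) for r in range(5) for c in range(5)
                                if r in (0, 4) or c in (0, 4)}

    def test_shares_definition_with_supervision_labels(self):
        mask = random_mask(7, 20, 0.3)
        grad = morphological_gradient(mask)
        bs = extract_boundary(mask)
        assert bs.pixels == set(zip(*np.nonzero(grad)))


class TestBfScore:
    def test_reference_cases(self):
        b = BoundaryPixelSet(frozenset({(0, 0), (1, 1)}))
        assert bf_score(b, b) == (1.0, 1.0, 1.0)
        bp = BoundaryPixelSet(frozenset({(0, 0), (10, 10)}))
        bg = BoundaryPixelSet(frozenset({(0, 0)}))
        prec, rec, bf = bf_score(bp, bg)
        assert (prec, rec) == (0.5, 1.0)
        assert bf == pytest.approx(2 / 3, rel=1e-12)

    def test_matching_is_inclusive_at_delta(self):
        bp = BoundaryPixelSet(frozenset({(0, 0)}))
        bg = BoundaryPixelSet(frozenset({(0, 3)}))
        assert bf_score(bp, bg, delta=3.0) == (1.0, 1.0, 1.0)

    def test_empty_set_conventions(self):
        empty = BoundaryPixelSet(frozenset())
        some = BoundaryPixelSet(frozenset({(1, 1)}))
        assert bf_score(empty, empty) == (1.0, 1.0, 1.0)
        assert bf_score(empty, some) == (0.0, 0.0, 0.0)
        assert bf_score(some, empty) == (0.0, 0.0, 0.0)

    def test_invalid_delta(self):
        with pytest.raises(ConfigError):
            BoundaryPixelSet(frozenset(), delta=0.0)
        with pytest.raises(ConfigError):
            bf_score(BoundaryPixelSet(frozenset({(0, 0)})),
                     BoundaryPixelSet(frozenset({(0, 0)})), delta=-1.0)

    def test_symmetry_under_swap(self, rng):
        for seed in range(20):
            bp = extract_boundary(random_mask(seed, 16, 0.3))
            bg = extract_boundary(random_mask(seed + 1000, 16, 0.3))
            p1, r1, bf1 = bf_score(bp, bg)
            p2, r2, bf2 = bf_score(bg, bp)
            assert (p1, r1) == (r2, p2)
            assert bf1 == pytest.approx(bf2, rel=1e-12)

    def test_monotone_in_delta(self):
        bp = extract_boundary(random_mask(3, 24, 0.2))
        bg = extract_boundary(random_mask(4, 24, 0.2))
        prev = (0.0, 0.0, 0.0)
        for delta in (1.0, 2.0, 3.0, 5.0, 10.0):
            cur = bf_score(bp, bg, delta=delta)
            assert all(c >= p - 1e-12 for c, p in zip(cur, prev))
            prev = cur


class TestHausdorff:
    def test_reference_cases(self):
        a = BoundaryPixelSet(frozenset({(0, 0), (2, 3)}))
        assert hausdorff(a, a) == 0.0
        assert hausdorff(BoundaryPixelSet(frozenset({(0, 0)})),
                         BoundaryPixelSet(frozenset({(3, 4)}))) == 5.0
        assert hausdorff(BoundaryPixelSet(frozenset({(0, 0), (0, 10)})),
                         BoundaryPixelSet(frozenset({(0, 0)}))) == 10.0

    def test_empty_conventions(self):
        empty = BoundaryPixelSet(frozenset())
        some = BoundaryPixelSet(frozenset({(0, 0)}))
        assert hausdorff(empty, empty) == 0.0
        assert np.isnan(hausdorff(empty, some))
        assert np.isnan(hausdorff(some, empty))

    def test_symmetric_and_zero_iff_equal(self):
        for seed in range(20):
            bp = extract_boundary(random_mask(seed, 16, 0.3))
            bg = extract_boundary(random_mask(seed + 500, 16, 0.3))
            if len(bp) == 0 or len(bg) == 0:
                continue
            d1, d2 = hausdorff(bp, bg), hausdorff(bg, bp)
            assert d1 == pytest.approx(d2, rel=1e-12)
            assert d1 >= 0.0
            assert (d1 == 0.0) == (bp.pixels == bg.pixels)


class TestOracleEquivalence:
    """BF-score and HD agree exactly with O(|Bp|*|Bg|) pairwise oracles."""

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(4, 32),
           st.floats(0.05, 0.6), st.floats(0.05, 0.6))
    def test_bf_and_hd_match_pairwise_oracles(self, seed, side, d1, d2):
        pred = random_mask(seed, side, d1)
        gt = random_mask(seed ^ 0xA5A5A5, side, d2)
        bp = extract_boundary(pred)
        bg = extract_boundary(gt)
        got = bf_score(bp, bg)
        want = bf_oracle(bp.pixels, bg.pixels, 3.0)
        np.testing.assert_allclose(got, want, rtol=0, atol=0)
        hd_got, hd_want = hausdorff(bp, bg), hd_oracle(bp.pixels, bg.pixels)
        if np.isnan(hd_want):
            assert np.isnan(hd_got)
        else:
            assert hd_got == hd_want


class TestAggregation:
    def test_single_and_identical_images(self):
        m = random_mask(11, 16, 0.3)
        p = random_mask(12, 16, 0.3)
        rep, cnt = evaluate_pair(p, m)
        agg1 = aggregate([rep], [cnt])
        assert agg1.miou == pytest.approx(rep.miou, rel=1e-12)
        assert agg1.bf_score == pytest.approx(rep.bf_score, rel=1e-12)
        agg2 = aggregate([rep, rep], [cnt, cnt])
        assert agg2.miou == pytest.approx(rep.miou, rel=1e-12)
        assert agg2.hd == pytest.approx(rep.hd, rel=1e-12)

    def test_region_metrics_pool_counts_not_scores(self):
        """Pooled IoU from summed counts, not the mean of per-image IoUs."""
        gt = np.zeros((4, 4), dtype=int)
        gt[:2] = 1
        half = gt.copy()
        half[0] = 0  # fg IoU 0.5
        rep1, c1 = evaluate_pair(half, gt)
        rep2, c2 = evaluate_pair(gt, gt)
        agg = aggregate([rep1, rep2], [c1, c2])
        pooled = c1 + c2
        miou_pooled, _, _, _ = region_metrics(pooled)
        assert agg.miou == pytest.approx(miou_pooled, rel=1e-12)
        naive = 0.5 * (rep1.miou + rep2.miou)
        assert abs(agg.miou - naive) > 1e-6

    def test_hd_excludes_undefined_images(self):
        gt = np.zeros((6, 6), dtype=int)
        gt[2:4, 2:4] = 1
        rep1, c1 = evaluate_pair(np.zeros_like(gt), gt)   # empty pred -> HD NaN
        rep2, c2 = evaluate_pair(gt, gt)                  # HD 0
        agg = aggregate([rep1, rep2], [c1, c2])
        assert agg.hd == 0.0
        assert agg.n_hd_excluded == 1

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            aggregate([], [])
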