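"""Metric oracles: overlap counts, skeleton topology, clDice, HD95, paired tests."""

import numpy as np
import pytest
from scipy import ndimage, stats

from snakeseg.exceptions import ShapeError
from snakeseg.metrics import (
    cldice,
    confusion_counts,
    evaluate_batch,
    hd95,
    overlap_metrics,
    paired_compare,
    skeletonize,
)


def random_blob_mask(rng, size=32, p=0.35):
    m = rng.random((size, size)) < p
    return ndimage.binary_closing(m)


class TestOverlap:
    def test_identical_masks_score_one(self, rng):
        m = random_blob_mask(rng)
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:2, :2] = True
        b[5:, 5:] = True
        assert overlap_metrics(a, b) == (0.0, 0.0, 0.0)

    def test_hand_counts(self):
        gt = np.zeros((3, 3), int)
        gt[0, 0] = gt[0, 1] = 1  # two positives
        pred = np.zeros((3, 3), int)
        pred[0, 0] = 1  # tp=1, fp=0, fn=1
        d, p, r = overlap_metrics(pred, gt)
        assert (d, p, r) == (pytest.approx(2 / 3), 1.0, 0.5)

    def test_empty_empty_convention(self):
        z = np.zeros((4, 4), bool)
        assert overlap_metrics(z, z) == (1.0, 1.0, 1.0)

    def test_confusion_counts_partition_image(self, rng):
        a, b = random_blob_mask(rng), random_blob_mask(rng)
        c = confusion_counts(a, b)
        assert c.total == a.size
        assert min(c.tp, c.fp, c.fn, c.tn) >= 0

    def test_dice_symmetry(self, rng):
        a, b = random_blob_mask(rng), random_blob_mask(rng)
        assert overlap_metrics(a, b)[0] == pytest.approx(overlap_metrics(b, a)[0])


class TestSkeletonize:
    def test_wide_bar_thins_to_line(self):
        m = np.zeros((9, 20), bool)
        m[3:6] = True
        sk = skeletonize(m)
        assert sk.sum(axis=0).max() == 1  # one pixel per column where present
        assert sk[~m].sum() == 0  # skeleton inside the mask

    def test_empty_mask_gives_empty_skeleton(self):
        assert skeletonize(np.zeros((5, 5), bool)).sum() == 0

    def test_component_count_preserved_on_random_blobs(self, rng):
        for _ in range(50):
            m = random_blob_mask(rng, p=0.25)
            sk = skeletonize(m)
            n_before = ndimage.label(m, structure=np.ones((3, 3)))[1]
            n_after = ndimage.label(sk, structure=np.ones((3, 3)))[1]
            assert n_before == n_after


class TestClDice:
    def test_identical_curve_scores_one(self):
        m = np.zeros((9, 9), bool)
        rr = np.arange(9)
        m[rr, rr] = True
        assert cldice(m, m) == 1.0

    def test_disjoint_curves_score_zero(self):
        a = np.zeros((9, 9), bool)
        b = np.zeros((9, 9), bool)
        a[0] = True
        b[8] = True
        assert cldice(a, b) == 0.0

    def test_empty_conventions(self):
        z = np.zeros((5, 5), bool)
        f = np.ones((5, 5), bool)
        assert cldice(z, z) == 1.0
        assert cldice(z, f) == 0.0
        assert cldice(f, z) == 0.0

    def test_half_covered_skeleton_hand_case(self):
        # gt: full 5-pixel horizontal line, pred: covers left 3 pixels
        gt = np.zeros((5, 5), bool)
        gt[2, :] = True
        pred = np.zeros((5, 5), bool)
        pred[2, :3] = True
        # skeletons equal the curves themselves here:
        # Tprec = 3/3, Tsens = 3/5, clDice = 2*(1*0.6)/1.6 = 0.75
        assert cldice(pred, gt) == pytest.approx(0.75)

    def test_never_exceeds_one(self, rng):
        for _ in range(20):
            a, b = random_blob_mask(rng), random_blob_mask(rng)
            assert 0.0 <= cldice(a, b) <= 1.0


class TestHd95:
    def test_identical_masks_zero(self, rng):
        m = random_blob_mask(rng)
        if m.any():
            assert hd95(m, m) == 0.0

    def test_two_single_pixels_five_apart(self):
        a = np.zeros((9, 9), bool)
        b = np.zeros((9, 9), bool)
        a[4, 1] = True
        b[4, 6] = True
        assert hd95(a, b) == pytest.approx(5.0)

    def test_empty_mask_returns_diagonal_sentinel(self):
        z = np.zeros((30, 40), bool)
        m = np.ones((30, 40), bool)
        assert hd95(z, m) == pytest.approx(np.hypot(30, 40))

    def test_matches_brute_force_on_random_pairs(self, rng):
        def brute(pred, gt):
            def boundary(m):
                pts = []
                H, W = m.shape
                for r in range(H):
                    for c in range(W):
                        if not m[r, c]:
                            continue
                        nb = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
                        if any(not (0 <= rr < H and 0 <= cc < W) or not m[rr, cc] for rr, cc in nb):
                            pts.append((r, c))
                return np.array(pts, dtype=float)

            bp, bg = boundary(pred), boundary(gt)
            d_pg = [min(np.hypot(*(p - q)) for q in bg) for p in bp]
            d_gp = [min(np.hypot(*(q - p)) for p in bp) for q in bg]
            return float(np.percentile(np.array(d_pg + d_gp), 95, method="linear"))

        checked = 0
        for _ in range(50):
            a, b = random_blob_mask(rng, 32), random_blob_mask(rng, 32)
            if not (a.any() and b.any()):
                continue
            assert hd95(a, b) == pytest.approx(brute(a, b), abs=1e-9)
            checked += 1
        assert checked >= 40

    def test_symmetry_and_translation_invariance(self, rng):
        a, b = random_blob_mask(rng, 16), random_blob_mask(rng, 16)
        if not (a.any() and b.any()):
            pytest.skip("degenerate draw")
        assert hd95(a, b) == pytest.approx(hd95(b, a))
        pad = ((3, 5), (2, 4))
        at = np.pad(a, pad)
        bt = np.pad(b, pad)
        assert hd95(at, bt) == pytest.approx(hd95(a, b))

    def test_directed_dialect_differs_but_bounded_below_by_zero(self, rng):
        a, b = random_blob_mask(rng, 16), random_blob_mask(rng, 16)
        if a.any() and b.any():
            assert hd95(a, b, dialect="directed") >= 0.0


class TestPairedCompare:
    def test_identical_vectors(self):
        v = np.linspace(0.5, 0.9, 10)
        r = paired_compare(v, v)
        assert r.mean_difference == 0.0
        assert r.p_value == 1.0

    def test_constant_shift_with_tiny_noise_has_huge_effect(self, rng):
        b = rng.uniform(0.6, 0.8, 30)
        a = b + 0.05 + rng.normal(0, 1e-4, 30)
        r = paired_compare(a, b)
        assert r.cohens_d > 50
        assert r.p_value < 1e-10

    def test_matches_textbook_t_statistic(self, rng):
        a = rng.uniform(0.5, 0.9, 10)
        b = rng.uniform(0.5, 0.9, 10)
        r = paired_compare(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        p = 2 * stats.t.sf(abs(t), df=9)
        assert r.p_value == pytest.approx(p, rel=1e-9)
        assert r.cohens_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([0.5], [0.6])


def test_evaluate_batch_writes_per_image_and_mean_rows(tmp_path, rng):
    preds = [random_blob_mask(rng) for _ in range(3)]
    csv = tmp_path / "metrics.csv"
    df = evaluate_batch(preds, preds, ids=["a", "b", "c"], csv_path=csv)
    assert list(df["id"]) == ["a", "b", "c", "mean"]
    assert df["dice"].iloc[-1] == pytest.approx(1.0)
    assert df["hd95"].iloc[-1] == pytest.approx(0.0)
    assert csv.exists()


def test_shape_mismatch_raises():
    with pytest.raises(ShapeError):
        overlap_metrics(np.zeros((3, 3)), np.zeros((4, 4)))
    with pytest.raises(ShapeError):
        hd95(np.zeros((3, 3)), np.zeros((4, 4)))


def test_write_comparisons_emits_csv_table(tmp_path, rng):
    a = rng.uniform(0.6, 0.9, 12)
    b = a - 0.03
    from snakeseg.metrics import write_comparisons

    df = write_comparisons({"ours_vs_baseline": paired_compare(a, b)}, tmp_path / "cmp.csv")
    assert (tmp_path / "cmp.csv").read_text().startswith("comparison,mean_difference,cohens_d,p_value")
    assert df.loc[0, "mean_difference"] == pytest.approx(0.03)
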