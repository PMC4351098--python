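"""ROC analysis, thresholding, landmarks and paired statistics.

The ROC and signed-rank implementations are checked against independent
brute-force oracles: pairwise concordance counting for the AUC and full
enumeration of sign assignments for the exact Wilcoxon null.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ortrack import (
    BinaryMask,
    SDI,
    dice_coefficient,
    finalize_tracts,
    measure_landmarks,
    paired_tests,
    roc_analysis,
    threshold_at_fpr,
    wilcoxon_signed_rank,
)


def affine_25():
    return np.diag([2.5, 2.5, 2.5, 1.0])


def make_instance(values, gold_flags, shape=None):
    """SDI + gold + search masks over a small 1-D voxel strip."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    shape = shape or (n, 1, 1)
    sdi = SDI(values.reshape(shape), affine_25(), n_retained=1)
    gold = BinaryMask(np.asarray(gold_flags, bool).reshape(shape), affine_25(), "gold")
    search = BinaryMask(np.ones(shape, bool), affine_25(), "search")
    return sdi, gold, search


def concordance_auc(values, gold_flags):
    """Brute-force Mann-Whitney concordance with tie correction."""
    values = np.asarray(values, dtype=float)
    gold_flags = np.asarray(gold_flags, bool)
    pos = values[gold_flags]
    neg = values[~gold_flags]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_classifier(self):
        gold = [True] * 4 + [False] * 6
        values = [1.0] * 4 + [0.0] * 6
        sdi, g, s = make_instance(values, gold)
        roc = roc_analysis(sdi, g, s)
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)

    def test_uninformative_uniform_noise(self):
        rng = np.random.default_rng(77)
        n = 10_000
        values = rng.random(n)
        gold = np.zeros(n, bool)
        gold[:2000] = True
        sdi, g, s = make_instance(values, gold, shape=(100, 100, 1))
        roc = roc_analysis(sdi, g, s)
        assert abs(roc.auc - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_matches_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        values = np.round(rng.random(n), 1)  # coarse values force ties
        gold = rng.random(n) < 0.5
        if gold.all() or not gold.any():
            gold[0] = ~gold[0]
        sdi, g, s = make_instance(values, gold)
        roc = roc_analysis(sdi, g, s)
        assert roc.auc == pytest.approx(concordance_auc(values, gold), abs=0.01)

    def test_monotone_tpr_and_grid(self):
        rng = np.random.default_rng(3)
        values = rng.random(50)
        gold = rng.random(50) < 0.4
        sdi, g, s = make_instance(values, gold)
        roc = roc_analysis(sdi, g, s)
        assert len(roc.fpr_grid) == 1000
        assert np.all(np.diff(roc.fpr_grid) > 0)
        assert np.all(np.diff(roc.tpr) >= -1e-12)
        assert -1 <= roc.youden_j <= 1

    def test_empty_gold_rejected(self):
        sdi, g, s = make_instance([0.1, 0.2], [False, False])
        with pytest.raises(ValueError, match="undefined|empty"):
            roc_analysis(sdi, g, s)


class TestThresholdAtFPR:
    def test_zero_fpr_boundary(self):
        values = [0.9, 0.8, 0.3, 0.2, 0.6]
        gold = [True, True, False, False, False]
        sdi, g, s = make_instance(values, gold)
        thr = threshold_at_fpr(sdi, g, s, target_fpr=0.0)
        assert thr == pytest.approx(0.6)  # the background maximum

    def test_fpr_one_boundary(self):
        values = [0.9, 0.8, 0.3, 0.2, 0.6]
        gold = [True, True, False, False, False]
        sdi, g, s = make_instance(values, gold)
        thr = threshold_at_fpr(sdi, g, s, target_fpr=1.0)
        assert thr == pytest.approx(min(values))

    def test_twenty_voxel_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        values = np.round(rng.random(20), 2)
        gold = np.zeros(20, bool)
        gold[:8] = True
        sdi, g, s = make_instance(values, gold)
        target = 0.25
        # oracle: enumerate every distinct threshold, recompute FPR directly
        best = None
        bg = values[~gold]
        for t in sorted(set(values)):
            fpr = np.mean(bg > t)
            if fpr <= target:
                best = t
                break
        assert threshold_at_fpr(sdi, g, s, target) == pytest.approx(best)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_target(self, seed, f1, f2):
        lo, hi = sorted([f1, f2])
        rng = np.random.default_rng(seed)
        values = np.round(rng.random(12), 1)
        gold = np.zeros(12, bool)
        gold[:5] = True
        sdi, g, s = make_instance(values, gold)
        t_lo = threshold_at_fpr(sdi, g, s, lo)
        t_hi = threshold_at_fpr(sdi, g, s, hi)
        assert t_hi <= t_lo

    def test_invalid_target(self):
        sdi, g, s = make_instance([0.1, 0.9], [True, False])
        with pytest.raises(ValueError):
            threshold_at_fpr(sdi, g, s, 1.5)


class TestFinalizeTracts:
    def sdi_of(self, values):
        return SDI(np.asarray(values, float).reshape(-1, 1, 1), affine_25(), 1)

    def test_median_threshold_applied_to_all(self):
        sdis = [self.sdi_of([0.3, 0.05]), self.sdi_of([0.25, 0.15]), self.sdi_of([0.5, 0.1])]
        masks, volumes, med = finalize_tracts(sdis, [0.1, 0.2, 0.4])
        assert med == pytest.approx(0.2)
        assert [m.n_voxels for m in masks] == [1, 1, 1]

    def test_volume_conversion(self):
        # 1000 suprathreshold voxels at 2.5 mm isotropic = 15.625 cm^3
        data = np.zeros((10, 10, 11))
        data.reshape(-1)[:1000] = 1.0
        masks, volumes, _ = finalize_tracts([SDI(data, affine_25(), 1)], [0.5])
        assert volumes[0] == pytest.approx(15.625)

    def test_single_subject_median_is_own_threshold(self):
        masks, volumes, med = finalize_tracts([self.sdi_of([0.4, 0.1])], [0.3])
        assert med == 0.3

    def test_empty_final_tract_warns_with_zero_volume(self):
        with pytest.warns(UserWarning, match="empty"):
            masks, volumes, _ = finalize_tracts([self.sdi_of([0.1, 0.05])], [0.9])
        assert volumes[0] == 0.0


class TestLandmarks:
    def tract(self, voxels, shape=(20, 30, 10)):
        data = np.zeros(shape, bool)
        for v in voxels:
            data[v] = True
        return BinaryMask(data, affine_25(), "tract")

    def test_anterior_slice_centroid(self):
        tract = self.tract([(5, 20, 4), (7, 20, 4), (6, 10, 4)])
        tp = np.array([15.0, 70.0, 10.0])
        op = np.array([15.0, 2.5, 10.0])
        lm = measure_landmarks(tract, tp, op)
        # most anterior occupied slice j=20 -> y=50; centroid x=15
        assert lm["mla_mm"][1] == pytest.approx(50.0)
        assert lm["mla_tp"] == pytest.approx(20.0)
        assert lm["mla_op"] == pytest.approx(47.5)
        assert lm["tp_op"] == pytest.approx(67.5)

    def test_posterior_translation_equivariance(self):
        tp = np.array([15.0, 70.0, 10.0])
        op = np.array([15.0, 2.5, 10.0])
        base = self.tract([(5, 20, 4), (5, 12, 4)])
        shifted = self.tract([(5, 16, 4), (5, 8, 4)])  # 4 voxels = 10 mm posterior
        d0 = measure_landmarks(base, tp, op)["mla_tp"]
        d1 = measure_landmarks(shifted, tp, op)["mla_tp"]
        assert d1 - d0 == pytest.approx(10.0)

    def test_gold_mask_tip_within_one_voxel(self, phantom):
        gold = BinaryMask(phantom.tract_mask, phantom.affine, "gold")
        lm = measure_landmarks(gold, phantom.landmarks["tp"], phantom.landmarks["op"])
        # the mask tip sits within tube radius + one voxel of the centerline apex
        tol = phantom.config.tube_radius_mm + 2.5
        assert abs(lm["mla_mm"][1] - phantom.anterior_tip_mm[1]) <= tol

    def test_empty_tract_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_landmarks(self.tract([]), np.zeros(3), np.zeros(3))


def enumerate_signed_rank_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_max = ranks.sum()
    w_tail = min(w_obs, w_max - w_obs)
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if w <= w_tail or w >= w_max - w_tail:
            count += 1
    return count / total


class TestPairedStatistics:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_signed_rank(np.ones(6), np.ones(6))
        assert res["degenerate"] and res["p_value"] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.3, 1.0, 6)
        b = np.zeros(6)
        expected = enumerate_signed_rank_p(a - b)
        res = wilcoxon_signed_rank(a, b)
        assert res["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.5, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        ours = wilcoxon_signed_rank(a, b)["p_value"]
        ref = stats.wilcoxon(a, b, zero_method="wilcox", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.4, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        ours = wilcoxon_signed_rank(a, b)["p_value"]
        ref = stats.wilcoxon(a, b, zero_method="wilcox", method="approx",
                             correction=False).pvalue
        assert ours == pytest.approx(ref, rel=0.05)

    def test_paired_t_of_zero_mean_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = paired_tests(a, a)
        assert res["ttest"]["statistic"] == 0.0
        assert res["ttest"]["p_value"] == 1.0

    def test_unequal_or_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_tests(np.ones(4), np.ones(4))
        with pytest.raises(ValueError):
            paired_tests(np.ones(6), np.ones(5))


def test_plot_roc_writes_png(tmp_path):
    from ortrack import plot_roc

    rng = np.random.default_rng(1)
    values = rng.random(40)
    gold = rng.random(40) < 0.5
    sdi, g, s = make_instance(values, gold)
    roc = roc_analysis(sdi, g, s)
    out = tmp_path / "roc.png"
    plot_roc({"csd": roc}, out)
    assert out.exists() and out.stat().st_size > 0


class TestDice:
    def test_identical_disjoint_and_empty(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        b = ~a
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, b) == 0.0
        empty = np.zeros((4, 4, 4), bool)
        assert dice_coefficient(empty, empty) == 1.0

    def test_half_overlap(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[:4] = True
        b[2:6] = True
        assert dice_coefficient(a, b) == pytest.approx(0.5)
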