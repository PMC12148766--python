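"""Reader agreement, heterogeneity criterion, Friedman and Wilcoxon tests."""

import itertools

import numpy as np
import pytest
import scipy.stats

from vent4d.core import FunctionImage
from vent4d.phantom import ReaderScore
from vent4d.stats import (
    binary_agreement,
    bonferroni_alpha,
    friedman_test,
    heterogeneity_criterion,
    posthoc_wilcoxon,
    wilcoxon_signed_rank,
)


def _scores(calls, method="A", lobes=None):
    lobes = lobes or ["RUL" if c else "none" for c in calls]
    return [
        ReaderScore(f"P{i}", method, bool(c), lobes[i])
        for i, c in enumerate(calls)
    ]


class TestBinaryAgreement:
    def test_perfect_agreement(self):
        ref = _scores([1, 0, 1, 1, 0])
        out = binary_agreement(ref, _scores([1, 0, 1, 1, 0], "B"))
        assert (out.sensitivity, out.precision, out.specificity, out.accuracy) == (1, 1, 1, 1)

    def test_complement_calls(self):
        ref = _scores([1, 0, 1, 0])
        out = binary_agreement(ref, _scores([0, 1, 0, 1], "B"))
        assert out.sensitivity == 0.0 and out.specificity == 0.0

    def test_hand_counted_confusion(self):
        # 10 cases: 4 TP, 1 FN, 2 FP, 3 TN
        ref = _scores([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        tst = _scores([1, 1, 1, 1, 0, 1, 1, 0, 0, 0], "B")
        out = binary_agreement(ref, tst)
        assert (out.tp, out.fn, out.fp, out.tn) == (4, 1, 2, 3)
        assert out.sensitivity == pytest.approx(0.8)
        assert out.precision == pytest.approx(0.667, abs=5e-4)
        assert out.specificity == pytest.approx(0.6)
        assert out.accuracy == pytest.approx(0.7)

    def test_patient_mismatch_rejected(self):
        ref = _scores([1, 0])
        bad = [ReaderScore("PX", "B", True, "RUL"), ReaderScore("P1", "B", False)]
        with pytest.raises(ValueError, match="symmetric difference"):
            binary_agreement(ref, bad)

    def test_location_mismatch_counts_against_test_arm(self):
        ref = _scores([1], lobes=["RUL"])
        tst = _scores([1], "B", lobes=["LLL"])
        loose = binary_agreement(ref, tst, use_location=False)
        strict = binary_agreement(ref, tst, use_location=True)
        assert loose.tp == 1 and strict.tp == 0 and strict.fp == 1

    def test_matches_bruteforce_counting_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 20)
            rc = rng.random(n) < 0.5
            tc = rng.random(n) < 0.5
            ref, tst = _scores(rc), _scores(tc, "B")
            out = binary_agreement(ref, tst)
            tp = int(np.sum(rc & tc))
            fp = int(np.sum(~rc & tc))
            fn = int(np.sum(rc & ~tc))
            tn = int(np.sum(~rc & ~tc))
            assert (out.tp, out.fp, out.fn, out.tn) == (tp, fp, fn, tn)


class TestHeterogeneityCriterion:
    def _scene(self, peri_value):
        n = 24
        lung = np.zeros((n, n, n), bool)
        lung[2:-2, 2:-2, 2:-2] = True
        tumor = np.zeros_like(lung)
        tumor[10:14, 10:14, 10:14] = True
        ax = np.arange(n)
        X = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).astype(float)
        r = np.linalg.norm(X - 11.5, axis=-1)
        vals = np.where(r < 9.0, peri_value, 1.0)
        f = FunctionImage(
            np.where(lung, vals, np.nan), "jacobian", np.ones(3), np.zeros(3)
        )
        return f, tumor, lung

    def test_uniform_function_fails(self):
        f, tumor, lung = self._scene(1.0)
        dec, ok = heterogeneity_criterion(f, tumor, lung, shell_mm=5, threshold=0.15)
        assert dec == pytest.approx(0.0, abs=1e-12) and not ok

    def test_clear_defect_passes(self):
        f, tumor, lung = self._scene(0.4)
        dec, ok = heterogeneity_criterion(f, tumor, lung, shell_mm=5, threshold=0.15)
        assert dec > 0.15 and ok

    def test_threshold_boundary_inclusive(self):
        f, tumor, lung = self._scene(1.0)
        dec, ok = heterogeneity_criterion(f, tumor, lung, shell_mm=5, threshold=0.0)
        assert ok  # decrease == threshold passes

    def test_empty_tumor_rejected(self):
        f, tumor, lung = self._scene(1.0)
        with pytest.raises(ValueError, match="empty"):
            heterogeneity_criterion(f, np.zeros_like(tumor), lung)


class TestFriedman:
    def test_identical_methods_give_null(self):
        x = np.tile([[3.0, 3.0, 3.0]], (5, 1))
        res = friedman_test(x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_three_by_three_perfect_ordering(self):
        # every patient ranks the methods (1, 2, 3): Q = 12n/(k(k+1)) * sum
        # (Rbar - 2)^2 = 12*3/12 * ((1-2)^2+(0)^2+(1)^2) = 6
        x = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [0.1, 0.2, 0.3]])
        res = friedman_test(x)
        assert res.statistic == pytest.approx(6.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 4))
        a = friedman_test(x)
        b = friedman_test(np.exp(x))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 4))
        mine = friedman_test(x)
        ref = scipy.stats.friedmanchisquare(*(x[:, j] for j in range(4)))
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_missing_cells_rejected(self):
        x = np.ones((3, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_test(x)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0 and res.n == 0 and res.n_zeros == 8

    def test_six_positive_differences_exact(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 7.0))
        assert res.exact
        assert res.p_value == pytest.approx(2 / 64)

    def test_exact_matches_full_sign_enumeration(self):
        rng = np.random.default_rng(2)
        for n in (5, 7, 10):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            ranks = scipy.stats.rankdata(np.abs(d))
            ws = [
                sum(r for r, s in zip(ranks, signs) if s > 0)
                for signs in itertools.product((-1, 1), repeat=n)
            ]
            ws = np.asarray(ws)
            w = res.statistic
            p_le = np.mean(ws <= w + 1e-12)
            p_ge = np.mean(ws >= w - 1e-12)
            expected = min(1.0, 2 * min(p_le, p_ge))
            assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_exact_mode(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        mine = wilcoxon_signed_rank(x, y)
        ref = scipy.stats.wilcoxon(x, y, mode="exact", alternative="two-sided")
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 1.0, 60)
        mine = wilcoxon_signed_rank(x)
        ref = scipy.stats.wilcoxon(x, mode="approx", correction=True)
        assert not mine.exact
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestPosthoc:
    def test_bonferroni_truncated_alpha(self):
        assert bonferroni_alpha(0.05, 3) == 0.016

    def test_identical_arms_not_significant(self):
        ref = np.arange(10.0)
        res = posthoc_wilcoxon(ref, {"same": ref.copy()})
        assert res[0].p_value == 1.0
        assert res[0].all_zero
        assert not res[0].significant

    def test_adjusted_alpha_applied(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=20)
        tests = {f"arm{i}": ref + rng.normal(0, 0.1, 20) for i in range(3)}
        for r in posthoc_wilcoxon(ref, tests):
            assert r.adjusted_alpha == 0.016
            assert r.significant == (r.p_value < 0.016)

    def test_null_rejection_rate_calibrated(self):
        # type-I error at the Bonferroni-adjusted alpha over simulated
        # null families of paired samples
        rng = np.random.default_rng(6)
        n_fam, n = 2000, 20
        alpha = bonferroni_alpha(0.05, 3)
        rejections = 0
        for _ in range(n_fam):
            d = rng.normal(size=n)
            rejections += wilcoxon_signed_rank(d).p_value < alpha
        rate = rejections / n_fam
        se = np.sqrt(alpha * (1 - alpha) / n_fam)
        assert abs(rate - alpha) <= 3 * se
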