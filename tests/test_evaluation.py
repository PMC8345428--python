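"""Confusion counting, metric formulas, Fisher's LSD, cohort tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ptcscreen import (ConfusionCounts, confusion, evaluate_cohort, lsd_test,
                       metrics)


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.zeros((100, 100), dtype=np.uint8)
        truth.flat[:100] = 2
        c = confusion(truth, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (100, 0, 0, 9900)

    def test_all_negative_prediction(self):
        truth = np.zeros((50, 50), dtype=np.uint8)
        truth.flat[:77] = 2
        c = confusion(np.zeros_like(truth), truth)
        assert (c.tp, c.fn) == (0, 77)
        assert c.fp == 0

    def test_4x4_worked_example(self):
        """Enumerated 16-pixel case: tp=5, fp=2, fn=1, tn=8."""
        truth = np.array([
            [2, 2, 0, 0],
            [2, 2, 0, 0],
            [2, 2, 0, 0],
            [0, 0, 0, 0]], dtype=np.uint8)
        pred = np.array([
            [2, 2, 2, 0],
            [2, 2, 2, 0],
            [2, 0, 0, 0],
            [0, 0, 0, 0]], dtype=np.uint8)
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 2, 1, 8)
        rec = metrics(c)
        assert rec.precision == pytest.approx(5 / 7)
        assert rec.recall == pytest.approx(5 / 6)
        assert rec.jaccard == pytest.approx(5 / 8)
        assert rec.accuracy == pytest.approx(13 / 16)
        assert rec.f1 == pytest.approx(10 / 13)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((4, 4)), np.zeros((5, 4)))

    def test_streaming_equals_dense(self):
        """Block-streamed counts equal a dense one-shot comparison."""
        rng = np.random.default_rng(12)
        pred = rng.integers(0, 3, (700, 900)).astype(np.uint8)
        truth = rng.integers(0, 3, (700, 900)).astype(np.uint8)
        streamed = confusion(pred, truth, block_px=128)
        pb, tb = pred == 2, truth == 2
        assert streamed.tp == int((pb & tb).sum())
        assert streamed.fp == int((pb & ~tb).sum())
        assert streamed.fn == int((~pb & tb).sum())
        assert streamed.tn == int((~pb & ~tb).sum())

    def test_mask_path_input(self, small_slide):
        c = confusion(small_slide["truth_path"], small_slide["truth"])
        assert c.fp == c.fn == 0
        assert c.tp == int((small_slide["truth"] == 2).sum())


class TestMetrics:
    def test_empty_positive_convention(self):
        rec = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=100))
        assert (rec.precision, rec.recall, rec.f1, rec.jaccard) == (1, 1, 1, 1)
        assert rec.accuracy == 1.0

    def test_empty_denominator_otherwise_zero(self):
        rec = metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=95))
        assert rec.precision == 0.0
        assert rec.recall == 0.0

    def test_total_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts())

    @given(tp=st.integers(0, 1000), fp=st.integers(0, 1000),
           fn=st.integers(0, 1000), tn=st.integers(1, 1000))
    @settings(max_examples=200, deadline=None)
    def test_f1_jaccard_identity(self, tp, fp, fn, tn):
        rec = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        assert rec.f1 == pytest.approx(2 * rec.jaccard / (1 + rec.jaccard))


class TestLSD:
    def test_identical_groups(self):
        out = lsd_test({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out[0].mean_diff == 0.0
        assert out[0].p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """{1,2,3} vs {4,5,6}: MSE=1, SE=sqrt(2/3), t=-3.674, p≈0.0213."""
        (cmp,) = lsd_test({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert cmp.mean_diff == pytest.approx(-3.0)
        assert cmp.std_error == pytest.approx(np.sqrt(2 / 3))
        assert cmp.df == 4
        assert cmp.p_value == pytest.approx(0.0213116, abs=1e-6)
        assert cmp.ci_low <= cmp.mean_diff <= cmp.ci_high

    def test_pair_swap_symmetry(self):
        a = {"a": [1.0, 2.0, 4.0], "b": [2.5, 3.5, 5.0]}
        b = {"b": a["b"], "a": a["a"]}
        (c1,), (c2,) = lsd_test(a), lsd_test(b)
        assert c1.mean_diff == pytest.approx(-c2.mean_diff)
        assert c1.p_value == pytest.approx(c2.p_value)
        assert c1.ci_low == pytest.approx(-c2.ci_high)
        assert c1.ci_high == pytest.approx(-c2.ci_low)

    def test_two_groups_match_pooled_t_test(self):
        """For k=2, LSD equals the equal-variance two-sample t test."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(2, 9)).tolist()
            y = rng.normal(0.5, 1.5, rng.integers(2, 9)).tolist()
            (cmp,) = lsd_test({"x": x, "y": y})
            t, p = stats.ttest_ind(x, y, equal_var=True)
            assert cmp.p_value == pytest.approx(p, abs=1e-10)

    def test_three_groups_match_anova_oracle(self):
        """Pooled MSE agrees with a brute-force ANOVA table and f_oneway."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            groups = {g: rng.normal(i, 1, 5).tolist()
                      for i, g in enumerate("abc")}
            comps = lsd_test(groups)
            # brute-force within-group sum of squares
            ssw = sum(sum((v - np.mean(vals)) ** 2 for v in vals)
                      for vals in groups.values())
            n = sum(len(v) for v in groups.values())
            mse = ssw / (n - 3)
            for cmp in comps:
                ni = len(groups[cmp.group_i])
                nj = len(groups[cmp.group_j])
                se = np.sqrt(mse * (1 / ni + 1 / nj))
                assert cmp.std_error == pytest.approx(se, abs=1e-12)
                diff = (np.mean(groups[cmp.group_i])
                        - np.mean(groups[cmp.group_j]))
                t = diff / se
                p = 2 * stats.t.sf(abs(t), n - 3)
                assert cmp.p_value == pytest.approx(p, abs=1e-10)
            # cross-check the pooled variance against scipy's one-way ANOVA
            f, _ = stats.f_oneway(*groups.values())
            means = [np.mean(v) for v in groups.values()]
            grand = np.mean(np.concatenate([np.asarray(v) for v in groups.values()]))
            ssb = sum(len(v) * (m - grand) ** 2
                      for v, m in zip(groups.values(), means))
            assert ssb / 2 / mse == pytest.approx(f, rel=1e-10)

    def test_degenerate_variance_flagged(self):
        out = lsd_test({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert out[0].degenerate
        assert out[0].p_value == 0.0

    def test_group_validation(self):
        with pytest.raises(ValueError):
            lsd_test({"a": [1, 2]})
        with pytest.raises(ValueError):
            lsd_test({"a": [1, 2], "b": [3]})


class TestEvaluateCohort:
    def _mask_pair(self, seed, perfect=False):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 3, (64, 64)).astype(np.uint8)
        pred = truth.copy() if perfect else rng.integers(0, 3, (64, 64)).astype(np.uint8)
        return pred, truth

    def test_single_perfect_slide(self):
        pred, truth = self._mask_pair(1, perfect=True)
        per_slide, summary, lsd = evaluate_cohort({"s1": pred}, {"s1": truth})
        row = summary.iloc[0]
        for m in ("accuracy", "precision", "recall", "f1", "jaccard"):
            assert row[m] == 1.0
        assert lsd.empty

    def test_macro_mean_of_per_slide(self):
        preds, truths = {}, {}
        for i in range(3):
            preds[f"s{i}"], truths[f"s{i}"] = self._mask_pair(i + 10)
        per_slide, summary, _ = evaluate_cohort(preds, truths)
        assert summary.iloc[0]["accuracy"] == pytest.approx(
            per_slide["accuracy"].mean())

    def test_stratified_summary(self):
        preds, truths = {}, {}
        for i in range(4):
            preds[f"s{i}"], truths[f"s{i}"] = self._mask_pair(i + 20)
        types = {"s0": "FNA", "s1": "FNA", "s2": "TP", "s3": "TP"}
        _, summary, _ = evaluate_cohort(preds, truths, slide_types=types)
        assert set(summary["stratum"]) == {"All", "FNA", "TP"}
        # without stratification only the overall row appears
        _, summary2, _ = evaluate_cohort(preds, truths)
        assert set(summary2["stratum"]) == {"All"}

    def test_two_methods_yield_lsd_table(self, tmp_path):
        truths = {}
        by_method = {"m1": {}, "m2": {}}
        for i in range(3):
            p1, t = self._mask_pair(i + 30)
            p2, _ = self._mask_pair(i + 60)
            truths[f"s{i}"] = t
            by_method["m1"][f"s{i}"] = p1
            by_method["m2"][f"s{i}"] = p2
        per_slide, summary, lsd = evaluate_cohort(
            by_method, truths, out_dir=tmp_path)
        assert len(lsd) == 5  # one pair per metric
        assert (tmp_path / "per_slide.csv").exists()
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "lsd.csv").exists()

    def test_missing_slide_named(self):
        pred, truth = self._mask_pair(99)
        with pytest.raises(ValueError, match="s_missing"):
            evaluate_cohort({"s1": pred}, {"s1": truth, "s_missing": truth})
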