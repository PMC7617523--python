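"""Classifier metric arithmetic, ΔΔG thresholding, and McNemar's test."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppi_missense.evaluation import (
    ConfusionCounts,
    DdgThreshold,
    benchmark_table,
    classify_ddg,
    compute_metrics,
    confusion_from_calls,
    mcnemar_test,
)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert m.sensitivity == m.specificity == m.accuracy == m.mcc == 1.0
        assert m.fpr == 0.0 and math.isinf(m.tpr_fpr_ratio)

    def test_coin_flip_symmetry(self):
        m = compute_metrics(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert m.mcc == 0.0
        assert m.accuracy == 0.5

    def test_counts_vs_raw_call_lists(self):
        labels = ["damaging"] * 6 + ["benign"] * 4
        calls = ["damaging", "neutral", "damaging", "damaging", "neutral",
                 "damaging", "neutral", "damaging", "neutral", "neutral"]
        c = confusion_from_calls(labels, calls)
        assert (c.tp, c.fn, c.fp, c.tn) == (4, 2, 1, 3)
        m = compute_metrics(c)
        assert m.accuracy == pytest.approx(0.7)

    def test_degenerate_marginal_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=5))

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(derandomize=True, max_examples=200)
    def test_mcc_bounded_and_label_swap_negates(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0 or tp + fp + tn + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert -1.0 <= m.mcc <= 1.0
        if fn + fp > 0 or True:
            swapped = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
            assert swapped.mcc == pytest.approx(-(-m.mcc))
            assert swapped.accuracy == pytest.approx(m.accuracy)


class TestClassifyDdg:
    @pytest.mark.parametrize("ddg, expected", [
        (1.6, "damaging"), (-1.6, "damaging"),
        (1.5, "damaging"), (-1.5, "damaging"),  # boundary inclusive
        (1.49, "neutral"), (-1.49, "neutral"),
        (0.3, "neutral"), (0.0, "neutral"),
    ])
    def test_two_sided_rule(self, ddg, expected):
        assert classify_ddg(ddg) == expected

    @given(st.floats(-20, 20, allow_nan=False))
    @settings(derandomize=True)
    def test_sign_symmetry(self, x):
        assert classify_ddg(x) == classify_ddg(-x)

    def test_custom_cutoff(self):
        assert classify_ddg(1.0, DdgThreshold(0.5)) == "damaging"


class TestMcNemar:
    def test_formula_statistic_without_exact_switch(self):
        pairs = [(True, False)] * 10  # b=10, c=0
        stat, p = mcnemar_test(pairs, exact_threshold=0)
        assert stat == pytest.approx(10.0)
        assert p < 0.005

    def test_balanced_discordance_is_null(self):
        pairs = [(True, False)] * 7 + [(False, True)] * 7
        for exact in (0, 25):
            _, p = mcnemar_test(pairs, exact_threshold=exact)
            assert p == pytest.approx(1.0)

    def test_small_counts_use_exact_binomial(self):
        pairs = [(True, False)] * 3 + [(False, True)]  # b=3, c=1
        _, p = mcnemar_test(pairs)
        assert p == pytest.approx(0.625)

    def test_no_discordance_is_p_one(self):
        pairs = [(True, True)] * 5 + [(False, False)] * 3
        stat, p = mcnemar_test(pairs)
        assert (stat, p) == (0.0, 1.0)


class TestBenchmarkTable:
    def test_mixed_call_and_ddg_columns(self):
        df = pd.DataFrame({
            "variant_id": ["v1", "v2", "v3", "v4"],
            "label": ["damaging", "damaging", "benign", "benign"],
            "structural": ["damaging", "neutral", "neutral", "neutral"],
            "energy": [2.0, 0.5, -0.2, -3.0],
        })
        metrics, pvals = benchmark_table(df)
        assert metrics.loc["structural", "sensitivity"] == pytest.approx(0.5)
        assert metrics.loc["structural", "specificity"] == pytest.approx(1.0)
        # energy: v1 damaging (2.0), v4 damaging (-3.0, two-sided rule)
        assert metrics.loc["energy", "sensitivity"] == pytest.approx(0.5)
        assert metrics.loc["energy", "specificity"] == pytest.approx(0.5)
        assert pvals.shape == (2, 2)
        assert pvals.loc["structural", "energy"] == pvals.loc["energy", "structural"]
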