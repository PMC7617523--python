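"""Binary-classifier evaluation and benchmarking arithmetic.

Covers the confusion-matrix panel (sensitivity, specificity, TPR, FPR,
TPR/FPR ratio, accuracy, Matthews correlation coefficient), the two-sided
ΔΔG thresholding used to binarise energy-based predictors, and McNemar's
paired test for comparing two classifiers on the same variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts", "MetricPanel", "DdgThreshold",
    "compute_metrics", "confusion_from_calls", "classify_ddg",
    "mcnemar_test", "benchmark_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricPanel:
    sensitivity: float
    specificity: float
    tpr: float
    fpr: float
    tpr_fpr_ratio: float  # inf when fpr == 0
    accuracy: float
    mcc: float


def compute_metrics(c: ConfusionCounts) -> MetricPanel:
    """Full performance panel from a confusion matrix.

    The MCC is defined as 0 when any marginal is empty (the usual
    convention for a degenerate classifier), and the TPR/FPR ratio is
    reported as ``inf`` when no false positives occur.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0 or neg == 0:
        raise ValueError("metrics require at least one positive and one negative")

    sens = c.tp / pos
    spec = c.tn / neg
    fpr = c.fp / neg
    accuracy = (c.tp + c.tn) / c.total

    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / denom
    ratio = math.inf if fpr == 0 else sens / fpr
    return MetricPanel(sens, spec, sens, fpr, ratio, accuracy, mcc)


def confusion_from_calls(labels, calls, positive="damaging") -> ConfusionCounts:
    """Build counts from parallel lists of true labels and predicted calls."""
    if len(labels) != len(calls):
        raise ValueError("labels and calls differ in length")
    tp = fp = tn = fn = 0
    for lab, call in zip(labels, calls):
        truth = lab == positive
        pred = call == positive
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


@dataclass(frozen=True)
class DdgThreshold:
    cutoff: float = 1.5  # kcal/mol

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("ddg cutoff must be positive")


def classify_ddg(ddg: float, thr: DdgThreshold = DdgThreshold()) -> str:
    """Two-sided binding-energy rule: damaging when |ΔΔG| >= cutoff.

    Destabilising and (over-)stabilising changes both count as damaging;
    the boundary value itself is damaging (inclusive threshold).
    """
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    return "damaging" if abs(ddg) >= thr.cutoff else "neutral"


def mcnemar_test(
    paired_calls,
    continuity_correction: bool = False,
    exact_threshold: int = 25,
) -> tuple[float, float]:
    """McNemar's paired test on (method_a_correct, method_b_correct) pairs.

    Returns (statistic, p-value). With fewer than ``exact_threshold``
    discordant pairs the exact two-sided binomial test is used and the
    statistic reported is the smaller discordant count; otherwise the
    chi-squared approximation on 1 df (continuity correction optional).
    Zero discordant pairs give p = 1 by convention.
    """
    b = sum(1 for a_ok, b_ok in paired_calls if a_ok and not b_ok)
    c = sum(1 for a_ok, b_ok in paired_calls if b_ok and not a_ok)
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if n < exact_threshold:
        p = float(stats.binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue)
        return float(min(b, c)), min(p, 1.0)
    diff = abs(b - c) - (1.0 if continuity_correction else 0.0)
    chi2 = max(diff, 0.0) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def benchmark_table(
    df: pd.DataFrame,
    label_col: str = "label",
    ddg_threshold: DdgThreshold = DdgThreshold(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate several predictors against shared variant annotations.

    ``df`` holds one row per variant: a ``label`` column with
    damaging/benign annotations and one column per method containing
    either a categorical call (damaging/neutral) or a ΔΔG in kcal/mol
    (binarised with the two-sided rule). Returns (metric panel per
    method, pairwise McNemar p-value matrix).
    """
    if label_col not in df.columns:
        raise ValueError(f"missing {label_col!r} column")
    labels = ["damaging" if str(v).lower() in ("damaging", "pathogenic") else "benign"
              for v in df[label_col]]
    methods = [c for c in df.columns if c not in (label_col, "variant_id")]

    calls: dict[str, list[str]] = {}
    for m in methods:
        col = df[m]
        if col.dtype.kind in "fi":
            calls[m] = [classify_ddg(float(v), ddg_threshold) for v in col]
        else:
            calls[m] = [str(v).lower() for v in col]

    rows = []
    for m in methods:
        panel = compute_metrics(confusion_from_calls(labels, calls[m]))
        rows.append({
            "method": m,
            "sensitivity": panel.sensitivity,
            "specificity": panel.specificity,
            "tpr": panel.tpr,
            "fpr": panel.fpr,
            "tpr_fpr_ratio": panel.tpr_fpr_ratio,
            "accuracy": panel.accuracy,
            "mcc": panel.mcc,
        })
    metrics = pd.DataFrame(rows).set_index("method")

    pvals = pd.DataFrame(1.0, index=methods, columns=methods)
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            pairs = [
                (call_a == ("damaging" if lab == "damaging" else "neutral"),
                 call_b == ("damaging" if lab == "damaging" else "neutral"))
                for lab, call_a, call_b in zip(labels, calls[ma], calls[mb])
            ]
            _, p = mcnemar_test(pairs)
            pvals.loc[ma, mb] = pvals.loc[mb, ma] = p
    return metrics, pvals
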