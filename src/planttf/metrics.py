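"""Classification metrics with open-set "unknown" accounting, threshold sweeps,
and the Mann-Whitney U comparison of per-family score vectors.

Metrics are one-vs-rest per family: accuracy = (TP+TN)/(TP+TN+FP+FN),
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); aggregated as
micro (global TP/FP/FN sums), macro (unweighted mean over families present in
the truth) and weighted (family-size weighted mean). A prediction of
``"unknown"`` counts as an error: it contributes a false negative to the true
family and a true negative everywhere else — so micro accuracy falls as the
rejection threshold rises. In single-label evaluation micro precision, recall
and F1 all equal accuracy; they are reported anyway for a complete grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import UNKNOWN_LABEL, EnsembleModel, finalize, predict_proba, score_all

#: Thresholds of the standard stringency sweep.
DEFAULT_THRESHOLDS = (0.0, 0.5, 0.95)

#: Largest n1*n2 for which the Mann-Whitney p-value is computed by exact
#: enumeration of all group assignments; larger samples use the normal
#: approximation with tie correction.
EXACT_MWU_LIMIT = 64


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class. Rows sum to the evaluated total."""

    classes: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.classes, "TP": self.tp, "FP": self.fp,
             "FN": self.fn, "TN": self.tn}
        )


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> ConfusionCounts:
    """One-vs-rest confusion counts; ``y_pred`` may contain ``"unknown"``."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    n_cls = len(classes)
    tp = np.zeros(n_cls, dtype=np.int64)
    fp = np.zeros(n_cls, dtype=np.int64)
    fn = np.zeros(n_cls, dtype=np.int64)
    for truth, pred in zip(y_true, y_pred):
        if truth not in index:
            raise ValueError(f"true label {truth!r} not in classes")
        t = index[truth]
        if pred == truth:
            tp[t] += 1
        else:
            fn[t] += 1
            if pred != UNKNOWN_LABEL:
                if pred not in index:
                    raise ValueError(f"predicted label {pred!r} not in classes")
                fp[index[pred]] += 1
    total = len(y_true)
    tn = total - tp - fp - fn
    return ConfusionCounts(classes=classes, tp=tp, fp=fp, fn=fn, tn=tn)


def _prf(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> tuple:
    # 0/0 -> 0 convention for empty precision/recall denominators
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return precision, recall, f1


@dataclass
class MetricsReport:
    """Micro/macro/weighted aggregate metrics plus the per-class table."""

    micro: dict[str, float]
    macro: dict[str, float]
    weighted: dict[str, float]
    per_class: pd.DataFrame
    n_unknown: int
    threshold: float | None = None
    method: str | None = None

    def as_grid(self) -> pd.DataFrame:
        rows = []
        for avg, d in (("micro", self.micro), ("macro", self.macro),
                       ("weighted", self.weighted)):
            for metric, value in d.items():
                rows.append({"averaging": avg, "metric": metric, "value": value,
                             "method": self.method, "threshold": self.threshold})
        return pd.DataFrame(rows)


def averaged_metrics(
    counts: ConfusionCounts,
    threshold: float | None = None,
    method: str | None = None,
) -> MetricsReport:
    """Aggregate one-vs-rest counts into micro/macro/weighted metrics.

    Macro and weighted means run over classes with at least one true member;
    weights are class sizes (TP+FN).
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    sizes = tp + fn
    total = int(sizes.sum())
    if total == 0:
        raise ValueError("no evaluated sequences")

    precision, recall, f1 = _prf(tp, fp, fn)
    per_class = counts.as_frame().assign(
        precision=precision, recall=recall, f1=f1, support=sizes
    )

    tp_g, fp_g, fn_g = int(tp.sum()), int(fp.sum()), int(fn.sum())
    accuracy = tp_g / total
    micro_p = tp_g / (tp_g + fp_g) if tp_g + fp_g else 0.0
    micro_r = tp_g / (tp_g + fn_g) if tp_g + fn_g else 0.0
    micro_f1 = (
        2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    )
    micro = {"accuracy": accuracy, "precision": micro_p,
             "recall": micro_r, "f1": micro_f1}

    present = sizes > 0
    macro = {
        "precision": float(precision[present].mean()),
        "recall": float(recall[present].mean()),
        "f1": float(f1[present].mean()),
    }
    w = sizes[present] / total
    weighted = {
        "precision": float((precision[present] * w).sum()),
        "recall": float((recall[present] * w).sum()),
        "f1": float((f1[present] * w).sum()),
    }
    # Every misassignment contributes one FN and one FP; a rejection only an
    # FN. Hence the rejected count is the FN/FP surplus.
    n_unknown = int(fn.sum() - fp.sum())
    return MetricsReport(
        micro=micro, macro=macro, weighted=weighted, per_class=per_class,
        n_unknown=n_unknown, threshold=threshold, method=method,
    )


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str],
    threshold: float | None = None,
    method: str | None = None,
) -> MetricsReport:
    """confusion + averaged_metrics in one call."""
    return averaged_metrics(
        confusion(y_true, y_pred, classes), threshold=threshold, method=method
    )


def threshold_sweep(
    ensemble: EnsembleModel,
    corpus,
    y_true: Sequence[str],
    method: str = "two_stage",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[MetricsReport]:
    """Evaluate one inference pass at several confidence thresholds.

    Base-learner scores are computed once (and mapped through the stacker once
    for the two-stage method); each threshold only re-runs the cheap
    thresholded argmax.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    P = score_all(ensemble, corpus)
    if method == "two_stage":
        if ensemble.stacker is None:
            raise ValueError("two_stage sweep requires a stacker")
        scores = predict_proba(ensemble.stacker, P)
    elif method == "max_vote":
        scores = P
    else:
        raise ValueError(f"unknown method {method!r}")
    reports = []
    for t in thresholds:
        labels, _ = finalize(scores, ensemble.families, t)
        reports.append(
            evaluate(y_true, labels, ensemble.families, threshold=t, method=method)
        )
    return reports


def per_family_scores(report: MetricsReport, metric: str = "f1") -> np.ndarray:
    """Per-family score vector (e.g. for Mann-Whitney comparison of methods)."""
    table = report.per_class
    if metric == "accuracy":
        total = int((table["TP"] + table["FN"]).sum())
        return ((table["TP"] + table["TN"]) / total).to_numpy()
    if metric not in table.columns:
        raise ValueError(f"unknown per-class metric {metric!r}")
    return table[metric].to_numpy()


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U statistic of sample ``a`` with a two-sided p-value.

    U is the rank-sum statistic with midranks for ties. For small problems
    (n1*n2 <= 64) the p-value is the exact permutation probability obtained by
    enumerating every assignment of the pooled values into the two groups; for
    larger samples the normal approximation with tie correction is used.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if n1 * n2 <= EXACT_MWU_LIMIT:
        p = _exact_mwu_p(ranks, n1, u_a)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u_a, p


def _exact_mwu_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all C(n, n1) group assignments of the
    pooled midranks (valid under ties)."""
    n = ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    hits = 0
    offset = n1 * (n1 + 1) / 2
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / comb(n, n1)
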