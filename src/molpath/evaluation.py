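"""Multi-label evaluation: micro-averaged metrics and model comparison.

All four headline metrics — accuracy, precision, recall, F1 — are computed
from the micro confusion counts pooled over every (compound, pathway) cell
of the prediction and truth matrices. Accuracy is element-wise over those
cells, which is why it can sit far above F1 on a sparse label matrix.
Undefined divisions (e.g. precision with no positive predictions) return 0
with an explicit warning flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def _validate_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} matrix must be binary")
    return pred.astype(np.int64), truth.astype(np.int64)


def micro_confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) pooled over all N*L cells."""
    pred, truth = _validate_pair(pred, truth)
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    return tp, fp, fn, tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def metrics_report(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Micro metrics over a prediction/truth label-matrix pair."""
    tp, fp, fn, tn = micro_confusion(pred, truth)
    total = tp + fp + fn + tn
    undefined: list[str] = []
    accuracy = (tp + tn) / total if total else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1,
                         tp=tp, fp=fp, fn=fn, tn=tn, undefined=tuple(undefined))


@dataclass(frozen=True)
class PerClassReport:
    """One one-vs-rest MetricsReport per pathway label."""

    reports: tuple[MetricsReport, ...]
    label_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.reports) != len(self.label_names):
            raise ValueError("one report per label required")

    def as_table(self) -> str:
        header = f"{'label':<28}{'accuracy':>10}{'precision':>11}{'recall':>9}{'f1':>9}"
        lines = [header]
        for name, r in zip(self.label_names, self.reports):
            lines.append(f"{name:<28}{r.accuracy:>10.4f}{r.precision:>11.4f}{r.recall:>9.4f}{r.f1:>9.4f}")
        return "\n".join(lines)


def per_class_report(pred: np.ndarray, truth: np.ndarray, label_names) -> PerClassReport:
    """Per-pathway one-vs-rest metrics (per-category table layout)."""
    pred, truth = _validate_pair(pred, truth)
    if pred.ndim != 2 or pred.shape[1] != len(label_names):
        raise ValueError("matrices must be (N, L) with one column per label")
    reports = tuple(metrics_report(pred[:, j], truth[:, j]) for j in range(pred.shape[1]))
    return PerClassReport(reports=reports, label_names=tuple(label_names))


def compare_models_ttest(scores_a, scores_b) -> float:
    """Two-tailed two-sample Student t-test (equal variance) on fold scores.

    Raises on zero pooled variance, where the statistic is undefined.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two scores per model")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    result = stats.ttest_ind(a, b, equal_var=True)
    return float(result.pvalue)


def significance_stars(p_value: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value out of range: {p_value}")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def summarize_folds(reports) -> dict[str, dict[str, float]]:
    """Mean +/- standard deviation of each metric across CV folds."""
    out: dict[str, dict[str, float]] = {}
    for metric in ("accuracy", "precision", "recall", "f1"):
        values = np.array([getattr(r, metric) for r in reports], dtype=float)
        out[metric] = {"mean": float(values.mean()), "std": float(values.std(ddof=0))}
    return out
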