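"""Multi-label evaluation: the five set-theoretic metrics, the repeated
random-subsample protocol, and significance testing between methods.

For sample i with true label set L_i and predicted set L*_i over M classes:

    Precision      = mean_i |L_i ∩ L*_i| / |L*_i|
    Coverage       = mean_i |L_i ∩ L*_i| / |L_i|
    Accuracy       = mean_i |L_i ∩ L*_i| / |L_i ∪ L*_i|
    Absolute true  = mean_i 1[L*_i == L_i]
    Absolute false = mean_i (|L_i ∪ L*_i| - |L_i ∩ L*_i|) / M

The first four are higher-better in [0,1]; Absolute false is the per-sample
Hamming-style error (lower better).  A sample with an empty predicted set
contributes 0 to Precision (1 when the true set is also empty, which cannot
occur on curated data).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport",
    "evaluate_multilabel",
    "per_class_coverage",
    "subsample_evaluate",
    "compare_methods_ttest",
    "significance_stars",
    "format_report_table",
]


@dataclass(frozen=True)
class MetricReport:
    """The five multi-label scores for one prediction set."""

    precision: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float

    FIELDS = ("precision", "coverage", "accuracy", "absolute_true", "absolute_false")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])

    @classmethod
    def from_array(cls, arr) -> "MetricReport":
        return cls(*(float(v) for v in arr))


def _as_binary(mat, name: str) -> np.ndarray:
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise ValueError(f"{name} must be a 2-D binary matrix")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return mat.astype(np.float64)


def evaluate_multilabel(truth: np.ndarray, predicted: np.ndarray) -> MetricReport:
    """Score an N x M binary prediction matrix against the truth matrix."""
    truth = _as_binary(truth, "truth")
    predicted = _as_binary(predicted, "predicted")
    if truth.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.shape} vs predicted {predicted.shape}"
        )
    n, m = truth.shape
    if n < 1 or m < 1:
        raise ValueError("need at least one sample and one label")
    inter = (truth * predicted).sum(axis=1)
    union = np.maximum(truth, predicted).sum(axis=1)
    n_true = truth.sum(axis=1)
    n_pred = predicted.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(n_pred > 0, inter / np.where(n_pred > 0, n_pred, 1), 0.0)
        prec = np.where((n_pred == 0) & (n_true == 0), 1.0, prec)
        cov = np.where(n_true > 0, inter / np.where(n_true > 0, n_true, 1), 1.0)
        acc = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    abs_true = (np.abs(truth - predicted).sum(axis=1) == 0).astype(np.float64)
    abs_false = (union - inter) / m
    return MetricReport(
        precision=float(prec.mean()),
        coverage=float(cov.mean()),
        accuracy=float(acc.mean()),
        absolute_true=float(abs_true.mean()),
        absolute_false=float(abs_false.mean()),
    )


def per_class_coverage(truth: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Coverage restricted to each class: among samples truly carrying class
    j, the fraction predicted to carry it (the per-class recall).  NaN for
    classes absent from the truth."""
    truth = _as_binary(truth, "truth")
    predicted = _as_binary(predicted, "predicted")
    pos = truth.sum(axis=0)
    hit = (truth * predicted).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pos > 0, hit / np.where(pos > 0, pos, 1), np.nan)


def subsample_evaluate(
    probs: np.ndarray,
    truth: np.ndarray,
    fraction: float = 0.8,
    reps: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[MetricReport, list[MetricReport]]:
    """Evaluate on repeated random subsets of the test predictions.

    Draws `reps` independent subsets of ``floor(fraction * N)`` samples
    (without replacement within a subset), scores each, and reports the
    arithmetic mean across repetitions alongside the per-rep reports.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    probs = np.asarray(probs, dtype=np.float64)
    truth = _as_binary(truth, "truth")
    n = probs.shape[0]
    size = int(np.floor(fraction * n))
    if size == 0:
        raise ValueError("subset size 0: fraction too small for this test set")
    predicted = (probs >= threshold).astype(np.float64)
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(reps):
        idx = rng.choice(n, size=size, replace=False)
        reports.append(evaluate_multilabel(truth[idx], predicted[idx]))
    mean = MetricReport.from_array(np.mean([r.as_array() for r in reports], axis=0))
    return mean, reports


def compare_methods_ttest(
    scores_a, scores_b, paired: bool = True
) -> tuple[float, float]:
    """Two-sided t-test between two methods' score samples.

    Paired by default, matching evaluation on shared test subsets.  A paired
    comparison with zero variance in the differences (e.g. a constant shift)
    has no defined t statistic and raises.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per method")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal sample sizes")
        if np.array_equal(a, b):
            return 0.0, 1.0
        if np.std(a - b, ddof=1) == 0:
            raise ValueError("degenerate comparison: paired differences have zero variance")
        res = stats.ttest_rel(a, b)
    else:
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                return 0.0, 1.0
            raise ValueError("degenerate comparison: both samples have zero variance")
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    for cut, mark in ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < cut:
            return mark
    return "ns"


def format_report_table(rows: dict[str, MetricReport]) -> str:
    """Aligned text table (Precision/Coverage/Accuracy higher-better first,
    Absolute false last, lower-better)."""
    headers = ["Model", "Precision ↑", "Coverage ↑", "Accuracy ↑", "Absolute true ↑", "Absolute false ↓"]
    lines = ["\t".join(headers)]
    for name, rep in rows.items():
        vals = [f"{v:.3f}" for v in rep.as_array()]
        lines.append("\t".join([name] + vals))
    return "\n".join(lines)
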