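"""Evaluation: confusion matrices, one-vs-rest metrics, ROC/AUC, bootstrap CIs.

Per-class statistics follow the standard one-vs-rest definitions on a
multiclass confusion matrix (rows = actual class, columns = predicted):

    precision   = Tp / (Tp + Fp)
    sensitivity = Tp / (Tp + Fn)          (= recall)
    accuracy    = (Tp + Tn) / (Tp + Fp + Tn + Fn)
    specificity = Tn / (Fp + Tn)
    F1          = 2 * precision * recall / (precision + recall)

all reported in percent. Two averaging conventions are exposed because the
miner-comparison tables mix them: *micro* pools the one-vs-rest counts (so
multiclass micro precision = micro sensitivity = total correct / total) and
*macro* takes the unweighted mean of per-class values. Ratios with a zero
denominator are reported as absent (None), never as zero.

ROC curves use the retrieval vote score: a query is called positive for a
class when its vote percentage reaches the threshold, swept 0..100 in 5%
increments (21 points); AUC is the trapezoid over the resulting curve with
the implicit (0, 0) endpoint. Confidence intervals come from a seeded
nonparametric bootstrap (1000 query resamples, 2.5/97.5 percentiles).

No-match queries (rejected by the cosine filter) are tallied in a separate
``rejected`` column and excluded from the per-class arithmetic by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import apply_gaussian_noise
from .retrieval import EmbeddingIndex, RetrievalResult, predict_batch

__all__ = [
    "ConfusionMatrix", "MetricReport", "RocCurve",
    "confusion_from_results", "confusion_from_counts", "per_class_metrics",
    "average_metrics", "roc_auc", "bootstrap_ci", "accuracy_statistic",
    "noise_robustness_curve", "project_embeddings_2d", "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up rounding, the convention of the printed result tables."""
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass
class ConfusionMatrix:
    counts: np.ndarray              # (n, n) int, rows actual, cols predicted
    classes: list[str]
    rejected: np.ndarray = None     # per-actual-class no-match tallies

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=np.int64)
        self.rejected = np.asarray(self.rejected, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.classes, columns=self.classes)
        if self.rejected.any():
            df["rejected"] = self.rejected
        return df


@dataclass
class MetricReport:
    classes: list[str]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    per_class: dict[str, dict[str, float | None]]
    micro: dict[str, float | None]
    macro: dict[str, float | None]

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        rows = {}
        for c in self.classes:
            rows[c] = {k: (None if v is None else round_half_up(v, decimals))
                       for k, v in self.per_class[c].items()}
        rows["micro_average"] = {k: (None if v is None
                                     else round_half_up(v, decimals))
                                 for k, v in self.micro.items()}
        rows["macro_average"] = {k: (None if v is None
                                     else round_half_up(v, decimals))
                                 for k, v in self.macro.items()}
        return pd.DataFrame(rows).T


# ----------------------------------------------------------- confusion matrix

def confusion_from_results(results: list[RetrievalResult],
                           truth: dict[str, str],
                           classes: list[str]) -> ConfusionMatrix:
    """Tally predictions against truth labels.

    `truth` maps query_id to the actual class code. No-match results land in
    the rejected column of their actual class.
    """
    idx = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    counts = np.zeros((n, n), dtype=np.int64)
    rejected = np.zeros(n, dtype=np.int64)
    for r in results:
        actual = truth[r.query_id]
        if actual not in idx:
            raise ValueError(f"truth label {actual!r} not in class vocabulary")
        if not r.matched or r.predicted is None:
            rejected[idx[actual]] += 1
        elif r.predicted not in idx:
            raise ValueError(f"prediction {r.predicted!r} not in vocabulary")
        else:
            counts[idx[actual], idx[r.predicted]] += 1
    return ConfusionMatrix(counts=counts, classes=list(classes),
                           rejected=rejected)


def confusion_from_counts(diagonal: list[int], classes: list[str],
                          errors: list[tuple[str, str, int]] = ()) -> ConfusionMatrix:
    """Build a matrix from per-class test sizes plus explicit errors.

    `diagonal` gives each class's test-set size; each (actual, predicted, k)
    error moves k queries off the diagonal.
    """
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.diag(np.asarray(diagonal, dtype=np.int64)).copy()
    for actual, predicted, k in errors:
        counts[idx[actual], idx[actual]] -= k
        counts[idx[actual], idx[predicted]] += k
    if np.any(counts < 0):
        raise ValueError("errors exceed a class's test size")
    return ConfusionMatrix(counts=counts, classes=list(classes))


# -------------------------------------------------------------------- metrics

def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def per_class_metrics(cm: ConfusionMatrix) -> MetricReport:
    """One-vs-rest Tp/Tn/Fp/Fn and the five statistics, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    total = cm.total
    tp = np.diag(counts).astype(np.int64)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp
    per_class = {}
    for i, c in enumerate(cm.classes):
        precision = _ratio(tp[i], tp[i] + fp[i])
        sensitivity = _ratio(tp[i], tp[i] + fn[i])
        specificity = _ratio(tn[i], fp[i] + tn[i])
        accuracy = _ratio(tp[i] + tn[i], total)
        if precision is None or sensitivity is None \
                or (precision + sensitivity) == 0:
            f1 = None
        else:
            f1 = 2 * precision * sensitivity / (precision + sensitivity)
        per_class[c] = {"precision": precision, "sensitivity": sensitivity,
                        "specificity": specificity, "accuracy": accuracy,
                        "f1": f1}
    report = MetricReport(classes=list(cm.classes), tp=tp, tn=tn, fp=fp, fn=fn,
                          per_class=per_class, micro={}, macro={})
    report.micro = average_metrics(report, "micro")
    report.macro = average_metrics(report, "macro")
    return report


def average_metrics(report: MetricReport, mode: str) -> dict[str, float | None]:
    """Pooled-count (micro) or unweighted per-class mean (macro) averages."""
    if mode == "micro":
        tp, tn = report.tp.sum(), report.tn.sum()
        fp, fn = report.fp.sum(), report.fn.sum()
        precision = _ratio(tp, tp + fp)
        sensitivity = _ratio(tp, tp + fn)
        out = {
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": _ratio(tn, fp + tn),
            "accuracy": _ratio(tp + tn, tp + fp + tn + fn),
        }
        if precision is None or sensitivity is None \
                or (precision + sensitivity) == 0:
            out["f1"] = None
        else:
            out["f1"] = 2 * precision * sensitivity / (precision + sensitivity)
        return out
    if mode == "macro":
        out = {}
        for key in ("precision", "sensitivity", "specificity", "accuracy", "f1"):
            vals = [report.per_class[c][key] for c in report.classes
                    if report.per_class[c][key] is not None]
            out[key] = float(np.mean(vals)) if vals else None
        return out
    raise ValueError(f"unknown averaging mode {mode!r}")


# ------------------------------------------------------------------------ ROC

@dataclass
class RocCurve:
    thresholds: np.ndarray                        # 0, 5, ..., 100
    per_class: dict[str, np.ndarray]              # (21, 2): (fpr, tpr) rows
    macro_points: np.ndarray                      # (21, 2) averaged curve
    auc: float
    per_class_auc: dict[str, float]
    ci: tuple[float, float] | None = None


def _auc_from_points(points: np.ndarray) -> float:
    """Trapezoid AUC over (fpr, tpr) points plus the implicit (0, 0)."""
    pts = np.vstack([points, [0.0, 0.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(results: list[RetrievalResult], truth: dict[str, str],
            classes: list[str], step: float = 5.0) -> RocCurve:
    """One-vs-rest ROC from vote scores at 5%-increment thresholds.

    A query counts as called-positive for class c at threshold t when its
    vote score for c is >= t. Classes with no positive queries are skipped
    with a warning. The macro curve averages tpr and fpr across classes at
    each threshold; `auc` is the trapezoid area under the macro curve.
    """
    thresholds = np.arange(0.0, 100.0 + step, step)
    scores = np.array([[r.class_scores.get(c, 0.0) for c in classes]
                       for r in results])
    actual = np.array([truth[r.query_id] for r in results])
    per_class: dict[str, np.ndarray] = {}
    per_class_auc: dict[str, float] = {}
    for j, c in enumerate(classes):
        pos = actual == c
        if not pos.any():
            warnings.warn(f"class {c!r} has no positive queries; skipped",
                          stacklevel=2)
            continue
        pts = np.empty((len(thresholds), 2))
        for ti, t in enumerate(thresholds):
            called = scores[:, j] >= t
            tpr = called[pos].mean()
            fpr = called[~pos].mean() if (~pos).any() else 0.0
            pts[ti] = (fpr, tpr)
        per_class[c] = pts
        per_class_auc[c] = _auc_from_points(pts)
    if not per_class:
        raise ValueError("no class had positive queries")
    macro_points = np.mean(np.stack(list(per_class.values())), axis=0)
    return RocCurve(thresholds=thresholds, per_class=per_class,
                    macro_points=macro_points,
                    auc=_auc_from_points(macro_points),
                    per_class_auc=per_class_auc)


# ------------------------------------------------------------------ bootstrap

def bootstrap_ci(results: list, truth: dict[str, str], statistic,
                 n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap over query resampling.

    `statistic(results_subset, truth)` maps a resampled result list to a
    number; the 2.5 and 97.5 percentiles over `n_boot` seeded resamples form
    the 95% interval.
    """
    if len(results) < 2:
        raise ValueError("bootstrap requires at least 2 queries")
    rng = np.random.default_rng(seed)
    n = len(results)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        stats[b] = statistic([results[i] for i in take], truth)
    return (float(np.percentile(stats, 2.5)),
            float(np.percentile(stats, 97.5)))


def accuracy_statistic(results: list[RetrievalResult],
                       truth: dict[str, str]) -> float:
    """Fraction of matched queries predicted correctly (percent)."""
    if not results:
        return 0.0
    correct = sum(1 for r in results
                  if r.matched and r.predicted == truth[r.query_id])
    return 100.0 * correct / len(results)


# ----------------------------------------------------------------- robustness

def noise_robustness_curve(model, index: EmbeddingIndex, images,
                           truth: dict[str, str], classes: list[str],
                           sigmas, k: int = 20, threshold: float = 0.5,
                           seed: int = 0, query_ids=None) -> list[dict]:
    """AUC per ascending Gaussian-noise level applied to the clean queries."""
    sigmas = list(sigmas)
    if sorted(sigmas) != sigmas:
        raise ValueError("sigmas must be ascending")
    if query_ids is None:
        query_ids = [f"q{i}" for i in range(len(images))]
    out = []
    for si, sigma in enumerate(sigmas):
        noisy = [apply_gaussian_noise(im, sigma, seed=int(
            np.random.SeedSequence([seed, si, i]).generate_state(1)[0]
            % (2 ** 31)))
            for i, im in enumerate(images)]
        results = predict_batch(model, index, np.stack(noisy),
                                query_ids=query_ids, k=k, threshold=threshold)
        curve = roc_auc(results, truth, classes)
        out.append({"sigma": float(sigma), "auc": curve.auc,
                    "results": results})
    return out


# ----------------------------------------------------------------- projection

def project_embeddings_2d(index: EmbeddingIndex, seed: int = 0) -> np.ndarray:
    """2-D layout of the gallery by uniform manifold approximation (UMAP)."""
    if len(index) < 10:
        raise ValueError("need at least 10 gallery rows to project")
    import umap  # deferred: numba compilation is expensive at import time

    reducer = umap.UMAP(n_components=2, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(index.embeddings),
                          dtype=np.float64)
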