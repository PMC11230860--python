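"""Classification metrics and the repeated balanced-subsampling validation.

The metric panel is the standard one for virtual-screening classifiers:
accuracy, precision, sensitivity (recall), specificity, F1 (harmonic mean
of precision and sensitivity), AUROC (Mann-Whitney formulation: the
probability a random positive outscores a random negative, ties counting
one half) and AUPRC (step-wise, non-interpolated summation — the
average-precision convention).

The external screen is heavily imbalanced (154 positives vs 5744
negatives by default), so the validation protocol repeatedly draws a
negative subset matching the positive count, evaluates the balanced set at
each threshold, and averages over repetitions.  Because text-book practice
is ambiguous about the aggregation order, the report carries both the mean
of per-repetition metrics and the metrics of the mean confusion counts.

Undefined metrics (zero denominators) are reported as ``None`` — never
coerced to 0, never raised — and excluded from averages with an explicit
exclusion count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .records import LabeledDataset

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


@dataclass
class ConfusionCounts:
    """TP/FN/TN/FP; fractional values arise as averages over repetitions."""

    tp: float
    fn: float
    tn: float
    fp: float

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError(f"counts must be >= 0: {self}")

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricSet:
    """The derived metric panel; ``None`` marks an undefined (flagged) metric."""

    accuracy: float | None = None
    precision: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    auroc: float | None = None
    auprc: float | None = None
    undefined: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, float | None]:
        return {
            k: getattr(self, k)
            for k in (*METRIC_NAMES, "auroc", "auprc")
        }


def confusion_counts(labels, predictions) -> ConfusionCounts:
    """Tally TP/FN/TN/FP from binary labels and binary predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size < 1:
        raise ValueError("empty inputs")
    tp = int(np.sum((y == 1) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Derive the five count-based metrics; zero denominators yield ``None``.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP),
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    F1 = 2·precision·sensitivity/(precision+sensitivity).
    """
    if not c.total > 0:
        raise ValueError("all counts are zero; no metrics derivable")
    out = MetricSet()
    out.accuracy = (c.tp + c.tn) / c.total
    out.precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    out.sensitivity = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    out.specificity = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else None
    if (
        out.precision is not None and out.sensitivity is not None
        and out.precision + out.sensitivity > 0
    ):
        out.f1 = (
            2 * out.precision * out.sensitivity / (out.precision + out.sensitivity)
        )
    out.undefined = {k for k in METRIC_NAMES if getattr(out, k) is None}
    return out


def auroc(scores, labels) -> float | None:
    """Area under the ROC curve; ``None`` (undefined) if a class is absent.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, with ties counting 1/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, s))


def auprc(scores, labels) -> float | None:
    """Area under the precision-recall curve by step-wise summation
    (average precision); ``None`` if there are no positives."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if np.sum(y == 1) == 0:
        return None
    return float(average_precision_score(y, s))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> MetricSet:
    """Full panel from continuous scores: counts at the threshold
    (boundary inclusive) plus AUROC/AUPRC from the raw scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    preds = (s >= threshold).astype(int)
    out = metrics_from_counts(confusion_counts(y, preds))
    out.auroc = auroc(s, y)
    out.auprc = auprc(s, y)
    if out.auroc is None:
        out.undefined.add("auroc")
    if out.auprc is None:
        out.undefined.add("auprc")
    return out


def evaluate_model_on_test(results, test: LabeledDataset, threshold: float = 0.5) -> MetricSet:
    """Score a held-out set with a fitted model and derive the panel."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    scores = results.predict(test.records)
    return evaluate_scores(scores, test.labels, threshold=threshold)


# ----- repeated balanced subsampling ---------------------------------------

@dataclass
class ResamplingReport:
    """Averaged counts and metrics over repeated balanced subsampling.

    For every threshold: ``mean_counts`` (averages of TP/FN/TN/FP over
    repetitions; TP+FN always equals the positive-set size and TN+FP the
    per-repetition negative sample size), ``counts_metrics`` (metric panel
    of the averaged counts), ``mean_metrics`` (averages of per-repetition
    metrics, with ``exclusions`` counting repetitions where a metric was
    undefined), and a ``convergence`` trace (running average of FP).
    """

    thresholds: list[float]
    n_reps: int
    n_sample: int
    n_pos: int
    seed: int
    mean_counts: dict[float, ConfusionCounts]
    counts_metrics: dict[float, MetricSet]
    mean_metrics: dict[float, MetricSet]
    exclusions: dict[float, dict[str, int]]
    convergence: dict[float, np.ndarray]

    def to_frame(self, aggregation: str = "counts") -> pd.DataFrame:
        """One row per threshold, shaped like the familiar report table:
        threshold, TP, FN, TN, FP, accuracy, precision, sensitivity,
        specificity, F1.  ``aggregation`` picks the metric variant:
        "counts" (metrics of mean counts) or "metrics" (mean of per-rep
        metrics)."""
        source = self.counts_metrics if aggregation == "counts" else self.mean_metrics
        rows = []
        for th in self.thresholds:
            c, m = self.mean_counts[th], source[th]
            rows.append({
                "threshold": th, "TP": c.tp, "FN": c.fn, "TN": c.tn, "FP": c.fp,
                "accuracy": m.accuracy, "precision": m.precision,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "F1": m.f1,
            })
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_reps": self.n_reps,
            "n_sample": self.n_sample,
            "n_pos": self.n_pos,
            "seed": self.seed,
            "thresholds": self.thresholds,
            "exclusions": {str(k): v for k, v in self.exclusions.items()},
            "convergence_fp": {
                str(k): np.asarray(v).tolist() for k, v in self.convergence.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def balanced_resampling_validation(
    score_table: pd.DataFrame,
    thresholds: list[float],
    n_reps: int = 1000,
    n_sample: int | None = None,
    seed: int = 0,
    score_column: str = "ensemble",
    label_column: str = "label",
) -> ResamplingReport:
    """Validate a scored, imbalanced library by repeated balanced subsampling.

    Each repetition draws ``n_sample`` negatives without replacement
    (default: as many as there are positives), pools them with *all*
    positives, and binarizes the scores at every threshold (boundary
    inclusive).  Counts and metrics are averaged over repetitions;
    repetitions where a metric is undefined are excluded from its average
    and counted.  Deterministic for a fixed seed.

    Parameters
    ----------
    score_table : DataFrame
        Must hold one score column and one binary truth column (the shape
        :meth:`EnsembleScreener.screen` produces).
    """
    scores = score_table[score_column].to_numpy(dtype=float)
    labels = score_table[label_column].to_numpy()
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    if n_pos < 1:
        raise ValueError("at least one positive is required")
    if n_sample is None:
        n_sample = n_pos
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    if n_sample > n_neg:
        raise ValueError(f"n_sample={n_sample} exceeds the negative pool ({n_neg})")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rng = np.random.default_rng(seed)
    # (n_reps, n_sample) negative indices, without replacement within a rep
    samples = np.stack([
        rng.choice(n_neg, size=n_sample, replace=False) for _ in range(n_reps)
    ])

    mean_counts: dict[float, ConfusionCounts] = {}
    counts_metrics: dict[float, MetricSet] = {}
    mean_metrics: dict[float, MetricSet] = {}
    exclusions: dict[float, dict[str, int]] = {}
    convergence: dict[float, np.ndarray] = {}

    for th in thresholds:
        tp = float(np.sum(pos_scores >= th))   # positives are reused in full
        fn = float(n_pos - tp)
        neg_positive_pred = neg_scores >= th
        fp_reps = neg_positive_pred[samples].sum(axis=1).astype(float)
        tn_reps = n_sample - fp_reps

        mean_counts[th] = ConfusionCounts(
            tp=tp, fn=fn, tn=float(tn_reps.mean()), fp=float(fp_reps.mean())
        )
        counts_metrics[th] = metrics_from_counts(mean_counts[th])

        per_rep = {name: [] for name in METRIC_NAMES}
        excl = {name: 0 for name in METRIC_NAMES}
        for fp_r, tn_r in zip(fp_reps, tn_reps):
            ms = metrics_from_counts(ConfusionCounts(tp=tp, fn=fn, tn=tn_r, fp=fp_r))
            for name in METRIC_NAMES:
                v = getattr(ms, name)
                if v is None:
                    excl[name] += 1
                else:
                    per_rep[name].append(v)
        agg = MetricSet()
        for name in METRIC_NAMES:
            vals = per_rep[name]
            setattr(agg, name, float(np.mean(vals)) if vals else None)
        agg.undefined = {k for k in METRIC_NAMES if getattr(agg, k) is None}
        mean_metrics[th] = agg
        exclusions[th] = excl
        convergence[th] = np.cumsum(fp_reps) / np.arange(1, n_reps + 1)

    return ResamplingReport(
        thresholds=list(thresholds),
        n_reps=n_reps,
        n_sample=n_sample,
        n_pos=n_pos,
        seed=seed,
        mean_counts=mean_counts,
        counts_metrics=counts_metrics,
        mean_metrics=mean_metrics,
        exclusions=exclusions,
        convergence=convergence,
    )
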