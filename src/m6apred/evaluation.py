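"""Confusion-based metrics, per-transcript averaging, imbalance benchmarks.

Headline metrics are precision, recall, F1 and the Matthews correlation
coefficient — the metrics of choice for heavily imbalanced site
prediction, where ROC-style summaries are misleadingly optimistic.
Degenerate denominators (no predicted positives, no true positives, a
zero MCC marginal) yield 0 by convention; per-transcript evaluation makes
this unavoidable since individual transcripts can receive no predicted
positives at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from m6apred.io import SampleTable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "mcc": self.mcc}


def metrics_from_counts(counts: ConfusionCounts) -> MetricSet:
    """precision, recall, F1 and MCC from a confusion quadruple.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); any zero
    marginal gives MCC 0 by convention, and F1 is 0 when precision and
    recall are both 0.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MetricSet(precision=precision, recall=recall, f1=f1, mcc=mcc)


def evaluate_predictions(
    labels: Sequence[int], predicted: Sequence[int]
) -> tuple[ConfusionCounts, MetricSet]:
    """Tally the confusion counts of hard predictions and derive metrics."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs {predicted.shape} predictions")
    counts = ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predicted == 1))),
        fp=int(np.sum((labels == 0) & (predicted == 1))),
        fn=int(np.sum((labels == 1) & (predicted == 0))),
        tn=int(np.sum((labels == 0) & (predicted == 0))),
    )
    return counts, metrics_from_counts(counts)


def per_transcript_average(
    samples: SampleTable, predicted: Sequence[int]
) -> tuple[MetricSet, pd.DataFrame]:
    """Metrics per transcript, then the unweighted mean across transcripts.

    Mirrors evaluation in practical use, where the unit of prediction is a
    single transcript whose own imbalance ratio is unknown.  Returns the
    mean MetricSet and the per-transcript table.
    """
    predicted = np.asarray(predicted)
    if len(predicted) != len(samples):
        raise ValueError("predictions and samples differ in length")
    df = samples.df.assign(predicted=predicted)
    rows = []
    for tx, group in df.groupby("transcript_id", sort=True):
        _, ms = evaluate_predictions(group["label"].to_numpy(),
                                     group["predicted"].to_numpy())
        rows.append({"transcript_id": tx, "n": len(group), **ms.as_dict()})
    per_tx = pd.DataFrame(rows)
    mean = MetricSet(*(float(per_tx[c].mean())
                       for c in ("precision", "recall", "f1", "mcc")))
    return mean, per_tx


def build_imbalance_subsets(
    samples: SampleTable,
    ratios: Iterable[int] = range(1, 10),
    seed: int = 0,
) -> dict[int, SampleTable]:
    """One test subset per negative:positive ratio k, all positives kept.

    Negatives are drawn uniformly without replacement (seeded) to k times
    the positive count.  Raises if the corpus cannot support the largest
    requested ratio, naming the maximum feasible one.
    """
    ratios = list(ratios)
    labels = samples.labels
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_pos = len(pos_idx)
    if n_pos == 0:
        raise ValueError("no positive samples")
    feasible = len(neg_idx) // n_pos
    if max(ratios) > feasible:
        raise ValueError(
            f"not enough negatives for ratio {max(ratios)}:1; "
            f"maximum feasible ratio is {feasible}:1")
    rng = np.random.default_rng(seed)
    subsets = {}
    for k in ratios:
        drawn = rng.choice(neg_idx, size=k * n_pos, replace=False)
        idx = np.sort(np.concatenate([pos_idx, drawn]))
        subsets[k] = samples.subset(idx)
    return subsets


def robustness_curve(
    results,
    subsets: dict[int, SampleTable],
    snp_table,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Metrics of a fitted classifier on each imbalance subset.

    ``results`` is an :class:`~m6apred.model.M6AClassifierResults` (or any
    object with ``predict_labels(samples, snp_table, threshold)``).
    Returns a frame with one row per ratio k, ready for plotting F1 / MCC
    against the imbalance level.
    """
    rows = []
    for k in sorted(subsets):
        subset = subsets[k]
        pred = results.predict_labels(subset, snp_table, threshold=threshold)
        _, ms = evaluate_predictions(subset.labels, pred)
        rows.append({"ratio": k, "n": len(subset), **ms.as_dict()})
    return pd.DataFrame(rows)


def plot_robustness(curve: pd.DataFrame, path=None):
    """F1 and MCC against the imbalance ratio k; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve["ratio"], curve["f1"], marker="o", label="F1")
    ax.plot(curve["ratio"], curve["mcc"], marker="s", label="MCC")
    ax.set_xlabel("imbalance ratio k (negatives : positives)")
    ax.set_ylabel("metric")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
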