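"""Weighted multiclass metrics, top-N accuracy, and the split harness.

Per-class precision/recall are one-vs-rest; class weights are the true
class proportions (normalised so they sum to 1), the weighted F1 is the
harmonic mean of the weighted precision and recall, and accuracy is
correct / total.  A literal variant that additionally divides the weighted
sums by the number of classes is available behind ``divide_by_l`` for
comparison; the default weighted form is the only one bounded by [0, 1]
for all inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .corpus import EMRecord
from .embedding import TrainConfig, train_model
from .kg import build_kg
from .recommender import Recommendation, RecordNotDiagnosableError, recommend

__all__ = [
    "ClassCounts",
    "MetricsReport",
    "per_class_counts",
    "weighted_report",
    "top_n_accuracy",
    "evaluate_split",
]

#: Sentinel prediction label for records the model could not score at all.
NO_PREDICTION = "__no_prediction__"


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class MetricsReport:
    """Per-class counts plus weighted aggregate metrics."""

    counts: dict[Hashable, ClassCounts]
    precision: dict[Hashable, float]
    recall: dict[Hashable, float]
    weights: dict[Hashable, float]
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float
    top_n: dict[int, float] = field(default_factory=dict)
    n_records: int = 0

    def as_dict(self) -> dict:
        return {
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "accuracy": self.accuracy,
            "top_n": {str(n): v for n, v in self.top_n.items()},
            "n_records": self.n_records,
        }


def per_class_counts(
    predictions: Sequence[Hashable], truths: Sequence[Hashable]
) -> dict[Hashable, ClassCounts]:
    """One-vs-rest TP/FP/FN for every class in truths or predictions."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    if not truths:
        raise ValueError("need at least one labelled item")
    counts: dict[Hashable, ClassCounts] = {}
    for cls in list(dict.fromkeys(truths)) + list(dict.fromkeys(predictions)):
        counts.setdefault(cls, ClassCounts())
    for pred, truth in zip(predictions, truths):
        if pred == truth:
            counts[truth].tp += 1
        else:
            counts[truth].fn += 1
            counts[pred].fp += 1
    return counts


def weighted_report(
    counts: Mapping[Hashable, ClassCounts],
    truths: Sequence[Hashable],
    top_n_hits: Mapping[int, float] | None = None,
    *,
    divide_by_l: bool = False,
) -> MetricsReport:
    """Aggregate per-class counts into weighted precision/recall/F1.

    Weights are the true class-size proportions; classes never seen in the
    truths get weight 0.  A never-predicted class has precision 0 by
    convention.  ``divide_by_l`` switches to the variant that divides the
    weighted sums by the class count L.
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    n_truth: dict[Hashable, int] = {}
    for truth in truths:
        n_truth[truth] = n_truth.get(truth, 0) + 1
    total = len(truths)

    precision: dict[Hashable, float] = {}
    recall: dict[Hashable, float] = {}
    weights: dict[Hashable, float] = {}
    for cls, c in counts.items():
        precision[cls] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
        recall[cls] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
        weights[cls] = n_truth.get(cls, 0) / total

    wp = sum(precision[c] * weights[c] for c in counts)
    wr = sum(recall[c] * weights[c] for c in counts)
    if divide_by_l:
        n_classes = len([c for c in counts if weights[c] > 0]) or 1
        wp /= n_classes
        wr /= n_classes
    f1 = 2 * wp * wr / (wp + wr) if (wp + wr) else 0.0
    correct = sum(c.tp for c in counts.values())
    return MetricsReport(
        counts=dict(counts),
        precision=precision,
        recall=recall,
        weights=weights,
        weighted_precision=wp,
        weighted_recall=wr,
        weighted_f1=f1,
        accuracy=correct / total,
        top_n=dict(top_n_hits or {}),
        n_records=total,
    )


def top_n_accuracy(
    recommendations: Sequence[Sequence[Hashable]],
    truths: Sequence[Hashable],
    n: int,
) -> float:
    """Fraction of records whose truth is within the first ``n`` items.

    Each recommendation is an ordered label list; an empty list counts as
    wrong for every ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(recommendations) != len(truths):
        raise ValueError("recommendations and truths must have equal length")
    if not truths:
        return 0.0
    hits = sum(1 for rec, truth in zip(recommendations, truths) if truth in list(rec)[:n])
    return hits / len(truths)


def evaluate_split(
    records: Sequence[EMRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    *,
    k: int = 10,
    top_n_list: Sequence[int] = (1, 3, 5),
    divide_by_l: bool = False,
) -> MetricsReport:
    """Seeded shuffle-split harness: build KG on train, recommend on test.

    The graph and embeddings see only the training partition.  Test records
    that cannot be dismantled (all tokens out of vocabulary) count as wrong
    for every metric.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    if n_train == 0 or n_train == len(records):
        raise ValueError("split leaves an empty train or test partition")
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]

    kg = build_kg(train)
    cfg = train_config or TrainConfig()
    emb = train_model(kg, cfg)

    truths: list[str] = []
    preds: list[str] = []
    rec_labels: list[list[str]] = []
    max_n = max(top_n_list)
    for rec in test:
        truths.append(rec.syndrome or NO_PREDICTION)
        try:
            result: Recommendation = recommend(rec, kg, emb, k=k, top_n=max_n)
            labels = [kg.entities[sid].name for sid in result.syndrome_ids()]
        except RecordNotDiagnosableError:
            labels = []
        rec_labels.append(labels)
        preds.append(labels[0] if labels else NO_PREDICTION)

    counts = per_class_counts(preds, truths)
    hits = {n: top_n_accuracy(rec_labels, truths, n) for n in top_n_list}
    return weighted_report(counts, truths, hits, divide_by_l=divide_by_l)
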