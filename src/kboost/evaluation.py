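"""Ranking metrics against a directed gold-standard network.

AUROC is the area under recall vs false-positive rate with trapezoidal tie
handling (equivalently the Mann-Whitney statistic); AUPR is the step-sum
area under precision vs recall over distinct score thresholds descending
(ties grouped, no interpolation between steps).  ``best_f1_threshold``
reproduces threshold selection by the F1 score with the keep-if-strictly-
greater rule.

A gold standard may be partial (DREAM-5 style): metrics are computed only
over labeled pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import InvalidParameterError, UndefinedMetricError

__all__ = ["GoldStandard", "auroc", "aupr", "best_f1_threshold"]

Pair = tuple[Hashable, Hashable]


@dataclass(frozen=True)
class GoldStandard:
    """Labeled (TF, target) pairs: 1 = true regulatory edge, 0 = non-edge.

    The key set is the scored universe; pairs not present are unlabeled and
    ignored by every metric.  Self-loops are rejected.
    """

    labels: Mapping[Pair, int]

    def __post_init__(self) -> None:
        labels = dict(self.labels)
        object.__setattr__(self, "labels", labels)
        for (tf, target), lab in labels.items():
            if tf == target:
                raise InvalidParameterError(f"self-loop in gold standard: {tf!r}")
            if lab not in (0, 1):
                raise InvalidParameterError(
                    f"gold label for ({tf!r}, {target!r}) must be 0 or 1, got {lab}"
                )

    @property
    def universe(self) -> set[Pair]:
        return set(self.labels)

    @property
    def positives(self) -> set[Pair]:
        return {pair for pair, lab in self.labels.items() if lab == 1}

    @property
    def n_positive(self) -> int:
        return sum(self.labels.values())

    @classmethod
    def from_positive_edges(
        cls, edges: set[Pair], tf_keys: list, target_keys: list
    ) -> "GoldStandard":
        """Complete gold standard over all TF x target pairs (no self-loops):
        listed edges are 1, everything else 0."""
        labels = {
            (tf, tgt): int((tf, tgt) in edges)
            for tf in tf_keys
            for tgt in target_keys
            if tf != tgt
        }
        return cls(labels)


def _aligned(scores: Mapping[Pair, float], gold: GoldStandard):
    pairs = sorted(gold.labels, key=repr)
    missing = [p for p in pairs if p not in scores]
    if missing:
        raise InvalidParameterError(
            f"{len(missing)} gold pairs lack a score, e.g. {missing[0]!r}"
        )
    y_true = np.array([gold.labels[p] for p in pairs])
    y_score = np.array([float(scores[p]) for p in pairs])
    return y_true, y_score


def auroc(scores: Mapping[Pair, float], gold: GoldStandard) -> float:
    """Area under the ROC curve of the scores over the labeled universe."""
    y_true, y_score = _aligned(scores, gold)
    n_pos = int(y_true.sum())
    if n_pos == 0 or n_pos == y_true.size:
        raise UndefinedMetricError(
            "AUROC needs at least one positive and one negative pair"
        )
    return float(roc_auc_score(y_true, y_score))


def aupr(scores: Mapping[Pair, float], gold: GoldStandard) -> float:
    """Step-sum area under the precision-recall curve (average precision)."""
    y_true, y_score = _aligned(scores, gold)
    if y_true.sum() == 0:
        raise UndefinedMetricError("AUPR needs at least one positive pair")
    return float(average_precision_score(y_true, y_score))


def best_f1_threshold(
    scores: Mapping[Pair, float], gold: GoldStandard
) -> tuple[float, float]:
    """Threshold maximizing F1 under the strictly-greater keep rule.

    Candidate thresholds are the distinct score values plus one value below
    the minimum (which keeps every pair).  An edge is predicted when its
    score is strictly greater than the threshold.  Ties in F1 resolve to the
    lowest threshold.  Returns ``(threshold, f1)``.
    """
    y_true, y_score = _aligned(scores, gold)
    n_pos = int(y_true.sum())
    if n_pos == 0:
        raise UndefinedMetricError("F1 needs at least one positive pair")
    distinct = np.unique(y_score)
    candidates = np.concatenate([[distinct[0] - 1.0], distinct])
    best_thr, best_f1 = candidates[0], -1.0
    for thr in candidates:
        kept = y_score > thr
        tp = int(np.sum(y_true[kept]))
        if tp == 0:
            f1 = 0.0
        else:
            precision = tp / int(kept.sum())
            recall = tp / n_pos
            f1 = 2.0 * precision * recall / (precision + recall)
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr, best_f1
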