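"""Classification metrics for heavily imbalanced target detection.

Accuracy, true/false positive rate and F1 come from hard decisions at a
configurable threshold on the target-class probability; AUC is the
probability that a random target trial scores above a random non-target
trial. Two tie policies are provided: ``strict`` counts tied pairs as
failures (the literal pairwise indicator), ``half`` credits them 0.5, which
is the Mann-Whitney convention and the reporting default. Undefined ratios
(zero denominators) are reported as NaN markers, never silently as zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ScoredPredictions:
    """Per-trial target-class probabilities with true labels."""

    scores: np.ndarray
    labels: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must be probabilities in [0, 1]")

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


@dataclass
class MetricsReport:
    acc: float
    tpr: float
    fpr: float
    f1: float
    auc: float
    counts: ConfusionCounts
    threshold: float = 0.5
    tie_policy: str = "half"

    def to_dict(self) -> dict:
        return {"acc": self.acc, "tpr": self.tpr, "fpr": self.fpr,
                "f1": self.f1, "auc": self.auc,
                "tp": self.counts.tp, "fp": self.counts.fp,
                "tn": self.counts.tn, "fn": self.counts.fn,
                "threshold": self.threshold, "tie_policy": self.tie_policy}

    def to_json(self) -> str:
        d = self.to_dict()
        return json.dumps({k: (None if isinstance(v, float) and math.isnan(v) else v)
                           for k, v in d.items()})

    def to_row(self, subject=0, fold=0, variant="default") -> dict:
        """One flat result row: subject, fold, variant, acc, tpr, fpr, f1, auc."""
        return {"subject": subject, "fold": fold, "variant": variant,
                "acc": self.acc, "tpr": self.tpr, "fpr": self.fpr,
                "f1": self.f1, "auc": self.auc}


def confusion(scored: ScoredPredictions) -> ConfusionCounts:
    """Tally the four confusion cells; predicted positive iff p > threshold."""
    if scored.scores.size == 0:
        raise ValueError("cannot tally an empty prediction set")
    pred = scored.scores > scored.threshold
    truth = scored.labels == 1
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def basic_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, TPR, FPR, F1); NaN where the denominator is zero."""
    if counts.total == 0:
        raise ValueError("no scored trials")
    acc = _ratio(counts.tp + counts.tn, counts.total)
    tpr = _ratio(counts.tp, counts.tp + counts.fn)
    fpr = _ratio(counts.fp, counts.fp + counts.tn)
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    return acc, tpr, fpr, f1


def auc(scored: ScoredPredictions, tie_policy: str = "half") -> float:
    """Pairwise ranking AUC via the rank-sum statistic, O(n log n).

    half: ties between a positive and a negative score count 0.5
    (Mann-Whitney / standard ROC-AUC). strict: ties count 0, the literal
    indicator I(p_i > p_j).
    """
    if tie_policy not in ("half", "strict"):
        raise ValueError("tie_policy must be 'half' or 'strict'")
    pos = scored.scores[scored.labels == 1]
    neg = scored.scores[scored.labels == 0]
    p, n = pos.size, neg.size
    if p == 0 or n == 0:
        raise ValueError("AUC needs at least one trial of each class")
    ranks = stats.rankdata(np.concatenate([pos, neg]), method="average")
    u_half = ranks[:p].sum() - p * (p + 1) / 2.0  # pairs won + half-ties
    if tie_policy == "half":
        return float(u_half / (p * n))
    # subtract the half credit given to every tied positive-negative pair
    ties = 0.0
    for v, c in zip(*np.unique(scored.scores, return_counts=True)):
        if c > 1:
            ties += (pos == v).sum() * (neg == v).sum()
    return float((u_half - 0.5 * ties) / (p * n))


def evaluate(scored: ScoredPredictions, tie_policy: str = "half") -> MetricsReport:
    """Bundle the full metric suite for one scored prediction set."""
    counts = confusion(scored)
    acc, tpr, fpr, f1 = basic_metrics(counts)
    try:
        a = auc(scored, tie_policy)
    except ValueError:
        a = float("nan")
    return MetricsReport(acc, tpr, fpr, f1, a, counts,
                         threshold=scored.threshold, tie_policy=tie_policy)
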