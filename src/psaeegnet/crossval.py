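"""Per-subject stratified k-fold evaluation and ablation sweeps.

Fold assignment shuffles indices within each class and deals them
round-robin to folds, so per-fold positive counts differ by at most one
even under severe imbalance and the split is an exact, seed-deterministic
function of the labels. Every variant in an ablation run is evaluated on
byte-identical fold splits (shared seed), making comparisons paired. Folds
whose test part contains a single class get an undefined (NaN) AUC that is
excluded from means, never silently zeroed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import MetricsReport, ScoredPredictions, evaluate
from .network import AblationSpec, NetworkConfig, build, variant_config
from .preprocessing import EpochSet
from .training import TrainConfig, TrainingHistory, fit

log = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "tpr", "fpr", "f1", "auc")


@dataclass
class FoldSplit:
    fold_index: int
    train: np.ndarray
    test: np.ndarray

    def check_disjoint(self) -> None:
        if np.intersect1d(self.train, self.test).size:
            raise AssertionError(
                f"fold {self.fold_index}: train and test indices overlap")


@dataclass
class CVResult:
    """Per-fold reports plus aggregated means/stds for one subject+variant."""

    variant: str
    fold_reports: list[MetricsReport]
    histories: list[TrainingHistory] = field(default_factory=list)
    subject: str | int = 0

    def metric_values(self, name: str) -> np.ndarray:
        vals = np.array([getattr(r, name) for r in self.fold_reports], dtype=float)
        return vals[~np.isnan(vals)]

    @property
    def means(self) -> dict[str, float]:
        return {m: (float(self.metric_values(m).mean())
                    if self.metric_values(m).size else float("nan"))
                for m in METRIC_NAMES}

    @property
    def stds(self) -> dict[str, float]:
        return {m: (float(self.metric_values(m).std(ddof=0))
                    if self.metric_values(m).size else float("nan"))
                for m in METRIC_NAMES}

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for fold, rep in enumerate(self.fold_reports):
            for m in METRIC_NAMES:
                rows.append({"subject": self.subject, "variant": self.variant,
                             "fold": fold, "metric": m, "value": getattr(rep, m)})
        return pd.DataFrame(rows)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Deterministic stratified k-fold splits of ``labels``."""
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} trials")
    n_pos = int((labels == 1).sum())
    if 0 < n_pos < k:
        warnings.warn(f"only {n_pos} positive trials for {k} folds; some test "
                      "folds will lack positives", stacklevel=2)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        fold_of[idx] = np.arange(idx.size) % k
    splits = []
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        split = FoldSplit(f, train, test)
        split.check_disjoint()
        splits.append(split)
    return splits


def run_cv(epochs: EpochSet, net_config: NetworkConfig | None = None,
           train_config: TrainConfig | None = None, k: int = 5, seed: int = 0,
           variant: str = "default", subject: str | int = 0,
           keep_histories: bool = False) -> CVResult:
    """Stratified k-fold: fit on each training portion (with its own inner
    validation sub-split), score the untouched test fold, bundle metrics."""
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainConfig()
    ss = np.random.SeedSequence(seed)
    split_seed, *fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in ss.spawn(1 + k)]
    splits = stratified_kfold(epochs.labels, k=k, seed=split_seed)
    reports, histories = [], []
    for split, fseed in zip(splits, fold_seeds):
        split.check_disjoint()
        net = build(net_config, seed=fseed)
        tc = TrainConfig(**{**train_config.__dict__, "seed": fseed})
        net, hist = fit(net, epochs.subset(split.train), tc)
        probs = net.predict_proba(epochs.subset(split.test))
        scored = ScoredPredictions(probs[:, 1], epochs.labels[split.test])
        rep = evaluate(scored)
        if np.isnan(rep.auc):
            log.warning("fold %d has a single-class test set; AUC undefined "
                        "and excluded from the mean", split.fold_index)
        reports.append(rep)
        if keep_histories:
            histories.append(hist)
    return CVResult(variant, reports, histories, subject=subject)


def run_ablation(epochs: EpochSet, variants: list[AblationSpec],
                 net_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None,
                 k: int = 5, seed: int = 0,
                 subject: str | int = 0) -> list[CVResult]:
    """One CVResult per variant, all on identical fold splits (same seed)."""
    if not variants:
        raise ValueError("variants must be non-empty")
    base = net_config or NetworkConfig()
    results = []
    for spec in variants:
        cfg = variant_config(base, spec)
        results.append(run_cv(epochs, cfg, train_config, k=k, seed=seed,
                              variant=spec.label, subject=subject))
    return results


def aggregate(results: list[CVResult]) -> pd.DataFrame:
    """Cross-subject summary: mean/std per metric per variant.

    Undefined fold metrics are excluded; n_folds counts the values that
    entered each mean.
    """
    if not results:
        raise ValueError("no results to aggregate")
    rows = []
    for m in METRIC_NAMES:
        by_variant: dict[str, list] = {}
        for r in results:
            by_variant.setdefault(r.variant, []).append(r)
        for variant, rs in by_variant.items():
            subject_means = np.array([r.means[m] for r in rs], dtype=float)
            valid = subject_means[~np.isnan(subject_means)]
            n_vals = int(sum(r.metric_values(m).size for r in rs))
            n_total = int(sum(len(r.fold_reports) for r in rs))
            rows.append({
                "variant": variant, "metric": m,
                "mean": float(valid.mean()) if valid.size else float("nan"),
                "std": float(valid.std(ddof=0)) if valid.size else float("nan"),
                "n_subjects": len(rs), "n_folds": n_vals,
                "n_excluded": n_total - n_vals,
            })
    return pd.DataFrame(rows)
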