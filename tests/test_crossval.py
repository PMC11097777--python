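"""Stratified k-fold machinery, paired ablations and aggregation."""

import numpy as np
import pandas as pd
import pytest

from psaeegnet import EpochSet, NetworkConfig, PSAConfig
from psaeegnet.crossval import (CVResult, aggregate, run_ablation, run_cv,
                                stratified_kfold)
from psaeegnet.metrics import ConfusionCounts, MetricsReport
from psaeegnet.network import AblationSpec
from psaeegnet.training import TrainConfig


class TestStratifiedKFold:
    def test_exactly_divisible_classes(self):
        labels = np.array([1] * 20 + [0] * 80)
        for split in stratified_kfold(labels, k=5, seed=0):
            assert (labels[split.test] == 1).sum() == 4
            assert (labels[split.test] == 0).sum() == 16

    def test_pigeonhole_with_few_positives_warns(self):
        labels = np.array([1] * 4 + [0] * 96)
        with pytest.warns(UserWarning, match="positive"):
            splits = stratified_kfold(labels, k=5, seed=0)
        pos_counts = sorted((labels[s.test] == 1).sum() for s in splits)
        assert pos_counts == [0, 1, 1, 1, 1]

    def test_disjoint_covering_deterministic(self):
        labels = (np.random.default_rng(0).random(1000) < 0.03).astype(int)
        a = stratified_kfold(labels, k=5, seed=42)
        b = stratified_kfold(labels, k=5, seed=42)
        seen = set()
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.test, sb.test)
            np.testing.assert_array_equal(sa.train, sb.train)
            assert set(sa.test).isdisjoint(sa.train)
            assert seen.isdisjoint(sa.test)
            seen.update(sa.test)
        assert seen == set(range(1000))

    def test_positive_counts_balanced_within_one(self):
        labels = (np.random.default_rng(3).random(337) < 0.07).astype(int)
        splits = stratified_kfold(labels, k=5, seed=1)
        pos = [(labels[s.test] == 1).sum() for s in splits]
        assert max(pos) - min(pos) <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            stratified_kfold(np.array([0, 1, 0]), k=5)


def _fast_config():
    return NetworkConfig(n_channels=8, n_samples=24, temporal_filters=4,
                         temporal_kernel=7, depth_multiplier=2,
                         separable_kernel=4, pool_size=3,
                         pool_out_lengths=(8, 3), dropout_p=0.25,
                         psa_psfe=PSAConfig((1, 3, 5, 7)),
                         psa_dtfe=PSAConfig((1, 3, 5, 7)))


def _toy_subject(n=40, seed=0, signal=3.0):
    rng = np.random.default_rng(seed)
    labels = np.array([0, 1] * (n // 2))
    x = rng.normal(size=(n, 8, 24)).astype(np.float32)
    x[labels == 1, :, 8:16] += signal
    return EpochSet(x, labels, 250.0)


FAST_TRAIN = TrainConfig(max_epochs=2, batch_size=8,
                         validation_fraction=0.25)


class TestRunCV:
    def test_two_fold_protocol_smoke(self):
        res = run_cv(_toy_subject(), _fast_config(), FAST_TRAIN, k=2, seed=0)
        assert len(res.fold_reports) == 2
        for m in ("acc", "tpr", "fpr", "f1", "auc"):
            assert m in res.means

    def test_single_class_test_fold_excludes_auc(self):
        # 3 positives in 16 trials over 4 folds -> one test fold lacks
        # positives while every training set keeps at least two
        rng = np.random.default_rng(1)
        labels = np.array([1, 1, 1] + [0] * 13)
        x = rng.normal(size=(16, 8, 24)).astype(np.float32)
        ep = EpochSet(x, labels, 250.0)
        tc = TrainConfig(max_epochs=1, batch_size=4, validation_fraction=0.3)
        with pytest.warns(UserWarning):
            res = run_cv(ep, _fast_config(), tc, k=4, seed=0)
        aucs = [r.auc for r in res.fold_reports]
        assert sum(np.isnan(aucs)) >= 1
        assert not np.isnan(res.means["auc"])  # mean over defined folds only


class TestRunAblation:
    def test_paired_rows_for_four_variants(self):
        ep = _toy_subject(seed=2)
        variants = [AblationSpec(n) for n in ("A+A", "A+0", "0+A", "EEGNet")]
        results = run_ablation(ep, variants, _fast_config(), FAST_TRAIN,
                               k=2, seed=5)
        assert [r.variant for r in results] == ["A+A", "A+0", "0+A", "EEGNet"]
        # paired: identical fold splits because the seed is shared
        splits = [stratified_kfold(ep.labels, 2, seed=s) for s in (1,)]
        assert all(len(r.fold_reports) == 2 for r in results)

    def test_duplicate_variant_reproduces_rows(self):
        ep = _toy_subject(seed=3)
        results = run_ablation(ep, [AblationSpec("EEGNet")] * 2,
                               _fast_config(), FAST_TRAIN, k=2, seed=9)
        a, b = results
        for ra, rb in zip(a.fold_reports, b.fold_reports):
            assert ra.to_dict() == rb.to_dict()

    def test_empty_variant_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            run_ablation(_toy_subject(), [], _fast_config(), FAST_TRAIN)


def _report(**kw):
    base = dict(acc=0.9, tpr=0.8, fpr=0.1, f1=0.5, auc=0.95,
                counts=ConfusionCounts(1, 1, 1, 1))
    base.update(kw)
    return MetricsReport(**base)


class TestAggregate:
    def test_single_subject_equals_its_means(self):
        r = CVResult("A+A", [_report(acc=0.8), _report(acc=0.9)], subject=0)
        table = aggregate([r])
        acc = table[(table.metric == "acc")].iloc[0]
        assert acc["mean"] == pytest.approx(r.means["acc"])

    def test_two_subject_hand_mean_std(self):
        r1 = CVResult("x", [_report(auc=0.9)], subject=0)
        r2 = CVResult("x", [_report(auc=0.7)], subject=1)
        row = aggregate([r1, r2]).query("metric == 'auc'").iloc[0]
        assert row["mean"] == pytest.approx(0.8)
        assert row["std"] == pytest.approx(0.1)
        assert row["n_subjects"] == 2

    def test_undefined_metric_excluded_and_counted(self):
        r = CVResult("x", [_report(auc=float("nan")), _report(auc=0.9)])
        row = aggregate([r]).query("metric == 'auc'").iloc[0]
        assert row["mean"] == pytest.approx(0.9)
        assert row["n_excluded"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_cv_mean_equals_arithmetic_mean(self):
        reports = [_report(acc=a) for a in (0.2, 0.4, 0.9)]
        r = CVResult("x", reports)
        assert r.means["acc"] == pytest.approx(np.mean([0.2, 0.4, 0.9]),
                                               abs=1e-12)
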