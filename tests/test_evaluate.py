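"""Metric formulas, AHI rule, agreement statistics, CV partitioning."""

import numpy as np
import pandas as pd
import pytest

from apneatw.config import EvalConfig, RunConfig
from apneatw.evaluate import (
    ConfusionCounts,
    RecordingSummary,
    bland_altman,
    compute_ahi,
    kfold_cv,
    recording_metrics,
    segment_metrics,
    summarize_recording,
)


class TestSegmentMetrics:
    def test_enumerated_confusion_table(self):
        out = segment_metrics(ConfusionCounts(TP=8, FN=2, TN=9, FP=1))
        assert out["accuracy"] == pytest.approx(0.85)
        assert out["sensitivity"] == pytest.approx(0.80)
        assert out["specificity"] == pytest.approx(0.90)

    def test_counts_from_labels_partition_everything(self, rng):
        y_true = rng.integers(0, 2, 500)
        y_pred = rng.integers(0, 2, 500)
        c = ConfusionCounts.from_labels(y_true, y_pred)
        assert c.total == 500
        # brute-force recount
        assert c.TP == sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        assert c.FN == sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)

    def test_perfect_separation_auc(self):
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        scores = np.r_[np.arange(5), np.arange(10, 15)]
        out = segment_metrics(ConfusionCounts.from_labels(labels, labels), scores, labels)
        assert out["auc"] == 1.0

    def test_random_scores_auc_near_half(self, rng):
        labels = rng.integers(0, 2, 10_000)
        scores = rng.standard_normal(10_000)
        out = segment_metrics(ConfusionCounts.from_labels(labels, labels), scores, labels)
        assert out["auc"] == pytest.approx(0.5, abs=0.02)

    def test_single_class_truth_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            out = segment_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=1))
        assert np.isnan(out["sensitivity"])

    def test_auc_ties_count_half(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([1.0, 1.0, 1.0, 1.0])
        out = segment_metrics(ConfusionCounts.from_labels(labels, labels), scores, labels)
        assert out["auc"] == pytest.approx(0.5)


class TestComputeAhi:
    def test_ten_sa_minutes_in_an_hour(self):
        ahi, cls = compute_ahi(10, 60)
        assert ahi == 10.0 and cls == "apnea"

    def test_boundary_is_strictly_greater(self):
        ahi, cls = compute_ahi(40, 480)
        assert ahi == 5.0 and cls == "normal"

    def test_zero_events(self):
        ahi, cls = compute_ahi(0, 60)
        assert ahi == 0.0 and cls == "normal"

    def test_exact_rational_identity(self, rng):
        for _ in range(100):
            T = int(rng.integers(1, 600))
            n = int(rng.integers(0, T + 1))
            ahi, _ = compute_ahi(n, T)
            assert ahi * T == pytest.approx(60.0 * n, abs=1e-9)

    def test_nonpositive_t_rejected(self):
        with pytest.raises(ValueError):
            compute_ahi(1, 0)

    def test_summarize_t_policy(self):
        pred = np.array([1, 0, 1, 0])          # 4 evaluated minutes
        true = np.array([1, 0, 1, 0, 1, 1])    # 6 labelled minutes
        s_eval = summarize_recording("r", pred, true, EvalConfig(ahi_t_policy="evaluated"))
        s_full = summarize_recording("r", pred, true, EvalConfig(ahi_t_policy="full"))
        assert s_eval.ahi_pred == 60 / 4 * 2
        assert s_full.ahi_pred == 60 / 6 * 2
        assert s_eval.ahi_true == s_full.ahi_true == 60 / 6 * 4


def _summary(rid, pred, true):
    return RecordingSummary(
        record_id=rid,
        T=60,
        n_sa_segments=0,
        ahi_pred=pred,
        ahi_true=true,
        class_pred="apnea" if pred > 5 else "normal",
        class_true="apnea" if true > 5 else "normal",
    )


class TestRecordingMetrics:
    def test_perfect_agreement(self):
        s = [_summary(f"r{i}", a, a) for i, a in enumerate([2.0, 8.0, 15.0, 3.0])]
        out = recording_metrics(s)
        assert out["accuracy"] == 1.0
        assert out["pearson_corr"] == pytest.approx(1.0)

    def test_inverted_two_point_correlation(self):
        s = [_summary("a", 1.0, 10.0), _summary("b", 10.0, 1.0)]
        out = recording_metrics(s)
        assert out["pearson_corr"] == pytest.approx(-1.0)

    def test_pearson_matches_brute_force(self, rng):
        pred = rng.uniform(0, 30, 5)
        true = rng.uniform(0, 30, 5)
        s = [_summary(f"r{i}", p, t) for i, (p, t) in enumerate(zip(pred, true))]
        out = recording_metrics(s)
        # direct formula
        px, tx = pred - pred.mean(), true - true.mean()
        want = np.sum(px * tx) / np.sqrt(np.sum(px**2) * np.sum(tx**2))
        assert out["pearson_corr"] == pytest.approx(want, abs=1e-12)

    def test_constant_vector_warns_nan(self):
        s = [_summary("a", 7.0, 3.0), _summary("b", 7.0, 9.0)]
        with pytest.warns(UserWarning, match="constant"):
            out = recording_metrics(s)
        assert np.isnan(out["pearson_corr"])


class TestBlandAltman:
    def test_identical_vectors(self):
        out = bland_altman(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert out["bias"] == 0.0
        assert out["loa_low"] == 0.0 and out["loa_high"] == 0.0

    def test_constant_offset(self):
        out = bland_altman(np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert out["bias"] == pytest.approx(3.0)
        assert out["loa_low"] == pytest.approx(3.0) and out["loa_high"] == pytest.approx(3.0)

    def test_hand_computed_toy_pairs(self):
        pred = np.array([10.0, 20.0, 30.0, 40.0])
        true = np.array([12.0, 18.0, 33.0, 35.0])
        out = bland_altman(pred, true)
        diffs = pred - true
        assert out["bias"] == pytest.approx(diffs.mean(), abs=1e-12)
        sd = np.std(diffs)
        assert out["loa_high"] == pytest.approx(diffs.mean() + 1.96 * sd, abs=1e-12)

    def test_limits_cover_95_percent_of_gaussian_differences(self, rng):
        true = rng.uniform(0, 30, 5000)
        pred = true + rng.normal(1.0, 2.0, 5000)
        out = bland_altman(pred, true)
        inside = np.mean((out["diffs"] >= out["loa_low"]) & (out["diffs"] <= out["loa_high"]))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([1.0]))


class TestKfoldPartition:
    @staticmethod
    def _tiny_frames(n_recs, rng):
        """Directly constructed feature frames (no signal pipeline needed)."""
        from apneatw.features import FEATURE_NAMES

        frames = {}
        for i in range(n_recs):
            n = 30
            labels = (rng.random(n) < 0.4).astype(int)
            df = pd.DataFrame(
                rng.standard_normal((n, 18)) + 1.5 * labels[:, None], columns=FEATURE_NAMES
            )
            # make a couple of features informative
            df.insert(0, "record_id", f"t{i}")
            df.insert(1, "minute_index", np.arange(n))
            df.insert(2, "label", labels)
            df.insert(3, "valid", True)
            frames[f"t{i}"] = df
        return frames

    def test_folds_are_a_disjoint_cover(self, rng):
        frames = self._tiny_frames(14, rng)
        cfg = RunConfig()
        cfg.train.epochs = 5
        table, summary = kfold_cv(frames, cfg, k=7, seed=0)
        seen = []
        for cell in table["test_recordings"]:
            seen.extend(cell.split(","))
        assert sorted(seen) == sorted(frames)          # cover, no repeats
        assert all(len(cell.split(",")) == 2 for cell in table["test_recordings"])
        assert "segment_accuracy" in summary

    def test_more_folds_than_recordings_rejected(self, rng):
        frames = self._tiny_frames(3, rng)
        with pytest.raises(ValueError, match="fold"):
            kfold_cv(frames, RunConfig(), k=7, seed=0)


class TestWindowSweep:
    def test_sweep_table_shape_and_hidden_sizes(self, rng):
        from apneatw.evaluate import window_sweep

        train_fr = TestKfoldPartition._tiny_frames(6, rng)
        test_fr = TestKfoldPartition._tiny_frames(2, np.random.default_rng(99))
        cfg = RunConfig()
        cfg.train.epochs = 3
        table = window_sweep(train_fr, test_fr, [3, 1, 2], cfg)
        assert list(table["w"]) == [1, 2, 3]          # strictly increasing
        assert list(table["H"]) == [2 * 18 * w + 1 for w in (1, 2, 3)]
        assert "segment_accuracy" in table.columns
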