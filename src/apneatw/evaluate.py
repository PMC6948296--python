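"""Per-segment and per-recording evaluation, agreement statistics, harnesses.

Per-segment: accuracy, sensitivity, specificity (confusion-count definitions)
and AUC.  Per-recording: the apnea-hypopnea index AHI = 60/T * (number of
apnea minutes), a recording is classified apneic iff AHI > 5 (strictly), plus
Pearson correlation and Bland-Altman agreement between predicted and
annotated AHI.  Harnesses: window-size sweep and recording-level k-fold
cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from apneatw.config import EvalConfig, RunConfig, TrainConfig
from apneatw.features import apply_normalizer, fit_normalizer
from apneatw.model import build_windows, hidden_size, init_model
from apneatw.model import predict_segments as _predict
from apneatw.model import train as _train

__all__ = [
    "ConfusionCounts",
    "RecordingSummary",
    "segment_metrics",
    "compute_ahi",
    "summarize_recording",
    "recording_metrics",
    "bland_altman",
    "run_experiment",
    "window_sweep",
    "kfold_cv",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def segment_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity from counts; AUC from scores.

    AUC is the probability that a random positive outscores a random negative
    (ties count 1/2).  With a single-class truth, the undefined entries are
    reported as NaN with a warning.
    """
    c = counts
    acc = (c.TP + c.TN) / c.total if c.total else float("nan")
    if c.TP + c.FN == 0:
        warnings.warn("no positive segments: sensitivity undefined (NaN)")
        sens = float("nan")
    else:
        sens = c.TP / (c.TP + c.FN)
    if c.TN + c.FP == 0:
        warnings.warn("no negative segments: specificity undefined (NaN)")
        spec = float("nan")
    else:
        spec = c.TN / (c.TN + c.FP)
    auc = float("nan")
    if scores is not None and labels is not None:
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) == 2:
            auc = float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
        else:
            warnings.warn("single-class truth: AUC undefined (NaN)")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "auc": auc}


@dataclass
class RecordingSummary:
    record_id: str
    T: int                    # minutes evaluated
    n_sa_segments: int
    ahi_pred: float
    ahi_true: float
    class_pred: str           # 'apnea' / 'normal' by the AHI > 5 rule
    class_true: str


def compute_ahi(n_sa_segments: int, T: int, threshold: float = 5.0) -> tuple[float, str]:
    """AHI = 60/T * n_sa_segments; class 'apnea' iff AHI strictly exceeds threshold."""
    if T <= 0:
        raise ValueError(f"T must be > 0 minutes, got {T}")
    ahi = 60.0 / T * n_sa_segments
    return ahi, ("apnea" if ahi > threshold else "normal")


def summarize_recording(
    record_id: str,
    pred_minutes: np.ndarray,
    true_minutes_all: np.ndarray,
    cfg: EvalConfig | None = None,
) -> RecordingSummary:
    """Per-recording AHI summary.

    ``pred_minutes`` are the binary predictions for the evaluated minutes
    (after window trimming); ``true_minutes_all`` the annotations for every
    labelled minute.  The predicted AHI uses T = evaluated minutes by default
    (``ahi_t_policy='full'`` uses all labelled minutes instead); the true AHI
    always uses all labelled minutes.
    """
    cfg = cfg or EvalConfig()
    pred_minutes = np.asarray(pred_minutes, dtype=int)
    true_all = np.asarray(true_minutes_all, dtype=int)
    t_pred = len(true_all) if cfg.ahi_t_policy == "full" else len(pred_minutes)
    ahi_pred, class_pred = compute_ahi(int(pred_minutes.sum()), t_pred, cfg.ahi_threshold)
    ahi_true, class_true = compute_ahi(int(true_all.sum()), len(true_all), cfg.ahi_threshold)
    return RecordingSummary(
        record_id=record_id,
        T=t_pred,
        n_sa_segments=int(pred_minutes.sum()),
        ahi_pred=ahi_pred,
        ahi_true=ahi_true,
        class_pred=class_pred,
        class_true=class_true,
    )


def recording_metrics(summaries: list[RecordingSummary]) -> dict[str, float]:
    """Confusion metrics on predicted vs true class, AUC over predicted AHI as
    score, and Pearson correlation between predicted and true AHI."""
    if len(summaries) < 2:
        raise ValueError("need >= 2 recordings")
    y_true = np.array([int(s.class_true == "apnea") for s in summaries])
    y_pred = np.array([int(s.class_pred == "apnea") for s in summaries])
    ahi_pred = np.array([s.ahi_pred for s in summaries])
    ahi_true = np.array([s.ahi_true for s in summaries])
    out = segment_metrics(ConfusionCounts.from_labels(y_true, y_pred), ahi_pred, y_true)
    if np.std(ahi_pred) == 0 or np.std(ahi_true) == 0:
        warnings.warn("constant AHI vector: correlation undefined (NaN)")
        out["pearson_corr"] = float("nan")
    else:
        out["pearson_corr"] = float(sstats.pearsonr(ahi_pred, ahi_true)[0])
    return out


def bland_altman(
    ahi_pred: np.ndarray, ahi_true: np.ndarray
) -> dict[str, float | np.ndarray]:
    """Bland-Altman agreement: bias = mean(pred - true), limits of agreement
    bias +/- 1.96 * sd(differences) (population sd), per-point diffs/means."""
    ahi_pred = np.asarray(ahi_pred, dtype=float)
    ahi_true = np.asarray(ahi_true, dtype=float)
    if len(ahi_pred) < 2 or len(ahi_pred) != len(ahi_true):
        raise ValueError("need >= 2 paired AHI values")
    diffs = ahi_pred - ahi_true
    means = (ahi_pred + ahi_true) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=0))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "diffs": diffs,
        "means": means,
    }


def bland_altman_plot(ba: dict, path) -> None:
    """Optional PNG artifact of a Bland-Altman analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["means"], ba["diffs"], s=18)
    for y, style in ((ba["bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of predicted and annotated AHI (events/h)")
    ax.set_ylabel("difference (events/h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# harnesses


def _frames_to_windows(frames: dict[str, pd.DataFrame], stats, w: int):
    from apneatw.features import FEATURE_NAMES

    by_rec = {}
    for rec_id, df in frames.items():
        X = df[FEATURE_NAMES].to_numpy(dtype=float)
        Xn = np.where(np.isfinite(X), X, 0.0)  # invalid rows are dropped by the mask
        by_rec[rec_id] = {
            "X": apply_normalizer(Xn, stats),
            "valid": df["valid"].to_numpy(dtype=bool),
            "label": df["label"].to_numpy(dtype=int),
            "minute_index": df["minute_index"].to_numpy(dtype=int),
        }
    return build_windows(by_rec, w)


def run_experiment(
    train_frames: dict[str, pd.DataFrame],
    test_frames: dict[str, pd.DataFrame],
    cfg: RunConfig,
    w: int | None = None,
    seed: int | None = None,
) -> dict:
    """Train a TW-MLP on ``train_frames`` and evaluate on ``test_frames``.

    Normalization statistics are fitted on the valid training segments only.
    Returns segment metrics, recording metrics, per-recording summaries and
    the fitted model.
    """
    from apneatw.features import FEATURE_NAMES

    w = cfg.window if w is None else w
    seed = cfg.train.seed if seed is None else seed
    train_valid = pd.concat(
        [df.loc[df["valid"], FEATURE_NAMES] for df in train_frames.values()]
    )
    stats = fit_normalizer(train_valid, fitted_on=",".join(sorted(train_frames)))
    ds_train = _frames_to_windows(train_frames, stats, w)
    ds_test = _frames_to_windows(test_frames, stats, w)

    tcfg = TrainConfig(**{**cfg.train.__dict__, "seed": seed})
    model = init_model(M=ds_train.X.shape[1], seed=seed, w=w)
    model.norm_stats = stats
    model = _train(model, ds_train, tcfg)

    pred, scores = _predict(model, ds_test.X)
    seg = segment_metrics(ConfusionCounts.from_labels(ds_test.y, pred), scores, ds_test.y)

    summaries = []
    for rec_id, df in test_frames.items():
        mask = [i for i, (r, _) in enumerate(ds_test.index) if r == rec_id]
        if not mask:
            logger.warning("recording %s produced no evaluable windows", rec_id)
            continue
        summaries.append(
            summarize_recording(
                rec_id, pred[mask], df["label"].to_numpy(dtype=int), cfg.eval
            )
        )
    rec = recording_metrics(summaries) if len(summaries) >= 2 else {}
    return {
        "segment": seg,
        "recording": rec,
        "summaries": summaries,
        "model": model,
        "n_train": len(ds_train),
        "n_test": len(ds_test),
        "predictions": pd.DataFrame(
            {
                "record_id": [r for r, _ in ds_test.index],
                "minute_index": [m for _, m in ds_test.index],
                "label": ds_test.y,
                "pred": pred,
                "score": scores,
            }
        ),
    }


def window_sweep(
    train_frames: dict[str, pd.DataFrame],
    test_frames: dict[str, pd.DataFrame],
    w_values: list[int],
    cfg: RunConfig,
) -> pd.DataFrame:
    """One train/eval cycle per window size, H recomputed as 2*(18w)+1."""
    rows = []
    for w in sorted(w_values):
        res = run_experiment(train_frames, test_frames, cfg, w=w)
        rows.append(
            {
                "w": w,
                "H": hidden_size(res["model"].M),
                "n_test": res["n_test"],
                **{f"segment_{k}": v for k, v in res["segment"].items()},
            }
        )
    return pd.DataFrame(rows)


def kfold_cv(
    frames: dict[str, pd.DataFrame], cfg: RunConfig, k: int = 7, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Recording-level k-fold cross-validation.

    Recordings (never individual segments) are shuffled with ``seed`` and
    partitioned into k folds; normalization and training are refit per fold.
    Returns the per-fold metric table and mean +/- 95% CI (t distribution,
    k-1 df) per metric.
    """
    rec_ids = sorted(frames)
    if k > len(rec_ids):
        raise ValueError(f"k={k} folds but only {len(rec_ids)} recordings")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rec_ids))
    folds = np.array_split(order, k)
    rows = []
    for fold_i, test_pos in enumerate(folds):
        test_ids = {rec_ids[i] for i in test_pos}
        train_fr = {r: frames[r] for r in rec_ids if r not in test_ids}
        test_fr = {r: frames[r] for r in test_ids}
        res = run_experiment(train_fr, test_fr, cfg, seed=seed + fold_i)
        row = {"fold": fold_i, "test_recordings": ",".join(sorted(test_ids))}
        row.update({f"segment_{k_}": v for k_, v in res["segment"].items()})
        row.update({f"recording_{k_}": v for k_, v in res["recording"].items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = {}
    tcrit = sstats.t.ppf(0.975, df=k - 1)
    for col in table.columns:
        if col in ("fold", "test_recordings"):
            continue
        vals = table[col].to_numpy(dtype=float)
        mean = float(np.nanmean(vals))
        sem = float(np.nanstd(vals, ddof=1) / np.sqrt(k))
        summary[col] = {"mean": mean, "ci95": tcrit * sem}
    return table, summary
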