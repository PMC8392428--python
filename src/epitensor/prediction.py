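"""Seizure alerts from label streams, and the two evaluation protocols.

The alarm rule scans a temporal stream of per-window (or per-tensor) labels:
a counter increments on every pre-ictal label (2) and resets on every
inter-ictal label (1); the first time it reaches ``alarm_len`` consecutive
pre-ictal detections an alert is raised.  For a pre-ictal segment the
prediction time is

    T = s * (n + 1)

with ``s`` the stream step in seconds and ``n`` the number of stream
positions left unprocessed when the alert fires (an alert at the final
position gives T = s).

Two protocols are provided: stratified ten-fold cross-validation on feature
rows (grouped by source segment when groups are given, so rows of one
recording never straddle a fold boundary) and leave-one-segment-out alarm
evaluation, where each held-out 45-min segment is stream-classified and
counts correct if an alert fires (pre-ictal) or stays silent (inter-ictal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import elm
from .config import ConfigurationError

logger = logging.getLogger("epitensor")


@dataclass(frozen=True)
class AlarmResult:
    """Outcome of scanning one label stream."""

    alert: bool
    trigger_index: int | None = None
    prediction_time_s: float | None = None


@dataclass
class EvaluationMetrics:
    """Confusion counts and derived rates; positive class = pre-ictal (2)."""

    tp: int
    fp: int
    tn: int
    fn: int
    mean_prediction_time_s: float | None = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "mean_prediction_time_s": self.mean_prediction_time_s,
            "counts": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
        }

    @classmethod
    def from_labels(cls, true: np.ndarray, pred: np.ndarray) -> "EvaluationMetrics":
        true, pred = np.asarray(true), np.asarray(pred)
        return cls(
            tp=int(np.sum((true == 2) & (pred == 2))),
            fp=int(np.sum((true == 1) & (pred == 2))),
            tn=int(np.sum((true == 1) & (pred == 1))),
            fn=int(np.sum((true == 2) & (pred == 1))),
        )


def alarm_scan(label_stream, alarm_len: int = 30) -> AlarmResult:
    """Scan labels {1, 2} for ``alarm_len`` consecutive pre-ictal states.

    The counter increments on 2 and resets on 1; scanning stops at the
    first index where it reaches ``alarm_len``.
    """
    if alarm_len < 1:
        raise ConfigurationError("alarm_len must be >= 1")
    stream = np.asarray(list(label_stream))
    if stream.size == 0:
        raise ValueError("label stream is empty")
    if not np.isin(stream, (1, 2)).all():
        raise ValueError("labels must be 1 or 2")
    counter = 0
    for i, label in enumerate(stream):
        counter = counter + 1 if label == 2 else 0
        if counter == alarm_len:
            return AlarmResult(alert=True, trigger_index=i)
    return AlarmResult(alert=False)


def prediction_time(total_windows: int, trigger_index: int, s: float = 4.0) -> float:
    """T = s * (n + 1) with n the stream positions left after the alert."""
    if not 0 <= trigger_index < total_windows:
        raise ValueError("trigger_index must lie within the stream")
    n = total_windows - 1 - trigger_index
    return s * (n + 1)


def tenfold_cv(
    features: np.ndarray,
    labels: np.ndarray,
    M: int = 100,
    E_grid=(1.0,),
    seed: int = 0,
    groups: np.ndarray | None = None,
    n_splits: int = 10,
) -> EvaluationMetrics:
    """Stratified ten-fold cross-validation of the ELM on feature rows.

    When ``groups`` is given (one source-segment id per row) folds keep
    groups intact, so a recording never contributes to both sides of a
    split.  The ridge parameter is re-selected inside every training fold;
    metrics are pooled over folds.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    for lab in (1, 2):
        if np.sum(labels == lab) < n_splits and groups is None:
            raise ConfigurationError(
                f"need >= {n_splits} samples of class {lab} for {n_splits}-fold CV"
            )
    if groups is None:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = splitter.split(features, labels)
    else:
        groups = np.asarray(groups)
        if np.unique(groups).size < n_splits:
            raise ConfigurationError("need at least n_splits groups")
        splitter = StratifiedGroupKFold(
            n_splits=n_splits, shuffle=True, random_state=seed
        )
        splits = splitter.split(features, labels, groups)

    true_all, pred_all = [], []
    for k, (tr, te) in enumerate(splits):
        E = elm.select_regularization(
            features[tr], labels[tr], M=M, E_grid=E_grid, seed=seed + k
        )
        model = elm.train(features[tr], labels[tr], M=M, E=E, seed=seed + k)
        pred_all.append(elm.predict(model, features[te]))
        true_all.append(labels[te])
    return EvaluationMetrics.from_labels(
        np.concatenate(true_all), np.concatenate(pred_all)
    )


def leave_one_segment_out(
    segment_features: list[np.ndarray],
    segment_labels: list[int],
    M: int = 100,
    E_grid=(1.0,),
    alarm_len: int = 30,
    step_seconds: float = 4.0,
    seed: int = 0,
    fold_builder=None,
) -> tuple[EvaluationMetrics, list[dict]]:
    """Alarm-based evaluation with one whole segment held out per fold.

    ``segment_features[i]`` holds the temporally ordered feature rows of
    segment i (already extracted under that fold's frozen factors when
    applicable); the classifier is trained on all other segments and the
    held-out rows are stream-classified and scanned by the alarm rule.  A
    pre-ictal segment is correct iff an alert fires (its prediction time is
    ``T = step_seconds * (n + 1)``); an inter-ictal segment is correct iff
    no alert fires.  Mean prediction time averages over correctly predicted
    pre-ictal segments only.

    When features depend on the training fold (the frozen tensor factors
    are refit from each fold's training segments), pass ``fold_builder``,
    a callable mapping the held-out index to that fold's full list of
    per-segment feature matrices; ``segment_features`` may then be ``None``.

    Returns pooled metrics and one trace dict per evaluated segment.
    """
    n_segments = len(segment_features if fold_builder is None else segment_labels)
    if n_segments < 2:
        raise ConfigurationError("need at least 2 segments")
    labels_arr = np.asarray(segment_labels)
    traces: list[dict] = []
    tp = fp = tn = fn = 0
    times: list[float] = []
    for i in range(n_segments):
        train_idx = [j for j in range(n_segments) if j != i]
        train_labels = labels_arr[train_idx]
        if np.unique(train_labels).size < 2:
            logger.warning("fold %d: training segments single-class; skipped", i)
            continue
        fold_features = (
            segment_features if fold_builder is None else fold_builder(i)
        )
        X_tr = np.vstack([fold_features[j] for j in train_idx])
        y_tr = np.concatenate(
            [np.full(len(fold_features[j]), labels_arr[j]) for j in train_idx]
        )
        E = elm.select_regularization(X_tr, y_tr, M=M, E_grid=E_grid, seed=seed + i)
        model = elm.train(X_tr, y_tr, M=M, E=E, seed=seed + i)
        stream = elm.predict(model, fold_features[i])
        result = alarm_scan(stream, alarm_len=alarm_len)
        t = None
        if labels_arr[i] == 2:
            if result.alert:
                tp += 1
                t = prediction_time(len(stream), result.trigger_index, step_seconds)
                times.append(t)
            else:
                fn += 1
        else:
            if result.alert:
                fp += 1
            else:
                tn += 1
        traces.append(
            {
                "segment": i,
                "label": int(labels_arr[i]),
                "stream": stream.tolist(),
                "alert": result.alert,
                "trigger_index": result.trigger_index,
                "prediction_time_s": t,
            }
        )
    metrics = EvaluationMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        mean_prediction_time_s=float(np.mean(times)) if times else None,
    )
    logger.info(
        "leave-one-segment-out: acc=%.3f sens=%.3f spec=%.3f",
        metrics.accuracy,
        metrics.sensitivity,
        metrics.specificity,
    )
    return metrics, traces
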