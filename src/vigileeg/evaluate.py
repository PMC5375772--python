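"""Evaluation statistics and the time-window (r) sweep experiment.

Drowsy is the positive class throughout — sensitivity is the fraction of
actual drowsy seconds detected as drowsy, the false-positive rate the
fraction of actual alert seconds flagged as drowsy — even though the SVM
labels alert +1 and drowsy -1. That sign mapping is centralised in
:class:`ConfusionCounts` so it cannot drift between metrics.

The r-sweep runs the full pipeline (denoise -> featurise -> contiguous
3-block cross-validation) once per time window r, pooling held-out seconds
across blocks (micro-average), and records the mean wall-clock time per
prediction. Rates are kept in [0, 1]; a percent view is provided for
reporting.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .features import extract_features, DEFAULT_BANDS
from .svm import TrainingConfig, cross_validate, decision_values
from .wavelet import denoise, DEFAULT_KEEP

DROWSY_LABEL = -1   # SVM label of the positive (drowsy) class
ALERT_LABEL = +1


@dataclass(frozen=True)
class ConfusionCounts:
    """Second-wise confusion counts with drowsy (-1) as positive.

    TP: drowsy predicted drowsy; FN: drowsy predicted alert;
    TN: alert predicted alert;  FP: alert predicted drowsy.
    """

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    @property
    def actual_positive(self) -> int:
        return self.TP + self.FN

    @property
    def actual_negative(self) -> int:
        return self.TN + self.FP

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FN + other.FN,
            self.TN + other.TN, self.FP + other.FP,
        )


def confusion(predicted: Sequence[int], actual: Sequence[int]) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be equal-length vectors")
    if len(predicted) == 0:
        raise ValueError("empty vectors")
    pos_pred = predicted == DROWSY_LABEL
    pos_act = actual == DROWSY_LABEL
    return ConfusionCounts(
        TP=int(np.sum(pos_pred & pos_act)),
        FN=int(np.sum(~pos_pred & pos_act)),
        TN=int(np.sum(~pos_pred & ~pos_act)),
        FP=int(np.sum(pos_pred & ~pos_act)),
    )


def accuracy_rate(c: ConfusionCounts) -> float:
    """Correctly detected time over total detection time."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.TP + c.TN) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """True positive time over total actual positive (drowsy) time."""
    if c.actual_positive == 0:
        raise ValueError("no actual drowsy time")
    return c.TP / c.actual_positive


def false_positive_rate(c: ConfusionCounts) -> float:
    """1 - TN / total actual negative = fraction of alert time flagged drowsy."""
    if c.actual_negative == 0:
        raise ValueError("no actual alert time")
    return 1.0 - c.TN / c.actual_negative


@dataclass
class SweepRow:
    channel: str
    r: int
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    false_positive_rate: float
    testing_time_s: float           # mean wall time per predicted second
    cv_fold_accuracies: List[float] = field(default_factory=list)

    def as_dict(self, percent: bool = False) -> Dict:
        k = 100.0 if percent else 1.0
        return {
            "channel": self.channel, "r": self.r,
            "accuracy": self.accuracy * k,
            "sensitivity": self.sensitivity * k,
            "false_positive_rate": self.false_positive_rate * k,
            "tp": self.counts.TP, "fn": self.counts.FN,
            "tn": self.counts.TN, "fp": self.counts.FP,
            "testing_time_s": self.testing_time_s,
        }


@dataclass
class EvaluationReport:
    rows: List[SweepRow]
    metadata: Dict = field(default_factory=dict)

    def row(self, r: int) -> SweepRow:
        for row in self.rows:
            if row.r == r:
                return row
        raise KeyError(f"no row for r={r}")

    def accuracies(self) -> Dict[int, float]:
        return {row.r: row.accuracy for row in self.rows}

    def as_records(self, percent: bool = False) -> List[Dict]:
        return [row.as_dict(percent) for row in self.rows]


def steady_state_mask(labels: np.ndarray, r: int) -> np.ndarray:
    """True for seconds t >= r whose window t-r..t lies in one state.

    The classifier rests on the assumption that the vigilance state is
    constant over the previous r seconds; at a state transition that
    assumption fails and the second has no well-defined label, so such
    seconds are excluded from training and scoring (recordings made as
    separate constant-state sessions contain none).
    """
    labels = np.asarray(labels, dtype=int)
    out = np.ones(len(labels) - r, dtype=bool)
    if r:
        for k, t in enumerate(range(r, len(labels))):
            out[k] = len(set(labels[t - r : t + 1].tolist())) == 1
    return out


def evaluate_channel(
    recording,
    labels: Sequence[int],
    channel: str,
    r: int,
    config: Optional[TrainingConfig] = None,
    bands=DEFAULT_BANDS,
    predenoised: bool = False,
    keep=DEFAULT_KEEP,
) -> SweepRow:
    """Denoise, featurise at window r and cross-validate one channel.

    Seconds whose averaging window straddles a state transition are dropped
    (see :func:`steady_state_mask`). Metrics are computed over the pooled
    held-out seconds of all usable folds. ``testing_time_s`` is the mean
    wall time to score one held-out second (decision function evaluation),
    reported but hardware-dependent.
    """
    config = config or TrainingConfig()
    rec = recording if predenoised else denoise(recording, keep)
    feats = extract_features(rec, labels, channel=channel, r=r, bands=bands)
    feats = feats.subset(steady_state_mask(labels, r))
    _, details = cross_validate(feats, config, return_details=True)
    y_true = np.concatenate([d["y_true"] for d in details])
    y_pred = np.concatenate([d["y_pred"] for d in details])
    c = confusion(y_pred, y_true)
    # time the decision function on the pooled held-out rows
    t0 = time.perf_counter()
    n_scored = 0
    for d in details:
        decision_values(d["model"], feats.X[d["test_idx"]])
        n_scored += len(d["test_idx"])
    per_second = (time.perf_counter() - t0) / max(n_scored, 1)
    return SweepRow(
        channel=channel, r=r, counts=c,
        accuracy=accuracy_rate(c),
        sensitivity=sensitivity(c),
        false_positive_rate=false_positive_rate(c),
        testing_time_s=per_second,
        cv_fold_accuracies=[d["accuracy"] for d in details],
    )


def r_sweep(
    recording,
    labels: Sequence[int],
    channel: str,
    r_values: Iterable[int] = (0, 1, 2, 3, 4),
    config: Optional[TrainingConfig] = None,
    bands=DEFAULT_BANDS,
    keep=DEFAULT_KEEP,
) -> EvaluationReport:
    """Run the pipeline for each time window r and collect metrics per r."""
    config = config or TrainingConfig()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both vigilance states must be present")
    r_values = sorted(set(int(r) for r in r_values))
    if recording.n_seconds < max(r_values) + config.folds:
        raise ValueError("recording too short for requested r values and folds")
    rec = denoise(recording, keep)   # denoise once, reuse across r
    rows = [
        evaluate_channel(rec, labels, channel, r, config, bands,
                         predenoised=True)
        for r in r_values
    ]
    return EvaluationReport(
        rows=rows,
        metadata={
            "channel": channel,
            "r_values": r_values,
            "C": config.C, "g": config.g, "kernel": config.kernel,
            "folds": config.folds,
            "seed": recording.meta.get("seed"),
        },
    )
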