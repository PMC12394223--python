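"""Open-set evaluation: FPR@TPR95, AUROC and closed-set accuracy.

Orientation is fixed project-wide: **known samples are the positive
class**.  A known sample is accepted (true positive) when its uncertainty
score S satisfies S ≤ λ; an unknown sample with S ≤ λ is a false positive.
The threshold λ is the smallest order statistic of the known scores that
achieves the target true-positive rate (default 0.95), so exact level
attainment is not required at small n — the achieved TPR is reported.

AUROC is the probability that an unknown sample's uncertainty score
exceeds a known sample's, with half credit for ties (the Mann-Whitney
convention); it is threshold-free and invariant under any strictly
increasing transform of the scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .containers import ScoreVector
from .exceptions import InputError, ParameterError


def _as_scores(x) -> np.ndarray:
    vals = x.values if isinstance(x, ScoreVector) else np.asarray(x, dtype=float)
    vals = np.asarray(vals, dtype=float)
    if vals.ndim != 1:
        raise InputError("scores must be one-dimensional")
    if not np.all(np.isfinite(vals)):
        raise InputError("scores must be finite")
    return vals


@dataclass(frozen=True)
class DecisionConfig:
    """How the rejection threshold λ is chosen.

    Either λ is derived from the known scores at ``tpr_level`` (default),
    or a fixed ``lambda_override`` is used directly.
    """

    tpr_level: float = 0.95
    lambda_override: float | None = None

    def __post_init__(self):
        if not (0.0 < self.tpr_level <= 1.0):
            raise ParameterError(
                f"tpr_level must be in (0, 1], got {self.tpr_level}"
            )
        if self.lambda_override is not None and not math.isfinite(
            self.lambda_override
        ):
            raise ParameterError("lambda_override must be finite")


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation summary at a single operating point."""

    fpr_at_tpr95: float
    auroc: float
    accuracy_known: float
    lambda_used: float
    tpr_level: float
    achieved_tpr: float
    confusion: dict[str, int]
    n_known: int
    n_unknown: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def threshold_at_tpr(known_scores, level: float = 0.95) -> float:
    """Smallest λ accepting at least a ``level`` fraction of known samples.

    λ is the k-th smallest known score with k = ceil(level · n_known);
    since acceptance is S ≤ λ, this guarantees TPR ≥ level and no smaller
    order statistic does.
    """
    known = _as_scores(known_scores)
    if known.size == 0:
        raise InputError("known score set is empty")
    if not (0.0 < level <= 1.0):
        raise ParameterError(f"level must be in (0, 1], got {level}")
    k = math.ceil(level * known.size)
    return float(np.sort(known)[k - 1])


def fpr_at_tpr(known_scores, unknown_scores, level: float = 0.95) -> float:
    """False-positive rate on unknowns at the TPR-derived threshold."""
    known = _as_scores(known_scores)
    unknown = _as_scores(unknown_scores)
    if unknown.size == 0:
        raise InputError("unknown score set is empty")
    lam = threshold_at_tpr(known, level)
    return float(np.mean(unknown <= lam))


def auroc(known_scores, unknown_scores) -> float:
    """P(S_unknown > S_known) + ½ P(S_unknown = S_known), rank-based."""
    known = _as_scores(known_scores)
    unknown = _as_scores(unknown_scores)
    if known.size == 0 or unknown.size == 0:
        raise InputError("both known and unknown score sets must be non-empty")
    y = np.concatenate([np.zeros(known.size), np.ones(unknown.size)])
    s = np.concatenate([known, unknown])
    return float(roc_auc_score(y, s))


def closed_set_accuracy(
    predicted_class: Sequence, true_class: Sequence
) -> float:
    """Fraction of known-labelled samples whose class is predicted right."""
    pred = np.asarray(predicted_class)
    true = np.asarray(true_class)
    if pred.size == 0:
        raise InputError("closed-set accuracy needs at least one known sample")
    if pred.shape != true.shape:
        raise InputError(
            f"prediction/label length mismatch: {pred.shape} vs {true.shape}"
        )
    return float(np.mean(pred == true))


def confusion_at(known_scores, unknown_scores, lam: float) -> dict[str, int]:
    """TP/FN/FP/TN counts at threshold λ (known = positive, accept S ≤ λ)."""
    known = _as_scores(known_scores)
    unknown = _as_scores(unknown_scores)
    tp = int(np.sum(known <= lam))
    fp = int(np.sum(unknown <= lam))
    return {
        "TP": tp,
        "FN": int(known.size - tp),
        "FP": fp,
        "TN": int(unknown.size - fp),
    }


def evaluate_scores(
    known_scores,
    unknown_scores,
    predicted_class: Sequence,
    true_class: Sequence,
    config: DecisionConfig = DecisionConfig(),
) -> MetricsReport:
    """Full open-set report: FPR@TPR, AUROC, accuracy, confusion at λ."""
    known = _as_scores(known_scores)
    unknown = _as_scores(unknown_scores)
    if known.size == 0 or unknown.size == 0:
        raise InputError("both known and unknown score sets must be non-empty")
    if config.lambda_override is not None:
        lam = float(config.lambda_override)
    else:
        lam = threshold_at_tpr(known, config.tpr_level)
    conf = confusion_at(known, unknown, lam)
    return MetricsReport(
        fpr_at_tpr95=fpr_at_tpr(known, unknown, config.tpr_level),
        auroc=auroc(known, unknown),
        accuracy_known=closed_set_accuracy(predicted_class, true_class),
        lambda_used=lam,
        tpr_level=config.tpr_level,
        achieved_tpr=conf["TP"] / known.size,
        confusion=conf,
        n_known=int(known.size),
        n_unknown=int(unknown.size),
    )
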