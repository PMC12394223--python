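"""Open-set experiment mechanics.

This module ties the scoring and metrics layers together: it validates
that known and unknown class sets are disjoint, subsamples M-shot
training banks reproducibly, and runs the full knowledge-ensemble
scoring loop — compute the category-prediction score, the
domain-specific (fine-tuned space) and general-knowledge (pretrained
space) feature-matching scores, fuse them, threshold, and evaluate.

Few-shot subsampling uses a seeded per-class shuffle with prefix
selection, so shot counts are nested: the 2-shot bank is a subset of the
4-shot bank, which is a subset of the 8-shot bank, and so on.  This
makes shot-ablation sweeps monotone in the data they condition on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    EmbeddingMatrix,
    EnsembleSpec,
    FeatureBank,
    LogitMatrix,
    ScoreVector,
    TextEmbeddings,
)
from .exceptions import (
    AlignmentError,
    ConfigurationError,
    InputError,
    ParameterError,
    ProtocolError,
)
from .metrics import DecisionConfig, MetricsReport, evaluate_scores
from .scoring import (
    _cosine_to_rows,
    cpd_score,
    dsk_score,
    ensemble_score,
    gk_score,
)

ALL_SHOTS = "all"
PAPER_SHOT_PRESETS = (2, 4, 8, 16)


@dataclass(frozen=True)
class OpenSetSplit:
    """Disjoint known and unknown class sets."""

    known_classes: frozenset[str]
    unknown_classes: frozenset[str]

    def __init__(self, known_classes, unknown_classes):
        object.__setattr__(
            self, "known_classes", frozenset(str(c) for c in known_classes)
        )
        object.__setattr__(
            self, "unknown_classes", frozenset(str(c) for c in unknown_classes)
        )


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample membership ('known'/'unknown') and class label."""

    sample_ids: tuple[str, ...]
    membership: tuple[str, ...]
    class_label: tuple[str, ...]

    def __init__(self, sample_ids, membership, class_label):
        ids = tuple(str(s) for s in sample_ids)
        mem = tuple(str(m) for m in membership)
        lab = tuple(str(c) for c in class_label)
        if not (len(ids) == len(mem) == len(lab)):
            raise InputError("GroundTruth: column lengths differ")
        if len(set(ids)) != len(ids):
            raise InputError("GroundTruth: duplicate sample ids")
        bad = set(mem) - {"known", "unknown"}
        if bad:
            raise InputError(
                f"GroundTruth: membership must be 'known'/'unknown', "
                f"got {sorted(bad)}"
            )
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "membership", mem)
        object.__setattr__(self, "class_label", lab)

    @property
    def known_ids(self) -> tuple[str, ...]:
        return tuple(
            s for s, m in zip(self.sample_ids, self.membership) if m == "known"
        )

    @property
    def unknown_ids(self) -> tuple[str, ...]:
        return tuple(
            s for s, m in zip(self.sample_ids, self.membership) if m == "unknown"
        )

    def label_of(self, sample_id: str) -> str:
        return self.class_label[self.sample_ids.index(sample_id)]


@dataclass(frozen=True)
class ShotConfig:
    """Number of training samples kept per known class.

    ``shots`` is a positive integer (the benchmark presets are 2, 4, 8
    and 16, but any positive value is accepted) or the string ``"all"``
    to keep the full bank.
    """

    shots: int | str = ALL_SHOTS
    seed: int = 0

    def __post_init__(self):
        if self.shots != ALL_SHOTS:
            if not isinstance(self.shots, (int, np.integer)) or self.shots < 1:
                raise ParameterError(
                    f"shots must be a positive integer or 'all', "
                    f"got {self.shots!r}"
                )


def validate_split(split: OpenSetSplit) -> OpenSetSplit:
    """Check K ∩ U = ∅ and both sides non-empty; return split unchanged."""
    overlap = split.known_classes & split.unknown_classes
    if overlap:
        raise ProtocolError(
            f"known and unknown classes must be disjoint; overlap: "
            f"{sorted(overlap)}"
        )
    if not split.known_classes:
        raise ProtocolError("known class set is empty")
    if not split.unknown_classes:
        raise ProtocolError("unknown class set is empty")
    return split


def few_shot_subsample(bank: FeatureBank, config: ShotConfig) -> FeatureBank:
    """Keep exactly M rows per class, seeded and nested across M.

    Each class's rows are shuffled by a stream derived from (seed, class
    name) and the first M are kept, so increasing M only ever adds rows.
    """
    if config.shots == ALL_SHOTS:
        return bank
    m = int(config.shots)
    labels = np.asarray(bank.class_of_row)
    keep: list[int] = []
    for cls in sorted(set(bank.class_of_row)):
        rows = np.flatnonzero(labels == cls)
        if rows.size < m:
            raise InputError(
                f"class {cls!r} has only {rows.size} bank rows, "
                f"fewer than shots={m}"
            )
        # per-class substream keyed by the class name: deterministic and
        # independent of the other classes' row counts
        digest = np.frombuffer(
            cls.encode("utf-8").ljust(8, b"\0")[:8], dtype=np.uint32
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, *map(int, digest)])
        )
        order = rng.permutation(rows.size)
        keep.extend(int(rows[i]) for i in order[:m])
    keep.sort()
    return bank.select_rows(np.asarray(keep))


def _check_bank_purity(
    bank: FeatureBank,
    truth: GroundTruth,
    split: OpenSetSplit | None,
    which: str,
) -> None:
    bank_classes = set(bank.class_of_row)
    if split is not None:
        validate_split(split)
        offending = bank_classes - split.known_classes
    else:
        unknown_labels = {
            c for c, m in zip(truth.class_label, truth.membership)
            if m == "unknown"
        }
        offending = bank_classes & unknown_labels
    if offending:
        raise ProtocolError(
            f"{which} bank contains unknown-class rows: {sorted(offending)}"
        )


@dataclass(frozen=True)
class EnsembleResult:
    """Scores and metrics from one knowledge-ensemble run.

    ``components`` maps score kind (cpd/dsk/gk) to its normalized score
    vector; ``component_reports`` holds the single-component ablation
    metrics evaluated under the same decision config as the ensemble.
    """

    final: ScoreVector
    components: dict[str, ScoreVector]
    report: MetricsReport
    component_reports: dict[str, MetricsReport]
    predictions: dict[str, str]


def _predict_classes(
    test_logits: LogitMatrix | None,
    test_feats_ft: EmbeddingMatrix | None,
    text_feats: TextEmbeddings | None,
    spec: EnsembleSpec,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Closed-set predictions: argmax logits, or argmax text similarity."""
    vlm = spec.mode in ("vlm_two_way", "vlm_three_way") or (
        spec.base_cpd_method == "mcm"
    )
    if vlm and text_feats is not None and test_feats_ft is not None:
        sims = _cosine_to_rows(test_feats_ft.values, text_feats.values)
        idx = sims.argmax(axis=1)
        names = np.asarray(text_feats.class_names)
        return test_feats_ft.sample_ids, names[idx]
    if test_logits is not None:
        idx = test_logits.values.argmax(axis=1)
        names = np.asarray(test_logits.class_names)
        return test_logits.sample_ids, names[idx]
    raise ConfigurationError(
        "cannot predict known classes: need logits or text embeddings"
    )


def run_knowledge_ensemble(
    test_logits: LogitMatrix | None,
    test_feats_ft: EmbeddingMatrix,
    test_feats_pt: EmbeddingMatrix,
    bank_ft: FeatureBank,
    bank_pt: FeatureBank,
    truth: GroundTruth,
    spec: EnsembleSpec = EnsembleSpec.visual_three_way(),
    decision: DecisionConfig = DecisionConfig(),
    text_feats: TextEmbeddings | None = None,
    temperature: float = 1.0,
    split: OpenSetSplit | None = None,
) -> EnsembleResult:
    """End-to-end knowledge-ensemble scoring and evaluation.

    Computes the components required by ``spec`` — category-prediction
    (cpd) from logits or concept matching, domain-specific knowledge
    (dsk) against the fine-tuned bank, general knowledge (gk) against
    the pretrained bank — fuses them by arithmetic mean, thresholds at
    the TPR-derived λ and reports metrics for the ensemble and for each
    component alone.
    """
    _check_bank_purity(bank_ft, truth, split, "fine-tuned")
    _check_bank_purity(bank_pt, truth, split, "pretrained")
    ids = test_feats_ft.sample_ids
    if test_feats_pt.sample_ids != ids:
        raise AlignmentError(
            "fine-tuned and pretrained test features list different samples"
        )
    if tuple(truth.sample_ids) != ids:
        raise AlignmentError("ground truth does not match test sample ids")
    if test_logits is not None and test_logits.sample_ids != ids:
        raise AlignmentError("logits do not match test sample ids")

    components: dict[str, ScoreVector] = {}
    if "cpd" in spec.components:
        if spec.base_cpd_method == "mcm":
            if text_feats is None:
                raise ConfigurationError(
                    "ensemble with concept-matching cpd requires text "
                    "embeddings"
                )
            components["cpd"] = cpd_score(
                test_feats_ft, "mcm", temperature, text_feats
            )
        else:
            if test_logits is None:
                raise ConfigurationError(
                    f"cpd method {spec.base_cpd_method!r} requires logits"
                )
            components["cpd"] = cpd_score(
                test_logits, spec.base_cpd_method, temperature
            )
    if "dsk" in spec.components:
        components["dsk"] = dsk_score(test_feats_ft, bank_ft)
    if "gk" in spec.components:
        components["gk"] = gk_score(test_feats_pt, bank_pt)
    missing = set(spec.components) - set(components)
    if missing:
        raise ConfigurationError(
            f"cannot compute components {sorted(missing)} for mode "
            f"{spec.mode!r}"
        )

    final = ensemble_score(
        [components[k] for k in spec.components], spec
    )

    pred_ids, pred_classes = _predict_classes(
        test_logits, test_feats_ft, text_feats, spec
    )
    pred_map = dict(zip(pred_ids, (str(c) for c in pred_classes)))

    known_ids = truth.known_ids
    unknown_ids = truth.unknown_ids
    label_map = dict(zip(truth.sample_ids, truth.class_label))
    pred_known = [pred_map[s] for s in known_ids]
    true_known = [label_map[s] for s in known_ids]

    def _report(scores: ScoreVector) -> MetricsReport:
        return evaluate_scores(
            scores.subset(known_ids),
            scores.subset(unknown_ids),
            pred_known,
            true_known,
            decision,
        )

    return EnsembleResult(
        final=final,
        components=components,
        report=_report(final),
        component_reports={k: _report(v) for k, v in components.items()},
        predictions=pred_map,
    )


def export_score_distributions(
    scores: ScoreVector, truth: GroundTruth, bins: int = 20
) -> pd.DataFrame:
    """Histogram of scores per membership group, as a tidy table.

    Bins span [0, 1] for normalized scores and [min, max] otherwise.
    Columns: membership, bin, lower, upper, count; within each group the
    counts sum to that group's sample count.
    """
    if bins < 2:
        raise ParameterError(f"bins must be >= 2, got {bins}")
    if scores.sample_ids != tuple(truth.sample_ids):
        raise AlignmentError("scores and ground truth list different samples")
    if scores.normalized:
        lo, hi = 0.0, 1.0
    else:
        lo, hi = float(scores.values.min()), float(scores.values.max())
        if hi == lo:
            hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    rows = []
    mem = np.asarray(truth.membership)
    for group in ("known", "unknown"):
        vals = scores.values[mem == group]
        counts, _ = np.histogram(vals, bins=edges)
        for b in range(bins):
            rows.append(
                {
                    "membership": group,
                    "bin": b,
                    "lower": edges[b],
                    "upper": edges[b + 1],
                    "count": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)
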