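"""Typed in-memory containers.

The toolkit operates on four kinds of numeric tables — classifier logits,
image-encoder embeddings, training feature banks and per-class text
embeddings — plus per-sample uncertainty scores.  Each container validates
its invariants at construction so downstream code can assume clean data.

Embeddings carry a ``space_tag`` naming the encoder that produced them:
``"finetuned"`` for the task-adapted model and ``"pretrained"`` for the
frozen original.  Scores computed by matching features may only compare
query and bank tensors from the same space; the tag makes mixing them a
hard error instead of a silent bug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import AlignmentError, InputError, ParameterError

FINETUNED = "finetuned"
PRETRAINED = "pretrained"
SPACE_TAGS = (FINETUNED, PRETRAINED)

SCORE_KINDS = ("max_logit", "energy", "mcm", "cpd", "dsk", "gk", "ensemble")

#: canonical component sets for the three named fusion modes
MODE_COMPONENTS = {
    "visual_three_way": frozenset({"cpd", "dsk", "gk"}),
    "vlm_two_way": frozenset({"dsk", "gk"}),
    "vlm_three_way": frozenset({"cpd", "dsk", "gk"}),
}

CPD_METHODS = ("msp", "raw_maxlogit", "energy", "mcm")


def _check_ids(sample_ids: Sequence[str], n: int, what: str) -> tuple[str, ...]:
    ids = tuple(str(s) for s in sample_ids)
    if len(ids) != n:
        raise InputError(
            f"{what}: {len(ids)} sample ids for {n} rows"
        )
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(s for s in ids if s in seen or seen.add(s))
        raise InputError(f"{what}: duplicate sample id {dup!r}")
    return ids


def _as_matrix(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InputError(f"{what}: expected a 2-d matrix, got ndim={arr.ndim}")
    if arr.shape[0] < 1:
        raise InputError(f"{what}: needs at least one row")
    if not np.all(np.isfinite(arr)):
        bad = int(np.argwhere(~np.isfinite(arr).all(axis=1))[0, 0])
        raise InputError(f"{what}: non-finite value in row {bad}")
    return arr


@dataclass(frozen=True)
class LogitMatrix:
    """Per-sample logits over the K known classes (rows = samples)."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    class_names: tuple[str, ...]

    def __init__(self, sample_ids, values, class_names):
        values = _as_matrix(values, "LogitMatrix")
        ids = _check_ids(sample_ids, values.shape[0], "LogitMatrix")
        names = tuple(str(c) for c in class_names)
        if len(names) != values.shape[1]:
            raise InputError(
                f"LogitMatrix: {len(names)} class names for "
                f"{values.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise InputError("LogitMatrix: class names must be unique")
        if len(names) < 1:
            raise InputError("LogitMatrix: needs at least one class")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "class_names", names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Image-encoder features for a set of samples, tagged by model space.

    Zero-norm rows are rejected at construction: cosine similarity is
    undefined at the origin, and every downstream use is cosine-based.
    """

    sample_ids: tuple[str, ...]
    values: np.ndarray
    space_tag: str
    l2_normalized: bool = False

    def __init__(self, sample_ids, values, space_tag, l2_normalized=False):
        values = _as_matrix(values, "EmbeddingMatrix")
        ids = _check_ids(sample_ids, values.shape[0], "EmbeddingMatrix")
        if space_tag not in SPACE_TAGS:
            raise ParameterError(
                f"space_tag must be one of {SPACE_TAGS}, got {space_tag!r}"
            )
        norms = np.linalg.norm(values, axis=1)
        if np.any(norms == 0.0):
            bad = ids[int(np.argmax(norms == 0.0))]
            raise InputError(f"EmbeddingMatrix: zero-norm row {bad!r}")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "space_tag", str(space_tag))
        object.__setattr__(self, "l2_normalized", bool(l2_normalized))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def normalized(self) -> "EmbeddingMatrix":
        """Return a copy with unit-norm rows (idempotent)."""
        if self.l2_normalized:
            return self
        norms = np.linalg.norm(self.values, axis=1, keepdims=True)
        return EmbeddingMatrix(
            self.sample_ids, self.values / norms, self.space_tag, True
        )


@dataclass(frozen=True)
class FeatureBank:
    """Training-set embeddings, one known-class label per row."""

    embeddings: EmbeddingMatrix
    class_of_row: tuple[str, ...]

    def __init__(self, embeddings: EmbeddingMatrix, class_of_row):
        labels = tuple(str(c) for c in class_of_row)
        if len(labels) != embeddings.n_samples:
            raise InputError(
                f"FeatureBank: {len(labels)} labels for "
                f"{embeddings.n_samples} rows"
            )
        object.__setattr__(self, "embeddings", embeddings)
        object.__setattr__(self, "class_of_row", labels)

    @property
    def space_tag(self) -> str:
        return self.embeddings.space_tag

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.class_of_row)))

    def select_rows(self, index: np.ndarray) -> "FeatureBank":
        emb = self.embeddings
        return FeatureBank(
            EmbeddingMatrix(
                [emb.sample_ids[i] for i in index],
                emb.values[index],
                emb.space_tag,
                emb.l2_normalized,
            ),
            [self.class_of_row[i] for i in index],
        )


@dataclass(frozen=True)
class TextEmbeddings:
    """One text-encoder embedding per known class (VLM concept vectors)."""

    class_names: tuple[str, ...]
    values: np.ndarray

    def __init__(self, class_names, values):
        values = _as_matrix(values, "TextEmbeddings")
        names = tuple(str(c) for c in class_names)
        if len(names) != values.shape[0]:
            raise InputError(
                f"TextEmbeddings: {len(names)} class names for "
                f"{values.shape[0]} rows"
            )
        if len(set(names)) != len(names):
            raise InputError("TextEmbeddings: class names must be unique")
        norms = np.linalg.norm(values, axis=1)
        if np.any(norms == 0.0):
            bad = names[int(np.argmax(norms == 0.0))]
            raise InputError(f"TextEmbeddings: zero-norm row for class {bad!r}")
        object.__setattr__(self, "class_names", names)
        object.__setattr__(self, "values", values)

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample uncertainty scores; higher always means more anomalous."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    score_kind: str
    normalized: bool = False
    temperature: float = 1.0

    def __init__(self, sample_ids, values, score_kind,
                 normalized=False, temperature=1.0):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise InputError("ScoreVector: values must be 1-d")
        if values.shape[0] < 1:
            raise InputError("ScoreVector: needs at least one score")
        if not np.all(np.isfinite(values)):
            raise InputError("ScoreVector: non-finite score")
        ids = _check_ids(sample_ids, values.shape[0], "ScoreVector")
        if score_kind not in SCORE_KINDS:
            raise ParameterError(
                f"score_kind must be one of {SCORE_KINDS}, got {score_kind!r}"
            )
        if temperature <= 0:
            raise ParameterError(f"temperature must be > 0, got {temperature}")
        if normalized and (values.min() < 0.0 or values.max() > 1.0):
            raise InputError(
                "ScoreVector: normalized scores must lie in [0, 1]"
            )
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "score_kind", str(score_kind))
        object.__setattr__(self, "normalized", bool(normalized))
        object.__setattr__(self, "temperature", float(temperature))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        """Score values for the given ids, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            index = [pos[s] for s in ids]
        except KeyError as exc:
            raise AlignmentError(
                f"sample id {exc.args[0]!r} not present in scores"
            ) from None
        return self.values[index]


@dataclass(frozen=True)
class EnsembleSpec:
    """Which components are fused and how the category branch is scored.

    ``visual_three_way`` averages the category-prediction, domain-specific
    and general-knowledge scores (CNN/ViT deployments).  ``vlm_two_way``
    drops the category branch and averages only the two feature-similarity
    scores, the recommended configuration for vision-language models.
    ``vlm_three_way`` keeps the concept-matching score as the category
    branch alongside both similarity scores.
    """

    mode: str = "visual_three_way"
    components: tuple[str, ...] = ()
    base_cpd_method: str = "msp"

    def __post_init__(self):
        if self.base_cpd_method not in CPD_METHODS:
            raise ParameterError(
                f"base_cpd_method must be one of {CPD_METHODS}, "
                f"got {self.base_cpd_method!r}"
            )
        if self.mode in MODE_COMPONENTS:
            expected = MODE_COMPONENTS[self.mode]
            comps = self.components or tuple(sorted(expected))
            if frozenset(comps) != expected:
                raise ParameterError(
                    f"mode {self.mode!r} requires components "
                    f"{sorted(expected)}, got {sorted(comps)}"
                )
            object.__setattr__(self, "components", tuple(comps))
        elif self.mode == "custom":
            if not self.components:
                raise ParameterError("custom mode requires explicit components")
            if len(set(self.components)) != len(self.components):
                raise ParameterError("components must be distinct")
            unknown = set(self.components) - set(SCORE_KINDS)
            if unknown:
                raise ParameterError(f"unknown component kinds {sorted(unknown)}")
        else:
            raise ParameterError(
                "mode must be visual_three_way, vlm_two_way, vlm_three_way "
                f"or custom, got {self.mode!r}"
            )
        if self.mode == "vlm_three_way" and self.base_cpd_method != "mcm":
            object.__setattr__(self, "base_cpd_method", "mcm")

    @classmethod
    def visual_three_way(cls, base_cpd_method: str = "msp") -> "EnsembleSpec":
        return cls("visual_three_way", base_cpd_method=base_cpd_method)

    @classmethod
    def vlm_two_way(cls) -> "EnsembleSpec":
        return cls("vlm_two_way")

    @classmethod
    def vlm_three_way(cls) -> "EnsembleSpec":
        return cls("vlm_three_way", base_cpd_method="mcm")
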