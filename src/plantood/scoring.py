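"""Uncertainty scores and their fusion.

Every score follows one convention: **higher = more anomalous**.  A test
sample is rejected as unknown-class when its fused score exceeds a
threshold λ (``decide``); a score exactly equal to λ is accepted as known.

Three families of scores are provided:

* Category-prediction scores computed from classifier logits or from
  image-text concept matching: ``max_logit_score`` (negative maximum
  softmax probability by default), ``energy_score`` (negative
  log-sum-exp of temperature-scaled logits) and ``mcm_score`` (negative
  maximum softmax over image-text cosine similarities).
* Feature-matching scores: ``knn_dissimilarity`` is the negative maximum
  cosine similarity between a test embedding and a bank of training
  embeddings.  Applied in the fine-tuned encoder space it yields the
  domain-specific knowledge score (``dsk_score``); in the frozen
  pretrained space, the general-knowledge score (``gk_score``).
* The knowledge ensemble: each component is min-max normalized to [0, 1]
  over the evaluated sample set and the normalized components are
  averaged element-wise (``ensemble_score``).

Normalization is transductive — min and max are taken over the full score
set being jointly evaluated.  ``MinMaxNormalizer`` offers a
frozen-statistics alternative for single-sample deployment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, softmax

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
    DegenerateInputError,
    InputError,
    ParameterError,
    ProtocolError,
)

MAX_LOGIT_DIALECTS = ("msp", "raw_maxlogit", "literal")


def _check_temperature(temperature: float) -> float:
    if not np.isfinite(temperature) or temperature <= 0:
        raise ParameterError(f"temperature must be > 0, got {temperature}")
    return float(temperature)


def max_logit_score(
    logits: LogitMatrix,
    temperature: float = 1.0,
    dialect: str = "msp",
) -> ScoreVector:
    """Negative maximum-confidence score from classification logits.

    Dialects:

    ``msp``
        −max softmax(z/T): the maximum-softmax-probability convention,
        safe for arbitrary logits (default).
    ``raw_maxlogit``
        −max z: the raw max-logit score; temperature has no effect on
        the ranking and is ignored.
    ``literal``
        −max of (z/T) divided by the plain (non-exponentiated) row sum
        Σ z/T.  Undefined when a row sums to zero, which is rejected.
    """
    T = _check_temperature(temperature)
    if dialect not in MAX_LOGIT_DIALECTS:
        raise ParameterError(
            f"dialect must be one of {MAX_LOGIT_DIALECTS}, got {dialect!r}"
        )
    z = logits.values
    if dialect == "msp":
        scores = -softmax(z / T, axis=1).max(axis=1)
    elif dialect == "raw_maxlogit":
        scores = -z.max(axis=1)
    else:  # literal
        scaled = z / T
        sums = scaled.sum(axis=1)
        zero = sums == 0.0
        if np.any(zero):
            bad = logits.sample_ids[int(np.argmax(zero))]
            raise DegenerateInputError(
                f"literal dialect undefined: row {bad!r} has zero logit sum"
            )
        scores = -(scaled / sums[:, None]).max(axis=1)
    return ScoreVector(
        logits.sample_ids, scores, "max_logit", normalized=False,
        temperature=T,
    )


def energy_score(logits: LogitMatrix, temperature: float = 1.0) -> ScoreVector:
    """Energy score −log Σ_i exp(z_i / T), overflow-safe via log-sum-exp.

    With a single class this reduces exactly to −z/T.  The default T=1.
    """
    T = _check_temperature(temperature)
    scores = -logsumexp(logits.values / T, axis=1)
    return ScoreVector(
        logits.sample_ids, scores, "energy", normalized=False, temperature=T
    )


def _cosine_to_rows(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between unit-normalized row sets."""
    qn = query / np.linalg.norm(query, axis=1, keepdims=True)
    rn = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    return qn @ rn.T


def mcm_score(
    image_feats: EmbeddingMatrix,
    text_feats: TextEmbeddings,
    temperature: float = 1.0,
) -> ScoreVector:
    """Concept-matching score: −max softmax over image-text cosine sims.

    Known-class images should sit close to their class's text embedding,
    so they receive a confident (low) score; unknown-class images match
    no concept strongly and score higher.
    """
    T = _check_temperature(temperature)
    if image_feats.dim != text_feats.dim:
        raise InputError(
            f"dimension mismatch: image d={image_feats.dim}, "
            f"text d={text_feats.dim}"
        )
    sims = _cosine_to_rows(image_feats.values, text_feats.values)
    scores = -softmax(sims / T, axis=1).max(axis=1)
    return ScoreVector(
        image_feats.sample_ids, scores, "mcm", normalized=False, temperature=T
    )


def knn_dissimilarity(query: EmbeddingMatrix, bank: FeatureBank) -> ScoreVector:
    """Negative nearest-neighbour cosine similarity to the training bank.

    Raw score in [−1, 1]; a query duplicating a bank row scores exactly −1.
    Query and bank must come from the same encoder space.
    """
    if bank.embeddings.n_samples < 1:
        raise InputError("feature bank is empty")
    if query.space_tag != bank.space_tag:
        raise ProtocolError(
            f"space tag mismatch: query is {query.space_tag!r}, "
            f"bank is {bank.space_tag!r}; refusing to mix encoder spaces"
        )
    if query.dim != bank.embeddings.dim:
        raise InputError(
            f"dimension mismatch: query d={query.dim}, "
            f"bank d={bank.embeddings.dim}"
        )
    sims = _cosine_to_rows(query.values, bank.embeddings.values)
    # clip numerical spill so the documented [-1, 1] range is exact
    scores = -np.clip(sims.max(axis=1), -1.0, 1.0)
    kind = "dsk" if query.space_tag == "finetuned" else "gk"
    return ScoreVector(query.sample_ids, scores, kind, normalized=False)


@dataclass(frozen=True)
class MinMaxNormalizer:
    """Frozen min-max statistics, for normalizing one sample at a time.

    Fit on a calibration score set; ``transform`` then maps new scores
    with the stored min/max, clipping into [0, 1].  The transductive
    default (:func:`minmax_normalize`) should be preferred whenever the
    whole evaluation set is available at once.
    """

    lo: float
    hi: float

    @classmethod
    def fit(cls, scores: ScoreVector) -> "MinMaxNormalizer":
        return cls(float(scores.values.min()), float(scores.values.max()))

    def transform(self, scores: ScoreVector) -> ScoreVector:
        if self.hi == self.lo:
            vals = np.full(scores.n_samples, 0.5)
        else:
            vals = np.clip(
                (scores.values - self.lo) / (self.hi - self.lo), 0.0, 1.0
            )
        return ScoreVector(
            scores.sample_ids, vals, scores.score_kind,
            normalized=True, temperature=scores.temperature,
        )


def minmax_normalize(scores: ScoreVector) -> ScoreVector:
    """Min-max scale scores into [0, 1] over the full evaluated set.

    Strictly increasing, hence rank-preserving: threshold-free metrics
    (AUROC) are identical before and after.  When all scores are equal
    the output is the constant 0.5, so a degenerate component contributes
    nothing to the ensemble ranking rather than poisoning it with NaN.
    """
    return MinMaxNormalizer.fit(scores).transform(scores)


def cpd_score(
    source: LogitMatrix | EmbeddingMatrix | ScoreVector,
    method: str = "msp",
    temperature: float = 1.0,
    text_feats: TextEmbeddings | None = None,
) -> ScoreVector:
    """Category-prediction-distribution score, normalized to [0, 1].

    ``source`` is a :class:`LogitMatrix` for the logit-based methods
    (``msp``, ``raw_maxlogit``, ``energy``), an :class:`EmbeddingMatrix`
    of image features (with ``text_feats``) for ``mcm``, or an already
    computed base :class:`ScoreVector` to be normalized as-is.
    """
    if isinstance(source, ScoreVector):
        base = source
    elif method == "mcm":
        if text_feats is None:
            raise ConfigurationError(
                "cpd method 'mcm' requires text embeddings"
            )
        if not isinstance(source, EmbeddingMatrix):
            raise ConfigurationError(
                "cpd method 'mcm' requires image embeddings as source"
            )
        base = mcm_score(source, text_feats, temperature)
    elif method in ("msp", "raw_maxlogit"):
        if not isinstance(source, LogitMatrix):
            raise ConfigurationError(f"cpd method {method!r} requires logits")
        base = max_logit_score(source, temperature, dialect=method)
    elif method == "energy":
        if not isinstance(source, LogitMatrix):
            raise ConfigurationError("cpd method 'energy' requires logits")
        base = energy_score(source, temperature)
    else:
        raise ParameterError(f"unknown cpd method {method!r}")
    norm = minmax_normalize(base)
    return ScoreVector(
        norm.sample_ids, norm.values, "cpd",
        normalized=True, temperature=norm.temperature,
    )


def dsk_score(
    test_feats: EmbeddingMatrix, bank: FeatureBank
) -> ScoreVector:
    """Domain-specific knowledge score (fine-tuned encoder space)."""
    if test_feats.space_tag != "finetuned":
        raise ProtocolError(
            f"dsk_score requires fine-tuned-space features, "
            f"got {test_feats.space_tag!r}"
        )
    raw = knn_dissimilarity(test_feats, bank)
    norm = minmax_normalize(raw)
    return ScoreVector(norm.sample_ids, norm.values, "dsk", normalized=True)


def gk_score(
    test_feats: EmbeddingMatrix, bank: FeatureBank
) -> ScoreVector:
    """General-knowledge score (frozen pretrained encoder space)."""
    if test_feats.space_tag != "pretrained":
        raise ProtocolError(
            f"gk_score requires pretrained-space features, "
            f"got {test_feats.space_tag!r}"
        )
    raw = knn_dissimilarity(test_feats, bank)
    norm = minmax_normalize(raw)
    return ScoreVector(norm.sample_ids, norm.values, "gk", normalized=True)


def ensemble_score(
    components: Sequence[ScoreVector], spec: EnsembleSpec
) -> ScoreVector:
    """Element-wise mean of normalized component scores.

    Components are aligned by sample id (which must agree in content and
    order; reordering is never done silently) and must match the kinds
    declared by ``spec``.  The fusion itself is non-parametric: a plain
    arithmetic mean, invariant to the order of the components.
    """
    if not components:
        raise ParameterError("ensemble requires at least one component")
    kinds = tuple(c.score_kind for c in components)
    if len(set(kinds)) != len(kinds):
        raise ProtocolError(f"duplicate component kinds {kinds}")
    if frozenset(kinds) != frozenset(spec.components):
        raise ProtocolError(
            f"component kinds {sorted(kinds)} do not match spec "
            f"{sorted(spec.components)}"
        )
    for c in components:
        if not c.normalized:
            raise ProtocolError(
                f"component {c.score_kind!r} is not normalized; fuse only "
                "min-max normalized scores"
            )
    ref = components[0].sample_ids
    for c in components[1:]:
        if c.sample_ids != ref:
            raise AlignmentError(
                f"sample ids of component {c.score_kind!r} do not match "
                f"component {components[0].score_kind!r}"
            )
    stacked = np.stack([c.values for c in components])
    return ScoreVector(ref, stacked.mean(axis=0), "ensemble", normalized=True)


def decide(scores: ScoreVector, lam: float) -> np.ndarray:
    """Threshold rule: unknown iff S(x) > λ, known iff S(x) ≤ λ."""
    if not np.isfinite(lam):
        raise ParameterError(f"lambda must be finite, got {lam}")
    return np.where(scores.values > lam, "unknown", "known")
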