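"""Seeded generator of open-set embedding/logit fixtures.

The generator emulates the geometry the knowledge-ensemble method relies
on: each class is a Gaussian cluster around a unit-sphere center, the
same center layout is shared by two encoder spaces — a "fine-tuned"
space with tight noise (the adapted model separates the task classes
well) and a "pretrained" space with broader noise (the frozen model
retains coarser but more general structure) — and unknown-class centers
are displaced away from the known region.  Classifier logits are a
linear-head surrogate: the cosine similarity of each fine-tuned-space
test embedding to the known class centers, scaled by a gain.  Text
embeddings for the concept-matching path are the known centers
themselves.

Everything is driven by one seed through independent deterministic
substreams (centers, bank noise per space, test noise per space), so
changing the number of test samples never perturbs the centers or the
training banks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    EmbeddingMatrix,
    EnsembleSpec,
    FeatureBank,
    LogitMatrix,
    TextEmbeddings,
)
from .exceptions import GenerationError, ParameterError
from .metrics import DecisionConfig
from .protocol import (
    EnsembleResult,
    GroundTruth,
    OpenSetSplit,
    ShotConfig,
    few_shot_subsample,
    run_knowledge_ensemble,
    validate_split,
)

# substream tags: one global seed, independent streams per purpose
_STREAM_CENTERS = 0
_STREAM_BANK_FT = 1
_STREAM_BANK_PT = 2
_STREAM_TEST_FT = 3
_STREAM_TEST_PT = 4
_STREAM_DEGRADE = {"cpd": 9001, "dsk": 9002, "gk": 9003}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic open-set fixture.

    Defaults describe a moderately easy 6-known / 4-unknown problem in a
    64-dimensional embedding space: class centers at least 0.5 rad
    apart, fine-tuned-space cluster noise 0.2 (tight), pretrained-space
    noise 0.4 (broad), unknown centers pushed 0.5 further from their
    nearest known center, 16 training samples per known class and 50
    test samples per class.
    """

    k: int = 6
    u: int = 4
    d: int = 64
    shots_train: int = 16
    n_test_per_class: int = 50
    sigma_ft: float = 0.2
    sigma_pt: float = 0.4
    separation: float = 0.5
    unknown_shift: float = 0.5
    logit_gain: float = 10.0
    seed: int = 7

    def __post_init__(self):
        if self.k < 2:
            raise ParameterError(f"k must be >= 2, got {self.k}")
        if self.u < 1:
            raise ParameterError(f"u must be >= 1, got {self.u}")
        if self.d < 2:
            raise ParameterError(f"d must be >= 2, got {self.d}")
        if self.shots_train < 1 or self.n_test_per_class < 1:
            raise ParameterError("shots_train and n_test_per_class must be >= 1")
        if self.sigma_ft <= 0 or self.sigma_pt <= 0:
            raise ParameterError("noise scales must be positive")
        if self.separation < 0 or self.unknown_shift < 0:
            raise ParameterError("separation and unknown_shift must be >= 0")
        if self.logit_gain <= 0:
            raise ParameterError("logit_gain must be positive")

    @property
    def known_class_names(self) -> tuple[str, ...]:
        return tuple(f"known_{i:02d}" for i in range(self.k))

    @property
    def unknown_class_names(self) -> tuple[str, ...]:
        return tuple(f"unknown_{i:02d}" for i in range(self.u))


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete, self-consistent open-set fixture."""

    bank_ft: FeatureBank
    bank_pt: FeatureBank
    test_feats_ft: EmbeddingMatrix
    test_feats_pt: EmbeddingMatrix
    test_logits: LogitMatrix
    text_feats: TextEmbeddings
    truth: GroundTruth
    split: OpenSetSplit
    config: SyntheticConfig


def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _sample_centers(config: SyntheticConfig) -> np.ndarray:
    """Unit-sphere centers with pairwise angle >= separation."""
    rng = _stream(config.seed, _STREAM_CENTERS)
    m = config.k + config.u
    max_cos = np.cos(config.separation)
    centers: list[np.ndarray] = []
    attempts = 0
    limit = 500 * m
    while len(centers) < m:
        attempts += 1
        if attempts > limit:
            raise GenerationError(
                f"cannot place {m} centers with pairwise angular "
                f"separation {config.separation} in d={config.d}"
            )
        c = _unit(rng.normal(size=config.d))
        if all(float(c @ other) <= max_cos + 1e-12 for other in centers):
            centers.append(c)
    return np.stack(centers)


def _displace_unknown(centers: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Push each unknown center away from the known-center centroid.

    Moving along ``center − centroid(known)`` increases the distance to
    the known region as a whole, so separability grows monotonically
    with ``unknown_shift`` instead of trading closeness to one known
    class for closeness to another.
    """
    k = config.k
    out = centers.copy()
    centroid = centers[:k].mean(axis=0)
    for j in range(k, centers.shape[0]):
        direction = centers[j] - centroid
        nrm = np.linalg.norm(direction)
        if nrm < 1e-12:
            direction = np.zeros(config.d)
            direction[0] = 1.0
            direction -= (direction @ centers[j]) * centers[j]
            nrm = np.linalg.norm(direction)
        out[j] = _unit(centers[j] + config.unknown_shift * direction / nrm)
    return out


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticBundle:
    """Generate a fixture; bit-identical for identical config and seed."""
    centers = _displace_unknown(_sample_centers(config), config)
    known_names = config.known_class_names
    unknown_names = config.unknown_class_names
    all_names = known_names + unknown_names

    # training banks: known classes only, same samples in both spaces
    rng_bft = _stream(config.seed, _STREAM_BANK_FT)
    rng_bpt = _stream(config.seed, _STREAM_BANK_PT)
    bank_ids, bank_labels, bank_ft_rows, bank_pt_rows = [], [], [], []
    for i, cls in enumerate(known_names):
        for j in range(config.shots_train):
            bank_ids.append(f"train_{cls}_{j:03d}")
            bank_labels.append(cls)
            bank_ft_rows.append(
                centers[i] + config.sigma_ft * rng_bft.normal(size=config.d)
            )
            bank_pt_rows.append(
                centers[i] + config.sigma_pt * rng_bpt.normal(size=config.d)
            )
    bank_ft = FeatureBank(
        EmbeddingMatrix(bank_ids, np.stack(bank_ft_rows), "finetuned"),
        bank_labels,
    )
    bank_pt = FeatureBank(
        EmbeddingMatrix(bank_ids, np.stack(bank_pt_rows), "pretrained"),
        bank_labels,
    )

    # test samples: every class, known and unknown
    rng_tft = _stream(config.seed, _STREAM_TEST_FT)
    rng_tpt = _stream(config.seed, _STREAM_TEST_PT)
    test_ids, memberships, labels, ft_rows, pt_rows = [], [], [], [], []
    idx = 0
    for i, cls in enumerate(all_names):
        member = "known" if i < config.k else "unknown"
        for _ in range(config.n_test_per_class):
            test_ids.append(f"test_{idx:04d}")
            memberships.append(member)
            labels.append(cls)
            ft_rows.append(
                centers[i] + config.sigma_ft * rng_tft.normal(size=config.d)
            )
            pt_rows.append(
                centers[i] + config.sigma_pt * rng_tpt.normal(size=config.d)
            )
            idx += 1
    test_ft = EmbeddingMatrix(test_ids, np.stack(ft_rows), "finetuned")
    test_pt = EmbeddingMatrix(test_ids, np.stack(pt_rows), "pretrained")

    # linear-head surrogate: gain-scaled cosine similarity to known centers
    logits = LogitMatrix(
        test_ids,
        config.logit_gain * (_unit(test_ft.values) @ centers[: config.k].T),
        known_names,
    )
    text = TextEmbeddings(known_names, centers[: config.k].copy())
    truth = GroundTruth(test_ids, memberships, labels)
    split = validate_split(OpenSetSplit(known_names, unknown_names))
    return SyntheticBundle(
        bank_ft, bank_pt, test_ft, test_pt, logits, text, truth, split, config
    )


def degrade(
    bundle: SyntheticBundle, component: str, severity: float
) -> SyntheticBundle:
    """Corrupt exactly one information channel, leaving the others intact.

    ``cpd``: a ``severity`` fraction of logit rows is permuted among
    themselves, decoupling logits from sample identity.  ``dsk`` /
    ``gk``: each fine-tuned / pretrained test embedding is blended with
    an equal-norm random direction, ``severity`` = 1 meaning fully
    random.  Severity 0 returns the bundle unchanged.
    """
    if component not in _STREAM_DEGRADE:
        raise ParameterError(
            f"component must be one of {sorted(_STREAM_DEGRADE)}, "
            f"got {component!r}"
        )
    if not (0.0 <= severity <= 1.0):
        raise ParameterError(f"severity must be in [0, 1], got {severity}")
    if severity == 0.0:
        return bundle
    rng = _stream(bundle.config.seed, _STREAM_DEGRADE[component])

    if component == "cpd":
        values = bundle.test_logits.values.copy()
        n = values.shape[0]
        m = int(round(severity * n))
        chosen = rng.choice(n, size=m, replace=False)
        values[chosen] = values[chosen[rng.permutation(m)]]
        logits = LogitMatrix(
            bundle.test_logits.sample_ids, values, bundle.test_logits.class_names
        )
        return dataclasses.replace(bundle, test_logits=logits)

    feats = bundle.test_feats_ft if component == "dsk" else bundle.test_feats_pt
    noise = rng.normal(size=feats.values.shape)
    noise *= np.linalg.norm(feats.values, axis=1, keepdims=True) / np.linalg.norm(
        noise, axis=1, keepdims=True
    )
    blended = (1.0 - severity) * feats.values + severity * noise
    degraded = EmbeddingMatrix(feats.sample_ids, blended, feats.space_tag)
    if component == "dsk":
        return dataclasses.replace(bundle, test_feats_ft=degraded)
    return dataclasses.replace(bundle, test_feats_pt=degraded)


def run_bundle(
    bundle: SyntheticBundle,
    spec: EnsembleSpec = EnsembleSpec.visual_three_way(),
    decision: DecisionConfig = DecisionConfig(),
    shots: int | str = "all",
    temperature: float = 1.0,
) -> EnsembleResult:
    """Score and evaluate a bundle, optionally with M-shot banks."""
    shot_cfg = ShotConfig(shots, seed=bundle.config.seed)
    bank_ft = few_shot_subsample(bundle.bank_ft, shot_cfg)
    bank_pt = few_shot_subsample(bundle.bank_pt, shot_cfg)
    return run_knowledge_ensemble(
        bundle.test_logits,
        bundle.test_feats_ft,
        bundle.test_feats_pt,
        bank_ft,
        bank_pt,
        bundle.truth,
        spec=spec,
        decision=decision,
        text_feats=bundle.text_feats,
        temperature=temperature,
        split=bundle.split,
    )


def _report_row(prefix: str, result: EnsembleResult) -> dict:
    rep = result.report
    return {
        f"{prefix}fpr_at_tpr95": rep.fpr_at_tpr95,
        f"{prefix}auroc": rep.auroc,
        f"{prefix}accuracy_known": rep.accuracy_known,
        f"{prefix}lambda": rep.lambda_used,
    }


def sweep(
    grid: Iterable[SyntheticConfig],
    spec: EnsembleSpec = EnsembleSpec.visual_three_way(),
    decision: DecisionConfig = DecisionConfig(),
) -> pd.DataFrame:
    """Run generate + knowledge ensemble over a config grid.

    One row per config with the config fields and the ensemble metrics;
    an empty grid yields an empty table.
    """
    rows = []
    for config in grid:
        result = run_bundle(generate(config), spec, decision)
        row = dataclasses.asdict(config)
        row.update(_report_row("", result))
        rows.append(row)
    return pd.DataFrame(rows)


def shots_sweep(
    config: SyntheticConfig,
    shots: Sequence[int],
    spec: EnsembleSpec = EnsembleSpec.visual_three_way(),
    decision: DecisionConfig = DecisionConfig(),
) -> pd.DataFrame:
    """Shot ablation on one bundle with nested M-shot banks.

    The bundle is generated once with its full training pool and the
    banks are subsampled per M, so smaller shot counts use subsets of
    the larger ones (seeded prefix selection).
    """
    bad = [m for m in shots if m != "all" and int(m) > config.shots_train]
    if bad:
        raise ParameterError(
            f"shots {bad} exceed the training pool ({config.shots_train} "
            "per class)"
        )
    bundle = generate(config)
    rows = []
    for m in shots:
        result = run_bundle(bundle, spec, decision, shots=m)
        row = {"shots": m}
        row.update(_report_row("", result))
        rows.append(row)
    return pd.DataFrame(rows)
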