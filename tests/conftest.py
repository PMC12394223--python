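import numpy as np
import pytest

from plantood import (
    EmbeddingMatrix,
    FeatureBank,
    GroundTruth,
    LogitMatrix,
    SyntheticConfig,
    TextEmbeddings,
    generate,
)


@pytest.fixture(scope="session")
def default_bundle():
    """The default seeded synthetic fixture (shared, never mutated)."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def separated_config():
    """Near-noiseless geometry with strongly displaced unknown centers."""
    return SyntheticConfig(sigma_ft=1e-4, sigma_pt=1e-4, unknown_shift=2.0)


def make_embeddings(rows, tag="finetuned", ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return EmbeddingMatrix(ids, rows, tag)


def make_bank(rows, classes=None, tag="finetuned"):
    rows = np.asarray(rows, dtype=float)
    classes = classes or ["c0"] * rows.shape[0]
    ids = [f"b{i}" for i in range(rows.shape[0])]
    return FeatureBank(EmbeddingMatrix(ids, rows, tag), classes)


def make_logits(rows, classes=None):
    rows = np.asarray(rows, dtype=float)
    classes = classes or [f"c{i}" for i in range(rows.shape[1])]
    ids = [f"s{i}" for i in range(rows.shape[0])]
    return LogitMatrix(ids, rows, classes)


def make_text(rows, classes=None):
    rows = np.asarray(rows, dtype=float)
    classes = classes or [f"c{i}" for i in range(rows.shape[0])]
    return TextEmbeddings(classes, rows)


def make_truth(n_known, n_unknown):
    ids = [f"s{i}" for i in range(n_known + n_unknown)]
    membership = ["known"] * n_known + ["unknown"] * n_unknown
    labels = ["c0"] * n_known + ["u0"] * n_unknown
    return GroundTruth(ids, membership, labels)
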