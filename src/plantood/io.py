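"""File formats: TSV matrices, JSON manifest and reports.

All numeric tables are UTF-8 TSV with a header row.  Floats are written
with 17 significant digits, which round-trips IEEE-754 doubles exactly,
so ``read(write(x)) == x`` bit-for-bit.  A fixture directory is tied
together by ``manifest.json``, which names each file's role, declares
matrix shapes and encoder-space tags, and records the evaluation
configuration (ensemble mode, temperature, TPR level, seed).

Schemas by role:

========  =====================================================
role      columns
========  =====================================================
test_ft   sample_id, f0 … f{d-1}           (fine-tuned space)
test_pt   sample_id, f0 … f{d-1}           (pretrained space)
bank_ft   sample_id, class, f0 … f{d-1}
bank_pt   sample_id, class, f0 … f{d-1}
logits    sample_id, <one column per known class>
text      class_name, f0 … f{d-1}
labels    sample_id, membership, class_label
========  =====================================================
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    EmbeddingMatrix,
    FeatureBank,
    LogitMatrix,
    ScoreVector,
    TextEmbeddings,
)
from .exceptions import InputError, ParameterError, ParseError
from .metrics import MetricsReport
from .protocol import GroundTruth, OpenSetSplit, validate_split

FORMAT_VERSION = "1.0"

MATRIX_ROLES = ("bank_ft", "bank_pt", "test_ft", "test_pt", "logits", "text")
FILE_ROLES = MATRIX_ROLES + ("labels",)

_ROLE_SPACE = {
    "bank_ft": "finetuned",
    "bank_pt": "pretrained",
    "test_ft": "finetuned",
    "test_pt": "pretrained",
}

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _read_rows(path: Path) -> tuple[list[str], list[list[str]]]:
    """Strict TSV reader with line-numbered errors (header = line 1)."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        rows.append(fields)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return header, rows


def _parse_floats(
    path: Path, rows: list[list[str]], start_col: int
) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0]) - start_col))
    for i, row in enumerate(rows):
        for j, cell in enumerate(row[start_col:]):
            try:
                out[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{i + 2}: non-numeric cell {cell!r} in "
                    f"column {start_col + j + 1}"
                ) from None
    return out


def _check_unique_ids(path: Path, ids: list[str]) -> None:
    seen: dict[str, int] = {}
    for lineno, sid in enumerate(ids, start=2):
        if sid in seen:
            raise ParseError(
                f"{path}:{lineno}: duplicate sample id {sid!r} "
                f"(first seen at line {seen[sid]})"
            )
        seen[sid] = lineno


def read_matrix(
    path: str | Path, role: str, expected_dim: int | None = None
):
    """Read a TSV matrix file as the typed container for its role."""
    if role not in MATRIX_ROLES:
        raise ParameterError(f"unknown matrix role {role!r}")
    path = Path(path)
    header, rows = _read_rows(path)
    start_col = 2 if role.startswith("bank_") else 1
    if len(header) <= start_col:
        raise ParseError(f"{path}:1: header has no value columns")
    ids = [r[0] for r in rows]
    _check_unique_ids(path, ids)
    values = _parse_floats(path, rows, start_col)
    if expected_dim is not None and values.shape[1] != expected_dim:
        raise ParseError(
            f"{path}: manifest declares {expected_dim} columns, "
            f"file has {values.shape[1]}"
        )
    if role == "logits":
        return LogitMatrix(ids, values, header[1:])
    if role == "text":
        return TextEmbeddings(ids, values)
    if role in ("test_ft", "test_pt"):
        return EmbeddingMatrix(ids, values, _ROLE_SPACE[role])
    classes = [r[1] for r in rows]
    return FeatureBank(
        EmbeddingMatrix(ids, values, _ROLE_SPACE[role]), classes
    )


def write_matrix(obj, path: str | Path) -> Path:
    """Write a typed matrix container as TSV (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if isinstance(obj, FeatureBank):
        emb = obj.embeddings
        header = ["sample_id", "class"] + [f"f{i}" for i in range(emb.dim)]
        lines.append("\t".join(header))
        for sid, cls, row in zip(emb.sample_ids, obj.class_of_row, emb.values):
            lines.append("\t".join([sid, cls] + [_fmt(v) for v in row]))
    elif isinstance(obj, LogitMatrix):
        lines.append("\t".join(["sample_id", *obj.class_names]))
        for sid, row in zip(obj.sample_ids, obj.values):
            lines.append("\t".join([sid] + [_fmt(v) for v in row]))
    elif isinstance(obj, TextEmbeddings):
        header = ["class_name"] + [f"f{i}" for i in range(obj.dim)]
        lines.append("\t".join(header))
        for cls, row in zip(obj.class_names, obj.values):
            lines.append("\t".join([cls] + [_fmt(v) for v in row]))
    elif isinstance(obj, EmbeddingMatrix):
        header = ["sample_id"] + [f"f{i}" for i in range(obj.dim)]
        lines.append("\t".join(header))
        for sid, row in zip(obj.sample_ids, obj.values):
            lines.append("\t".join([sid] + [_fmt(v) for v in row]))
    else:
        raise ParameterError(f"cannot serialize {type(obj).__name__}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_labels(path: str | Path) -> GroundTruth:
    path = Path(path)
    header, rows = _read_rows(path)
    if header[:3] != ["sample_id", "membership", "class_label"]:
        raise ParseError(
            f"{path}:1: labels header must be "
            "sample_id\\tmembership\\tclass_label"
        )
    ids = [r[0] for r in rows]
    _check_unique_ids(path, ids)
    return GroundTruth(ids, [r[1] for r in rows], [r[2] for r in rows])


def write_labels(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["sample_id\tmembership\tclass_label"]
    for sid, mem, lab in zip(
        truth.sample_ids, truth.membership, truth.class_label
    ):
        lines.append(f"{sid}\t{mem}\t{lab}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def split_from_truth(truth: GroundTruth) -> OpenSetSplit:
    known = {
        c for c, m in zip(truth.class_label, truth.membership) if m == "known"
    }
    unknown = {
        c for c, m in zip(truth.class_label, truth.membership) if m == "unknown"
    }
    return validate_split(OpenSetSplit(known, unknown))


def write_scores(
    scores: Sequence[ScoreVector], truth: GroundTruth, path: str | Path
) -> Path:
    """Score table: sample_id, one column per score kind, membership."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not scores:
        raise ParameterError("no score vectors to write")
    ref = scores[0].sample_ids
    for sv in scores[1:]:
        if sv.sample_ids != ref:
            raise InputError("score vectors list different samples")
    if tuple(truth.sample_ids) != ref:
        raise InputError("ground truth does not match score sample ids")
    mem = dict(zip(truth.sample_ids, truth.membership))
    kinds = [sv.score_kind for sv in scores]
    lines = ["\t".join(["sample_id", *kinds, "membership"])]
    for i, sid in enumerate(ref):
        cells = [sid] + [_fmt(sv.values[i]) for sv in scores] + [mem[sid]]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_report(report: MetricsReport | dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict() if isinstance(report, MetricsReport) else report
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path


def write_histogram(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


@dataclass(frozen=True)
class Manifest:
    """Index of a fixture directory plus its evaluation configuration."""

    files: dict[str, str]
    shapes: dict[str, dict]
    mode: str = "visual_three_way"
    cpd_method: str = "msp"
    temperature: float = 1.0
    tpr_level: float = 0.95
    seed: int | None = None
    format_version: str = FORMAT_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        path = Path(path)
        try:
            raw = json.loads(path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise ParseError(f"cannot read manifest {path}: {exc}") from exc
        version = raw.get("format_version")
        if version != FORMAT_VERSION:
            raise ParseError(
                f"{path}: unrecognized format_version {version!r} "
                f"(expected {FORMAT_VERSION})"
            )
        unknown = set(raw.get("files", {})) - set(FILE_ROLES)
        if unknown:
            raise ParseError(f"{path}: unknown file roles {sorted(unknown)}")
        return cls(
            files=dict(raw["files"]),
            shapes={k: dict(v) for k, v in raw.get("shapes", {}).items()},
            mode=raw.get("mode", "visual_three_way"),
            cpd_method=raw.get("cpd_method", "msp"),
            temperature=float(raw.get("temperature", 1.0)),
            tpr_level=float(raw.get("tpr_level", 0.95)),
            seed=raw.get("seed"),
        )


def _shape_of(obj) -> dict:
    if isinstance(obj, FeatureBank):
        emb = obj.embeddings
        return {"n": emb.n_samples, "d": emb.dim, "space_tag": emb.space_tag}
    if isinstance(obj, EmbeddingMatrix):
        return {"n": obj.n_samples, "d": obj.dim, "space_tag": obj.space_tag}
    if isinstance(obj, LogitMatrix):
        return {"n": obj.n_samples, "d": obj.n_classes}
    if isinstance(obj, TextEmbeddings):
        return {"n": len(obj.class_names), "d": obj.dim}
    raise ParameterError(f"cannot describe {type(obj).__name__}")


def write_fixture(
    out_dir: str | Path,
    *,
    bank_ft: FeatureBank,
    bank_pt: FeatureBank,
    test_ft: EmbeddingMatrix,
    test_pt: EmbeddingMatrix,
    truth: GroundTruth,
    logits: LogitMatrix | None = None,
    text: TextEmbeddings | None = None,
    mode: str = "visual_three_way",
    cpd_method: str = "msp",
    temperature: float = 1.0,
    tpr_level: float = 0.95,
    seed: int | None = None,
) -> Path:
    """Write a complete fixture directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    objects = {
        "bank_ft": bank_ft,
        "bank_pt": bank_pt,
        "test_ft": test_ft,
        "test_pt": test_pt,
    }
    if logits is not None:
        objects["logits"] = logits
    if text is not None:
        objects["text"] = text
    files, shapes = {}, {}
    for role, obj in objects.items():
        fname = f"{role}.tsv"
        write_matrix(obj, out / fname)
        files[role] = fname
        shapes[role] = _shape_of(obj)
    write_labels(truth, out / "labels.tsv")
    files["labels"] = "labels.tsv"
    manifest = Manifest(
        files=files,
        shapes=shapes,
        mode=mode,
        cpd_method=cpd_method,
        temperature=temperature,
        tpr_level=tpr_level,
        seed=seed,
    )
    return manifest.save(out / "manifest.json")


@dataclass(frozen=True)
class LoadedFixture:
    """Typed contents of a fixture directory."""

    manifest: Manifest
    bank_ft: FeatureBank
    bank_pt: FeatureBank
    test_ft: EmbeddingMatrix
    test_pt: EmbeddingMatrix
    truth: GroundTruth
    split: OpenSetSplit
    logits: LogitMatrix | None = None
    text: TextEmbeddings | None = None


def load_fixture(manifest_path: str | Path) -> LoadedFixture:
    """Load and cross-validate everything a manifest references."""
    manifest_path = Path(manifest_path)
    manifest = Manifest.load(manifest_path)
    base = manifest_path.parent
    required = ("bank_ft", "bank_pt", "test_ft", "test_pt", "labels")
    for role in required:
        if role not in manifest.files:
            raise ParseError(f"manifest missing required role {role!r}")
    loaded: dict[str, object] = {}
    for role, fname in manifest.files.items():
        fpath = base / fname
        if not fpath.exists():
            raise ParseError(f"manifest references missing file {fpath}")
        if role == "labels":
            loaded[role] = read_labels(fpath)
            continue
        declared = manifest.shapes.get(role, {})
        obj = read_matrix(fpath, role, expected_dim=declared.get("d"))
        n = declared.get("n")
        shape = _shape_of(obj)
        if n is not None and shape["n"] != n:
            raise ParseError(
                f"{fpath}: manifest declares {n} rows, file has {shape['n']}"
            )
        loaded[role] = obj
    truth = loaded["labels"]
    return LoadedFixture(
        manifest=manifest,
        bank_ft=loaded["bank_ft"],
        bank_pt=loaded["bank_pt"],
        test_ft=loaded["test_ft"],
        test_pt=loaded["test_pt"],
        truth=truth,
        split=split_from_truth(truth),
        logits=loaded.get("logits"),
        text=loaded.get("text"),
    )
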