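"""Tabular I/O: expression matrices, sample metadata, predictor call tables, GMT."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .model import CodingPotentialCalls, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Default column dialect for a predictor call table: the id column, the label
#: column and the mapping from file labels to {coding, noncoding}.
DEFAULT_CALL_DIALECT = {
    "id_column": "transcript_id",
    "label_column": "label",
    "label_map": {"coding": "coding", "noncoding": "noncoding"},
}


class ConfigError(ValueError):
    """Bad configuration (unknown predictor, malformed dialect...)."""


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (columns: sample_id, stage, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "stage"):
        if col not in df.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    return df.set_index("sample_id")


def read_expression_matrix(
    path: str | Path, kind: str, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read a features x samples TSV plus its sample metadata.

    First column = feature id, header row = sample ids. Counts must be
    exactly integral; negative values are rejected for either kind.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    metadata = read_metadata(metadata_path)
    return ExpressionMatrix(values, kind, metadata)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_coding_calls(
    paths: Mapping[str, str | Path],
    dialects: Mapping[str, dict] | None = None,
) -> CodingPotentialCalls:
    """Merge per-predictor coding-potential call tables.

    ``paths`` maps predictor name (CPC2, CPAT, CNCI, Pfam) to a TSV path.
    A transcript absent from one predictor's file gets ``missing`` for it.
    Per-predictor column dialects may override :data:`DEFAULT_CALL_DIALECT`.
    """
    from .model import PREDICTORS

    dialects = dialects or {}
    merged: dict[str, dict[str, str]] = {}
    for pred, path in paths.items():
        if pred not in PREDICTORS:
            raise ConfigError(
                f"unknown predictor {pred!r}; expected one of {PREDICTORS}"
            )
        dialect = {**DEFAULT_CALL_DIALECT, **dialects.get(pred, {})}
        df = pd.read_csv(path, sep="\t", dtype=str)
        id_col, label_col = dialect["id_column"], dialect["label_column"]
        for col in (id_col, label_col):
            if col not in df.columns:
                raise ConfigError(f"{path}: missing column {col!r} for {pred}")
        label_map = dialect["label_map"]
        for _, row in df.iterrows():
            raw = row[label_col]
            if raw not in label_map:
                raise ValidationError(
                    f"{path}: unmapped label {raw!r} for predictor {pred}"
                )
            merged.setdefault(row[id_col], {})[pred] = label_map[raw]
    return CodingPotentialCalls(merged)


def write_coding_calls(
    calls: CodingPotentialCalls, out_dir: str | Path
) -> dict[str, Path]:
    """Write one default-dialect TSV per predictor; returns predictor -> path."""
    from .model import PREDICTORS

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pred in PREDICTORS:
        rows = [
            (tid, per[pred])
            for tid, per in sorted(calls.calls.items())
            if per[pred] != "missing"
        ]
        path = out_dir / f"calls_{pred.lower()}.tsv"
        pd.DataFrame(rows, columns=["transcript_id", "label"]).to_csv(
            path, sep="\t", index=False
        )
        paths[pred] = path
    return paths


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT pathway file: ``pathway_id<TAB>description<TAB>gene...``."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs id, description, >=1 gene"
                )
            pathways[fields[0]] = set(fields[2:])
    return pathways


def write_gmt(pathways: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\t{pid}\t{genes}\n")
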