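"""Readers and writers for the tabular artifacts of the pipeline."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"  # deterministic output formatting


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_study(
    expression_path: str | Path,
    metadata_path: str | Path,
    name: str | None = None,
) -> ExpressionStudy:
    """Load and validate one study from an expression TSV/CSV and a metadata table.

    Expression: first column gene id, header row = sample ids. Metadata:
    first column sample id, then group/batch/sex/age/anxiety (and optionally
    bmi). Genes are sorted by id so downstream alignment is canonical.
    """
    expression_path, metadata_path = Path(expression_path), Path(metadata_path)
    expr = pd.read_csv(expression_path, sep=_sep_for(expression_path), index_col=0)
    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), index_col=0)
    if "group" in meta.columns:
        meta["group"] = meta["group"].astype(str).str.strip().str.lower()
    if "sex" in meta.columns:
        meta["sex"] = meta["sex"].astype(str).str.strip().str.lower()
    expr.index = expr.index.astype(str)
    meta.index = meta.index.astype(str)
    expr.columns = expr.columns.astype(str)
    study = ExpressionStudy(
        expr, meta, name=name or expression_path.stem.replace("_expression", "")
    )
    return study.sorted_by_gene()


def write_gene_list(gene_ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in gene_ids) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_results(
    tables: dict[str, pd.DataFrame], directory: str | Path
) -> dict[str, dict]:
    """Write each table as a TSV with deterministic formatting; return a manifest.

    The manifest maps table name to {"path", "n_rows"}. Files are written in
    sorted-name order; identical inputs produce byte-identical files.
    """
    directory = Path(directory)
    if directory.exists() and not directory.is_dir():
        raise ValidationError(f"not a directory: {directory}")
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for tname in sorted(tables):
        table = tables[tname]
        path = directory / f"{tname}.tsv"
        try:
            table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
        except OSError as err:
            raise OSError(f"failed writing {path}: {err}") from err
        manifest[tname] = {"path": str(path), "n_rows": int(len(table))}
    return manifest
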