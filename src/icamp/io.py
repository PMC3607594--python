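"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices and class maps are TSV; gene sets are standard GMT;
risk models are JSON.  All writers are deterministic (fixed column order,
floats at 6 significant digits) so repeated runs diff cleanly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, GeneSet

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample id, class) into a dict.

    A header line is tolerated if its second field is literally 'class'.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
            if i == 1 and parts[1].strip().lower() == "class":
                continue
            out[parts[0].strip()] = parts[1].strip().lower()
    return out


def read_expression_study(
    path: str | Path,
    study_id: str,
    class_map: Mapping[str, str] | str | Path,
) -> ExpressionStudy:
    """Read a genes x samples log2 expression TSV into an ExpressionStudy.

    The TSV has a header row of sample ids and gene symbols in the first
    column.  ``class_map`` is either a mapping sample -> class or the path
    of a two-column TSV.  Duplicate gene rows are collapsed by their mean
    on the log2 scale with a logged warning; a non-numeric cell or a sample
    without a class label is a hard error.
    """
    if not isinstance(class_map, Mapping):
        class_map = read_class_map(class_map)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().sum() > df[col].isna().sum():
                bad = df.index[coerced.isna() & df[col].notna()][0]
                raise ValueError(
                    f"{path}: non-numeric value at gene {bad!r}, sample {col!r} "
                    f"(column {j + 1})"
                ) from None
        raise
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        log.warning(
            "study %s: collapsing %d duplicate gene row(s) by mean", study_id, n
        )
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionStudy(study_id=study_id, values=df, class_of=dict(class_map))


def read_gene_set_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name, description, members, tab-separated).

    Gene symbols are uppercased; a line with fewer than three fields is an
    error naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = [p for p in line.split("\t")]
            members = [p.strip() for p in parts[2:] if p.strip()]
            if len(parts) < 3 or not members:
                raise ValueError(
                    f"{path}:{i}: GMT line needs a name, description and "
                    f">=1 member gene"
                )
            sets.append(GeneSet(name=parts[0].strip(), members=frozenset(members)))
    return sets


def write_results_table(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: list[str] | None = None,
) -> None:
    """Write records as a TSV with deterministic column order.

    Floats are rendered at 6 significant digits; the same records always
    produce byte-identical files.  An empty record list yields a
    header-only file (``columns`` must then be given or be inferable).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_risk_model_json(model_dict: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_dict, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_risk_model_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_expression_study(study: ExpressionStudy, matrix_path, classes_path) -> None:
    """Inverse of read_expression_study (matrix TSV + class-map TSV)."""
    study.values.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT)
    with open(classes_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tclass\n")
        for s in study.samples:
            fh.write(f"{s}\t{study.class_of[s]}\n")


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
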