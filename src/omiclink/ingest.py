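"""Tab-delimited readers and writers for all study tables.

All inputs are preprocessed, tab-delimited ASCII with a header row; the
caller supplies a column mapping saying which columns hold identifiers,
sample values, coordinates or clinical variables — mirroring a data-loading
settings dialog, but as plain objects reusable from a flat key-value config
file.

Dialect: TAB separator only, ``.`` decimal point, no locale handling,
identifiers taken verbatim (no sanitization) so cross-file identity stays
exact.  Non-numeric expression cells become missing with a logged warning;
unmapped copy-number tokens are an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ClinicalTable,
    ClinicalVariable,
    FeatureMatrix,
    GenomicFeature,
    StateMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionColumns", "StateColumns", "FeatureColumns", "ClinicalTypes",
    "read_expression", "read_states", "read_features", "read_clinical",
    "write_expression", "write_states", "write_features", "write_clinical",
    "read_config", "write_config",
]

DEFAULT_STATE_ENCODING = {"-1": -1.0, "0": 0.0, "1": 1.0}


@dataclass
class ExpressionColumns:
    """Column map for an expression table: gene-id column + sample columns."""

    id_column: str
    sample_columns: list[str]


@dataclass
class StateColumns(ExpressionColumns):
    """Column map for a copy-number state table; ``encoding`` maps file
    tokens to −1/0/+1 (default tokens ``-1``/``0``/``1``)."""

    encoding: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_ENCODING))
    missing_tokens: tuple[str, ...] = ("", "NA")


@dataclass
class FeatureColumns:
    """Column map for gene/marker annotation: id, chromosome, start and an
    optional end column (absent ⇒ point features)."""

    id_column: str
    chromosome_column: str
    start_column: str
    end_column: str | None = None


@dataclass
class ClinicalTypes:
    """Type map for the clinical table.

    ``types`` tags every used column: ``"categorical"``, ``"continuous"``,
    or ``("time_to_event", time_column, status_column)`` under the variable
    name.  Status tokens are parsed through ``status_encoding``
    (default ``1`` = event, ``0`` = censored).
    """

    id_column: str
    types: dict[str, object]
    status_encoding: dict[str, bool] = field(default_factory=lambda: {"1": True, "0": False})


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)


def _require(frame: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: mapped column(s) not found: {missing}")


def _to_float(raw: pd.DataFrame, path) -> np.ndarray:
    """Numeric parse; non-numeric / empty cells become NaN with one logged count."""
    parsed = raw.apply(pd.to_numeric, errors="coerce")
    norm = raw.apply(lambda c: c.astype(str).str.strip().str.upper())
    bad = int((parsed.isna() & (norm != "") & (norm != "NA")).sum().sum())
    if bad:
        logger.warning("%s: %d non-numeric cell(s) treated as missing", path, bad)
    return parsed.to_numpy(dtype=float)


def read_expression(path, colmap: ExpressionColumns) -> FeatureMatrix:
    """Read a genes × samples expression matrix."""
    frame = _read_table(path)
    _require(frame, [colmap.id_column, *colmap.sample_columns], path)
    ids = frame[colmap.id_column].tolist()
    values = _to_float(frame[colmap.sample_columns], path)
    return FeatureMatrix(values, ids, list(colmap.sample_columns))


def read_states(path, colmap: StateColumns) -> StateMatrix:
    """Read a markers × samples copy-number state matrix.

    Every token must be in ``colmap.encoding`` or ``colmap.missing_tokens``;
    anything else raises.
    """
    frame = _read_table(path)
    _require(frame, [colmap.id_column, *colmap.sample_columns], path)
    raw = frame[colmap.sample_columns]
    known = set(colmap.encoding) | set(colmap.missing_tokens)
    tokens = set(np.unique(raw.to_numpy(dtype=object)).tolist())
    bad = tokens - known
    if bad:
        raise ValueError(f"{path}: state token(s) outside encoding: {sorted(bad)}")
    lut = {**{t: np.nan for t in colmap.missing_tokens}, **colmap.encoding}
    values = raw.apply(lambda col: col.map(lut)).to_numpy(dtype=float)
    return StateMatrix(values, frame[colmap.id_column].tolist(), list(colmap.sample_columns))


def read_features(path, colmap: FeatureColumns) -> list[GenomicFeature]:
    """Read gene or marker annotation rows into genomic features.

    Without an end column every feature is a point (``end = start``).
    Coordinate validation (positive, start ≤ end) happens in the feature
    constructor.
    """
    frame = _read_table(path)
    cols = [colmap.id_column, colmap.chromosome_column, colmap.start_column]
    if colmap.end_column is not None:
        cols.append(colmap.end_column)
    _require(frame, cols, path)
    feats = []
    for _, row in frame.iterrows():
        start = int(float(row[colmap.start_column]))
        end = int(float(row[colmap.end_column])) if colmap.end_column else start
        feats.append(GenomicFeature(str(row[colmap.id_column]),
                                    row[colmap.chromosome_column], start, end))
    return feats


def read_clinical(path, typemap: ClinicalTypes) -> ClinicalTable:
    """Read the per-sample clinical table with explicit variable types."""
    frame = _read_table(path)
    _require(frame, [typemap.id_column], path)
    sample_ids = frame[typemap.id_column].tolist()
    variables: dict[str, ClinicalVariable] = {}
    for name, tag in typemap.types.items():
        if tag == "categorical":
            _require(frame, [name], path)
            vals = frame[name].replace({"": np.nan, "NA": np.nan}).to_numpy(dtype=object)
            variables[name] = ClinicalVariable("categorical", vals)
        elif tag == "continuous":
            _require(frame, [name], path)
            variables[name] = ClinicalVariable(
                "continuous", _to_float(frame[[name]], path).ravel())
        elif isinstance(tag, (tuple, list)) and tag[0] == "time_to_event":
            _, time_col, status_col = tag
            _require(frame, [time_col, status_col], path)
            times = _to_float(frame[[time_col]], path).ravel()
            status = []
            for tok in frame[status_col]:
                if tok in typemap.status_encoding:
                    status.append(typemap.status_encoding[tok])
                else:
                    raise ValueError(
                        f"{path}: unparseable status token {tok!r} in {status_col!r}")
            variables[name] = ClinicalVariable("time_to_event", times, np.array(status))
        else:
            raise ValueError(f"column {name!r} has unknown type tag {tag!r}")
    return ClinicalTable(sample_ids, variables)


# --------------------------------------------------------------------------
# writers (exact dialect the readers consume; float formatting repr-exact)

def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return repr(float(x))


def write_expression(matrix: FeatureMatrix, path, id_column: str = "gene_id") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([id_column, *matrix.col_ids]) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write("\t".join([rid, *(_fmt(v) for v in row)]) + "\n")


def write_states(matrix: StateMatrix, path, id_column: str = "marker_id") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([id_column, *matrix.col_ids]) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            toks = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write("\t".join([rid, *toks]) + "\n")


def write_features(features: Sequence[GenomicFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchromosome\tstart\tend\n")
        for f in features:
            fh.write(f"{f.id}\t{f.chromosome}\t{f.start}\t{f.end}\n")


def write_clinical(table: ClinicalTable, path, id_column: str = "sample_id") -> None:
    cols: list[tuple[str, list[str]]] = []
    for name, var in table.variables.items():
        if var.kind == "time_to_event":
            cols.append((f"{name}_time", [_fmt(v) for v in var.values]))
            cols.append((f"{name}_status", ["1" if e else "0" for e in var.event]))
        elif var.kind == "continuous":
            cols.append((name, [_fmt(v) for v in var.values]))
        else:
            cols.append((name, ["NA" if (isinstance(v, float) and np.isnan(v)) else str(v)
                                for v in var.values]))
    with open(path, "w") as fh:
        fh.write("\t".join([id_column, *(c for c, _ in cols)]) + "\n")
        for i, sid in enumerate(table.sample_ids):
            fh.write("\t".join([sid, *(vals[i] for _, vals in cols)]) + "\n")


def clinical_typemap(table: ClinicalTable, id_column: str = "sample_id") -> ClinicalTypes:
    """Type map matching :func:`write_clinical` output (round-trip helper)."""
    types: dict[str, object] = {}
    for name, var in table.variables.items():
        if var.kind == "time_to_event":
            types[name] = ("time_to_event", f"{name}_time", f"{name}_status")
        else:
            types[name] = var.kind
    return ClinicalTypes(id_column, types)


# --------------------------------------------------------------------------
# derived-result serialization (tab-delimited)

def write_partition(partition, path) -> None:
    """``id → label`` table."""
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for i, l in zip(partition.item_ids, partition.labels):
            fh.write(f"{i}\t{int(l)}\n")


def write_dendrogram(dendrogram, path) -> None:
    """Merge table: one row per agglomeration step (leaves are nodes
    ``0..n−1``, merge ``i`` creates node ``n+i``), plus the leaf order."""
    with open(path, "w") as fh:
        fh.write(f"# linkage={dendrogram.linkage}\tmetric={dendrogram.metric}\n")
        fh.write("# leaf_order=" + ",".join(
            dendrogram.item_ids[i] for i in dendrogram.leaf_order) + "\n")
        fh.write("node_a\tnode_b\theight\n")
        for a, b, h in dendrogram.merges:
            fh.write(f"{a}\t{b}\t{_fmt(h)}\n")


def write_biclusters(biclusters, path) -> None:
    """One row per bicluster: score + comma-joined row and column ids."""
    with open(path, "w") as fh:
        fh.write("bicluster\tscore\trow_ids\tcol_ids\n")
        for i, b in enumerate(biclusters, start=1):
            score = "" if b.score is None else _fmt(b.score)
            fh.write(f"{i}\t{score}\t{','.join(b.row_ids)}\t{','.join(b.col_ids)}\n")


def write_seriation(seriation, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# method={seriation.method}\taxis={seriation.axis}\n")
        fh.write("position\tindex\tid\n")
        for pos, idx in enumerate(seriation.permutation):
            label = seriation.item_ids[idx] if seriation.item_ids else str(idx)
            fh.write(f"{pos}\t{int(idx)}\t{label}\n")


# --------------------------------------------------------------------------
# flat key-value config (one "key = value" per line; lists comma-separated)

def read_config(path) -> dict[str, str]:
    cfg: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed config line {line!r}")
        key, _, value = line.partition("=")
        cfg[key.strip()] = value.strip()
    return cfg


def write_config(cfg: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for key in cfg:
            fh.write(f"{key} = {cfg[key]}\n")
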