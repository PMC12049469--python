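"""Reading expression matrices and sample labels.

Two input routes are supported:

* GEO series-matrix files (the tab-separated distribution format combining
  ``!Sample_*`` metadata lines with a probe x sample expression table between
  ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers);
  gzip-compressed files are accepted transparently;
* plain TSV matrices (header row of sample IDs, first column of probe IDs)
  with a separate two-column sample -> class label file.

On load, probes are additionally re-coded by their 1-based row order as
"V1".."VM". These V-codes are identifiers assigned once from the full file:
subsetting genes preserves them, so a report naming e.g. V1328 stays
meaningful after candidate filtering.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .infotheory import LabelVector

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_series_matrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "extract_class_labels",
    "impute_missing",
    "SeriesMatrixFormatError",
    "AlignmentError",
    "EmptyCohortError",
]


class SeriesMatrixFormatError(ValueError):
    """Series-matrix file violates the expected structure."""


class AlignmentError(ValueError):
    """Samples in the matrix and the label file cannot be aligned."""


class EmptyCohortError(ValueError):
    """A label mapping matched zero samples."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with probe IDs, V-codes and metadata."""

    values: np.ndarray  # (M genes, n samples)
    probe_ids: tuple
    sample_ids: tuple
    v_codes: tuple = ()
    sample_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = tuple(self.probe_ids)
        self.sample_ids = tuple(self.sample_ids)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not self.v_codes:
            self.v_codes = tuple(f"V{i}" for i in range(1, len(self.probe_ids) + 1))
        else:
            self.v_codes = tuple(self.v_codes)
        if len(self.v_codes) != len(self.probe_ids):
            raise ValueError("v_codes must align with probe_ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene(self, index: int) -> np.ndarray:
        return self.values[index]

    def block(self, indices: Sequence[int]) -> np.ndarray:
        return self.values[list(indices)]

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Row subset preserving original V-codes (identifiers, not ranks)."""
        idx = list(indices)
        return ExpressionMatrix(
            values=self.values[idx],
            probe_ids=tuple(self.probe_ids[i] for i in idx),
            sample_ids=self.sample_ids,
            v_codes=tuple(self.v_codes[i] for i in idx),
            sample_metadata=self.sample_metadata,
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        meta = {
            k: tuple(v[i] for i in idx) for k, v in self.sample_metadata.items()
        }
        return ExpressionMatrix(
            values=self.values[:, idx],
            probe_ids=self.probe_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            v_codes=self.v_codes,
            sample_metadata=meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.probe_ids), columns=list(self.sample_ids))


def impute_missing(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace NaN cells by their gene's median (downstream discretization
    rejects non-finite values, so imputation is an explicit opt-in step).

    A gene with no finite value at all raises ``ValueError``.
    """
    values = expr.values.copy()
    for i in range(values.shape[0]):
        row = values[i]
        mask = np.isnan(row)
        if mask.all():
            raise ValueError(f"gene {expr.probe_ids[i]!r} has no finite values to impute from")
        if mask.any():
            row[mask] = np.median(row[~mask])
    return ExpressionMatrix(
        values=values,
        probe_ids=expr.probe_ids,
        sample_ids=expr.sample_ids,
        v_codes=expr.v_codes,
        sample_metadata=expr.sample_metadata,
    )


_MISSING = {"", "null", "NULL", "NA", "na", "NaN", "nan"}


def _unquote(cell: str) -> str:
    cell = cell.strip()
    if len(cell) >= 2 and cell[0] == '"' and cell[-1] == '"':
        cell = cell[1:-1]
    return cell


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    raw = path.open("rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    raw.seek(0)
    return io.TextIOWrapper(raw, encoding="utf-8")


def read_series_matrix(path) -> ExpressionMatrix:
    """Parse a GEO series-matrix file into an :class:`ExpressionMatrix`.

    ``!Sample_*`` metadata lines are collected into ``sample_metadata``
    (repeated keys are suffixed ``.1``, ``.2``, ...); the expression table is
    read between the begin/end markers with rows and columns in file order.
    Missing-value tokens (empty, "null", "NA") become NaN; any other
    non-numeric cell raises a parse error naming its row and column.
    """
    metadata: dict = {}
    key_counts: dict = {}
    table_lines: list = []
    in_table = False
    saw_begin = saw_end = False
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!Sample_"):
                parts = line.split("\t")
                key = parts[0][len("!Sample_"):]
                n_seen = key_counts.get(key, 0)
                key_counts[key] = n_seen + 1
                if n_seen:
                    key = f"{key}.{n_seen}"
                metadata[key] = tuple(_unquote(p) for p in parts[1:])
    if not (saw_begin and saw_end):
        raise SeriesMatrixFormatError("missing !series_matrix_table_begin/end markers")
    if len(table_lines) < 2:
        raise SeriesMatrixFormatError("series-matrix table section is empty")

    header = [_unquote(c) for c in table_lines[0].split("\t")]
    sample_ids = tuple(header[1:])
    width = len(header)
    probe_ids = []
    rows = []
    for r, line in enumerate(table_lines[1:], start=1):
        cells = line.split("\t")
        if len(cells) != width:
            raise SeriesMatrixFormatError(
                f"ragged table row {r}: {len(cells)} cells, expected {width}"
            )
        probe_ids.append(_unquote(cells[0]))
        vals = []
        for c, cell in enumerate(cells[1:], start=1):
            cell = _unquote(cell)
            if cell in _MISSING:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise SeriesMatrixFormatError(
                    f"non-numeric cell at table row {r} (probe {probe_ids[-1]!r}), "
                    f"column {c} (sample {sample_ids[c - 1]!r}): {cell!r}"
                ) from None
        rows.append(vals)
    return ExpressionMatrix(
        values=np.array(rows, dtype=float),
        probe_ids=tuple(probe_ids),
        sample_ids=sample_ids,
        sample_metadata=metadata,
    )


def read_expression_tsv(matrix_path, labels_path) -> tuple:
    """Read a plain TSV matrix plus a two-column sample -> class label file.

    Returns ``(ExpressionMatrix, LabelVector)`` with labels aligned to the
    matrix's sample order regardless of the label file's row order. Samples
    missing a label raise :class:`AlignmentError`; duplicate probe IDs are
    suffix-deduplicated with a warning.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    probe_ids = [str(p) for p in df.index]
    if len(set(probe_ids)) != len(probe_ids):
        logger.warning("duplicate probe IDs found; suffix-deduplicating")
        seen: dict = {}
        fixed = []
        for p in probe_ids:
            k = seen.get(p, 0)
            seen[p] = k + 1
            fixed.append(p if k == 0 else f"{p}.{k}")
        probe_ids = fixed
    sample_ids = [str(s) for s in df.columns]

    lab = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    lab = lab.dropna(how="all")
    mapping = dict(zip(lab["sample"].str.strip(), lab["label"].str.strip()))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise AlignmentError(f"samples missing from label file: {missing}")
    labels = LabelVector([mapping[s] for s in sample_ids])
    expr = ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        probe_ids=tuple(probe_ids),
        sample_ids=tuple(sample_ids),
    )
    return expr, labels


def write_expression_tsv(expr: ExpressionMatrix, matrix_path, labels: Optional[LabelVector] = None,
                         labels_path=None) -> None:
    """Write the matrix (and optionally aligned labels) in the TSV layout
    ``read_expression_tsv`` accepts, preserving full float precision."""
    df = expr.to_frame()
    df.index.name = "probe_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    if labels is not None:
        if labels_path is None:
            raise ValueError("labels_path required when labels are given")
        with open(labels_path, "w") as fh:
            for s, lab in zip(expr.sample_ids, labels.labels):
                fh.write(f"{s}\t{lab}\n")


def extract_class_labels(
    expr: ExpressionMatrix,
    field_name: str,
    mapping: Mapping[str, str],
) -> tuple:
    """Map a sample-metadata field to class labels via ordered regex rules.

    ``mapping`` is an ordered {pattern: class} dict; the first pattern that
    matches (``re.search``) a sample's metadata value wins. Samples matching
    no pattern are dropped with a warning and the matrix is subset to the
    matched cohort. Returns ``(subset ExpressionMatrix, LabelVector)``.
    """
    if field_name not in expr.sample_metadata:
        raise KeyError(f"metadata field {field_name!r} not present")
    values = expr.sample_metadata[field_name]
    if len(values) != expr.n_samples:
        raise ValueError(f"metadata field {field_name!r} does not cover all samples")
    compiled = [(re.compile(pat), cls) for pat, cls in mapping.items()]
    kept, labels = [], []
    for i, v in enumerate(values):
        for rx, cls in compiled:
            if rx.search(v):
                kept.append(i)
                labels.append(cls)
                break
        else:
            logger.warning("sample %s matched no label pattern; dropped", expr.sample_ids[i])
    if not kept:
        raise EmptyCohortError("no sample matched any label pattern")
    return expr.subset_samples(kept), LabelVector(labels)
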