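"""Reading and writing labeled expression matrices.

Matrix files are genes-in-rows / samples-in-columns delimited text with a
header row of sample identifiers and gene symbols in the first column (the
GEO series-matrix convention).  Labels live in a separate two-column file
mapping sample id to tissue class.  Missing values are rejected rather than
imputed, and gene symbols are compared case-sensitively.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionMatrix, LabeledDataset
from .rules import RuleSet, parse_rules

__all__ = [
    "read_labeled_dataset",
    "write_labeled_dataset",
    "read_series_matrix",
    "load_table2_rules",
    "FormatError",
    "SampleMismatchError",
]


class FormatError(DatasetError):
    """Malformed matrix or label file."""


class SampleMismatchError(DatasetError):
    """Samples present in one file but missing from the other."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def _read_matrix(path: Path, delimiter: str | None, transpose: bool) -> ExpressionMatrix:
    delimiter = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: no data rows")
    if transpose:
        df = df.T
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at gene {gene!r}, "
                        f"sample {sample!r}"
                    ) from None
        raise  # pragma: no cover - defensive
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], values
    )


def _read_labels(path: Path, delimiter: str | None) -> dict[str, str]:
    delimiter = delimiter or _sniff_delimiter(path)
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(row)}"
                )
            sid, cls = row[0].strip(), row[1].strip()
            if lineno == 1 and sid.lower() in ("sample", "sample_id", "id"):
                continue
            if sid in labels:
                raise FormatError(f"{path}: duplicate sample id {sid!r} at line {lineno}")
            labels[sid] = cls
    if not labels:
        raise FormatError(f"{path}: no label rows")
    return labels


def read_labeled_dataset(
    matrix_path,
    labels_path,
    delimiter: str | None = None,
    transpose: bool = False,
) -> LabeledDataset:
    """Load a matrix file plus a sample->class label file.

    The delimiter is auto-detected among tab/comma unless given.  Label rows
    are realigned to the matrix column order; any sample present in only one
    of the two files raises :class:`SampleMismatchError` naming it.
    """
    matrix = _read_matrix(Path(matrix_path), delimiter, transpose)
    label_map = _read_labels(Path(labels_path), delimiter)
    matrix_samples = set(matrix.samples)
    label_samples = set(label_map)
    missing_labels = sorted(matrix_samples - label_samples)
    extra_labels = sorted(label_samples - matrix_samples)
    if missing_labels or extra_labels:
        parts = []
        if missing_labels:
            parts.append(f"samples without labels: {missing_labels}")
        if extra_labels:
            parts.append(f"labeled samples not in matrix: {extra_labels}")
        raise SampleMismatchError("; ".join(parts))
    labels = [label_map[s] for s in matrix.samples]
    return LabeledDataset(matrix, labels)


def write_labeled_dataset(ds: LabeledDataset, matrix_path, labels_path) -> None:
    """Write the matrix and label files read back by :func:`read_labeled_dataset`.

    Values keep >= 10 significant digits so a round trip reproduces the
    dataset to well within 1e-9.
    """
    if ds.n_samples == 0 or ds.n_genes == 0:
        raise DatasetError("refusing to write a dataset with no samples or no genes")
    df = pd.DataFrame(ds.values, index=ds.genes, columns=ds.samples)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.12g")
    with open(labels_path, "w", newline="") as fh:
        fh.write("sample_id\tclass\n")
        for sid, cls in zip(ds.samples, ds.labels):
            fh.write(f"{sid}\t{cls}\n")


def read_series_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Convenience reader for GEO series-matrix text exports.

    Strips the ``!``-prefixed metadata lines and surrounding quotes and
    returns the expression table (genes in rows).  No network access is ever
    performed; the file must already be on disk.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            rows.append([cell.strip().strip('"') for cell in line.split(delimiter)])
    if not rows:
        raise FormatError(f"{path}: no table content outside metadata lines")
    header, body = rows[0], rows[1:]
    df = pd.DataFrame(body, columns=header).set_index(header[0])
    return df.astype(float)


_TABLE2_RESOURCE = "table2_rules.txt"


def load_table2_rules() -> RuleSet:
    """The published 16-rule tissue classifier, packaged as a text fixture.

    Fifteen threshold rules plus the default rule (any other condition ->
    large intestine), with thresholds exactly as printed to three decimals.
    """
    text = (
        resources.files("pdxorigin").joinpath("data", _TABLE2_RESOURCE).read_text()
    )
    return parse_rules(text)
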