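"""Delimited-text readers and writers for tables and groupings.

Dialect: delimiter is a tab for ``.tsv`` and a comma for ``.csv``
(overridable), the first row holds column labels, the first column row
labels, encoding UTF-8.  Grouping files are two columns (category, group)
with no header.  Writing then reading reproduces counts exactly and labels
verbatim.
"""

from __future__ import annotations

import csv
import os
from typing import TextIO

from .core import Axis, ContingencyTable, GroupingMap, make_table
from .exceptions import TableParseError


def detect_delimiter(path: str | os.PathLike, delimiter: str | None = None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_rows(path, delim) -> list[list[str]]:
    try:
        with open(path, encoding="utf-8", newline="") as fh:
            rows = [row for row in csv.reader(fh, delimiter=delim) if row]
    except OSError as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    if not rows:
        raise TableParseError(f"{path}: file is empty")
    return rows


def read_table(path: str | os.PathLike, delimiter: str | None = None) -> ContingencyTable:
    """Read a labelled contingency table from delimited text."""
    delim = detect_delimiter(path, delimiter)
    rows = _read_rows(path, delim)
    header = rows[0]
    if len(header) < 2 or len(rows) < 2:
        raise TableParseError(f"{path}: need at least one data row and one data column")
    col_labels = [x.strip() for x in header[1:]]
    width = len(header)
    row_labels: list[str] = []
    counts: list[list[float]] = []
    for rix, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise TableParseError(
                f"{path}: line {rix} has {len(row)} fields, expected {width} (ragged row)"
            )
        row_labels.append(row[0].strip())
        parsed = []
        for cix, cell in enumerate(row[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise TableParseError(
                    f"{path}: non-numeric cell {cell!r} at row {row[0].strip()!r}, "
                    f"column {col_labels[cix]!r}"
                ) from None
        counts.append(parsed)
    return make_table(counts, row_labels, col_labels)


def write_table(
    table: ContingencyTable,
    dest: str | os.PathLike | TextIO,
    delimiter: str | None = None,
    precision: int | None = None,
) -> None:
    """Write a table; integral counts are emitted without a decimal point."""

    def fmt(x: float) -> str:
        if precision is not None:
            return f"{x:.{precision}f}"
        return repr(int(x)) if float(x).is_integer() else repr(float(x))

    def _write(fh: TextIO, delim: str) -> None:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["", *table.col_labels])
        for lab, row in zip(table.row_labels, table.counts):
            w.writerow([lab, *(fmt(x) for x in row)])

    if hasattr(dest, "write"):
        _write(dest, delimiter or "\t")
    else:
        delim = detect_delimiter(dest, delimiter)
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            _write(fh, delim)


def read_grouping(path: str | os.PathLike, axis: Axis | str, delimiter: str | None = None) -> GroupingMap:
    """Read a two-column (category, group) file into a :class:`GroupingMap`."""
    delim = detect_delimiter(path, delimiter)
    rows = _read_rows(path, delim)
    mapping: dict[str, str] = {}
    for rix, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise TableParseError(
                f"{path}: line {rix} has {len(row)} fields, expected 2 (category, group)"
            )
        cat, grp = row[0].strip(), row[1].strip()
        if cat in mapping:
            raise TableParseError(f"{path}: duplicate category {cat!r} at line {rix}")
        mapping[cat] = grp
    return GroupingMap(axis=Axis(axis), mapping=mapping)
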