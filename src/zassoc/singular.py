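"""Per-cell singular Z coefficients and their ranked list.

Each cell (i, j) of a table is scored by collapsing the table to 2x2 —
row i against all other rows pooled, column j against all other columns
pooled — and taking the Z coefficient of that 2x2 table.  On 2x2 tables
Z is symmetric, so singular coefficients are direction-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Axis,
    ContingencyTable,
    GroupingMap,
    collapse,
    z_coefficient,
)
from .exceptions import GroupingCoverageError, ShapeError


@dataclass(frozen=True)
class SingularZMatrix:
    """k x n matrix of per-cell singular Z coefficients."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]


@dataclass(frozen=True)
class RankedAssociation:
    row_label: str
    col_label: str
    z: float


def singular_table(table: ContingencyTable, i: int, j: int) -> ContingencyTable:
    """2x2 collapse distinguishing cell (i, j) from the pooled rest.

    Returns ``[[c_ij, r_i - c_ij], [s_j - c_ij, T - r_i - s_j + c_ij]]``
    with labels ``(L_i, not_L_i) x (L_j, not_L_j)``.  Indices are 0-based.
    """
    k, n = table.shape
    if k < 2 or n < 2:
        raise ShapeError(f"singular collapse needs at least 2x2, got {k}x{n}")
    if not (0 <= i < k) or not (0 <= j < n):
        raise IndexError(f"cell ({i}, {j}) out of range for {k}x{n} table")
    c = table.counts
    cij = c[i, j]
    ri = c[i].sum()
    sj = c[:, j].sum()
    total = c.sum()
    two = np.array([[cij, ri - cij], [sj - cij, total - ri - sj + cij]])
    rl = table.row_labels[i]
    cl = table.col_labels[j]
    return ContingencyTable(two, (rl, f"not_{rl}"), (cl, f"not_{cl}"))


def _apply_groups(table, row_groups, col_groups):
    t = table
    if row_groups is not None:
        if Axis(row_groups.axis) is not Axis.ROWS:
            raise GroupingCoverageError("row_groups must have axis='rows'")
        t = collapse(t, row_groups)
    if col_groups is not None:
        if Axis(col_groups.axis) is not Axis.COLS:
            raise GroupingCoverageError("col_groups must have axis='cols'")
        t = collapse(t, col_groups)
    return t


def z_matrix(
    table: ContingencyTable,
    row_groups: GroupingMap | None = None,
    col_groups: GroupingMap | None = None,
) -> SingularZMatrix:
    """Singular Z coefficient for every cell of the (grouped) table.

    Groupings are applied once, before cell enumeration, so entries refer
    to cells of the collapsed table.
    """
    t = _apply_groups(table, row_groups, col_groups)
    k, n = t.shape
    if k < 2 or n < 2:
        raise ShapeError(f"z_matrix needs a post-grouping table of at least 2x2, got {k}x{n}")
    values = np.empty((k, n))
    for i in range(k):
        for j in range(n):
            values[i, j] = z_coefficient(singular_table(t, i, j)).z
    return SingularZMatrix(values=values, row_labels=t.row_labels, col_labels=t.col_labels)


def z_ranks(
    table: ContingencyTable,
    row_groups: GroupingMap | None = None,
    col_groups: GroupingMap | None = None,
    top: int | None = None,
) -> list[RankedAssociation]:
    """Flattened :func:`z_matrix`, sorted by z descending.

    Ties break by (row index, column index) ascending; ``top`` truncates.
    """
    m = z_matrix(table, row_groups, col_groups)
    records = [
        (float(m.values[i, j]), i, j)
        for i in range(m.values.shape[0])
        for j in range(m.values.shape[1])
    ]
    records.sort(key=lambda t: (-t[0], t[1], t[2]))
    if top is not None:
        records = records[: max(top, 0)]
    return [
        RankedAssociation(row_label=m.row_labels[i], col_label=m.col_labels[j], z=z)
        for z, i, j in records
    ]
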