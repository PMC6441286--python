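"""Core domain types and the directional Z association coefficient.

The Z coefficient quantifies how much knowing the column category of an
observation reduces the error made when predicting its row category.  For a
joint distribution ``p`` with row marginals ``r`` and column marginals ``c``
the squared coefficient is::

    Z^2 = 1 - sum_i  r[i] * prod_j  p[i, j] / (r[i] * c[j])

where rows with ``r[i] == 0`` are skipped and columns with ``c[j] == 0`` are
excluded from every product.  ``Z = sqrt(max(Z^2, 0))`` lies in ``[0, 1]``:
0 for an exact product distribution, 1 when every column concentrates its
mass on a single row (and at least two rows carry mass).  The measure is
asymmetric for tables larger than 2x2; the transposed direction is exposed
through the ``direction`` argument of :func:`z_coefficient`.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    ContractViolationError,
    DimensionMismatchError,
    DuplicateLabelError,
    EmptyTableError,
    GroupingCoverageError,
    InvalidEntryError,
    UndefinedRatioError,
)

logger = logging.getLogger("zassoc")

#: raw Z^2 values above this (in absolute value) are treated as genuine
#: negativity rather than floating-point noise
NEGATIVITY_TOLERANCE = 1e-9


class Direction(str, enum.Enum):
    """Which partition is predicted from which."""

    ROWS_GIVEN_COLS = "rows_given_cols"
    COLS_GIVEN_ROWS = "cols_given_rows"


class Axis(str, enum.Enum):
    ROWS = "rows"
    COLS = "cols"


def _check_labels(labels: Sequence[str], name: str, expected: int) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != expected:
        raise DimensionMismatchError(
            f"{name}: expected {expected} labels, got {len(labels)}"
        )
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise DuplicateLabelError(f"{name}: duplicate labels {dups!r}")
    return labels


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled k x n matrix of non-negative weights.

    Entries need not be integers: the coefficient only depends on
    proportions, so any non-negative weights are accepted.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __init__(self, counts, row_labels, col_labels):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise DimensionMismatchError(
                f"counts: expected a 2-d matrix, got ndim={counts.ndim}"
            )
        k, n = counts.shape
        if k < 1 or n < 1:
            raise DimensionMismatchError(f"counts: empty shape {counts.shape}")
        if not np.all(np.isfinite(counts)):
            bad = np.argwhere(~np.isfinite(counts))[0]
            raise InvalidEntryError(f"counts: non-finite entry at {tuple(bad)}")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise InvalidEntryError(f"counts: negative entry at {tuple(bad)}")
        if counts.sum() <= 0:
            raise EmptyTableError("counts: table sums to zero")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", _check_labels(row_labels, "row_labels", k))
        object.__setattr__(self, "col_labels", _check_labels(col_labels, "col_labels", n))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class JointDistribution:
    """Joint probabilities with row and column marginals."""

    p: np.ndarray
    row_marginals: np.ndarray
    col_marginals: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        if abs(float(self.p.sum()) - 1.0) > 1e-12:
            raise InvalidEntryError("p: probabilities do not sum to 1")


@dataclass(frozen=True)
class GroupingMap:
    """Maps every category label of one axis to a group label."""

    axis: Axis
    mapping: Mapping[str, str]

    def __init__(self, axis, mapping):
        axis = Axis(axis)
        mapping = dict(mapping)
        if not mapping:
            raise GroupingCoverageError("mapping: empty grouping")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "mapping", mapping)


@dataclass(frozen=True)
class AssociationResult:
    """Z coefficient together with its raw square and diagnostics."""

    z: float
    z_squared_raw: float
    direction: Direction
    k_effective: int
    n_effective: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def make_table(counts, row_labels, col_labels) -> ContingencyTable:
    """Validate and build a :class:`ContingencyTable`."""
    return ContingencyTable(counts, row_labels, col_labels)


def normalize(table: ContingencyTable) -> JointDistribution:
    """Turn counts into joint probabilities with marginals."""
    p = table.counts / table.counts.sum()
    return JointDistribution(
        p=p,
        row_marginals=p.sum(axis=1),
        col_marginals=p.sum(axis=0),
        row_labels=table.row_labels,
        col_labels=table.col_labels,
    )


def transpose(table: ContingencyTable) -> ContingencyTable:
    """Swap rows and columns (labels travel with their axis)."""
    return ContingencyTable(table.counts.T, table.col_labels, table.row_labels)


def collapse(table: ContingencyTable, grouping: GroupingMap) -> ContingencyTable:
    """Sum categories of one axis into groups.

    The grouping must cover the axis labels exactly.  Groups are ordered by
    the first appearance of each group along the original axis.
    """
    labels = table.row_labels if grouping.axis is Axis.ROWS else table.col_labels
    label_set = set(labels)
    domain = set(grouping.mapping)
    missing = sorted(label_set - domain)
    extra = sorted(domain - label_set)
    if missing or extra:
        raise GroupingCoverageError(
            f"grouping for axis {grouping.axis.value!r} does not cover the axis: "
            f"unmapped={missing!r}, unknown={extra!r}"
        )
    group_order: list[str] = []
    for lab in labels:
        g = grouping.mapping[lab]
        if g not in group_order:
            group_order.append(g)
    index = {g: i for i, g in enumerate(group_order)}
    assign = np.array([index[grouping.mapping[lab]] for lab in labels])
    if grouping.axis is Axis.ROWS:
        new = np.zeros((len(group_order), table.shape[1]))
        np.add.at(new, assign, table.counts)
        return ContingencyTable(new, group_order, table.col_labels)
    new = np.zeros((table.shape[0], len(group_order)))
    np.add.at(new.T, assign, table.counts.T)
    return ContingencyTable(new, table.row_labels, group_order)


def error_rate_ratio(p_a_given_b: float, p_a: float) -> float:
    """``(1 - P(A|B)) / (1 - P(A))`` — below 1 iff B helps predict A."""
    if not (0.0 <= p_a_given_b <= 1.0) or not (0.0 <= p_a <= 1.0):
        raise InvalidEntryError("probabilities must lie in [0, 1]")
    if p_a == 1.0:
        raise UndefinedRatioError("P(A) = 1: error-rate ratio undefined")
    return (1.0 - p_a_given_b) / (1.0 - p_a)


def row_term(dist: JointDistribution, i: int) -> float:
    """Contribution of row ``i`` to the sum subtracted from 1 in ``Z^2``.

    ``term_i = r[i] * prod_{j: c[j] > 0} p[i, j] / (r[i] * c[j])``.  For an
    exact product distribution this equals ``r[i]``; a single zero cell in a
    supported column annihilates it.
    """
    r = float(dist.row_marginals[i])
    if r <= 0.0:
        raise ContractViolationError(f"row {i} has zero marginal; caller must skip it")
    cols = dist.col_marginals > 0
    ratios = dist.p[i, cols] / (r * dist.col_marginals[cols])
    return float(r * np.prod(ratios))


def z_squared(dist: JointDistribution) -> float:
    """Raw (unclamped) squared Z coefficient of a joint distribution."""
    r = dist.row_marginals
    c = dist.col_marginals
    rows = r > 0
    cols = c > 0
    ratios = dist.p[np.ix_(rows, cols)] / np.outer(r[rows], c[cols])
    terms = r[rows] * np.prod(ratios, axis=1)
    return float(1.0 - terms.sum())


def z_coefficient(
    table: ContingencyTable,
    row_groups: GroupingMap | None = None,
    col_groups: GroupingMap | None = None,
    direction: Direction = Direction.ROWS_GIVEN_COLS,
) -> AssociationResult:
    """Overall Z coefficient of a table, with optional axis groupings.

    Groupings are applied first; ``direction=COLS_GIVEN_ROWS`` then swaps
    the roles of the two partitions by transposing.  ``k_effective`` and
    ``n_effective`` count post-grouping rows/columns with positive mass in
    the orientation of the *input* table.
    """
    direction = Direction(direction)
    t = table
    if row_groups is not None:
        if Axis(row_groups.axis) is not Axis.ROWS:
            raise GroupingCoverageError("row_groups must have axis='rows'")
        t = collapse(t, row_groups)
    if col_groups is not None:
        if Axis(col_groups.axis) is not Axis.COLS:
            raise GroupingCoverageError("col_groups must have axis='cols'")
        t = collapse(t, col_groups)

    k_eff = int(np.count_nonzero(t.counts.sum(axis=1) > 0))
    n_eff = int(np.count_nonzero(t.counts.sum(axis=0) > 0))

    if direction is Direction.COLS_GIVEN_ROWS:
        t = transpose(t)

    warnings: list[str] = []
    raw = z_squared(normalize(t))
    if k_eff < 2 or n_eff < 2:
        warnings.append(
            f"degenerate table: effective shape {k_eff}x{n_eff} carries no "
            "association; Z set to 0"
        )
        raw = 0.0  # formula limit is exactly 0; drop accumulated rounding noise
    if raw < -NEGATIVITY_TOLERANCE:
        warnings.append(f"z_squared_raw = {raw!r} is negative beyond tolerance; clamped to 0")
        logger.warning("negative z_squared_raw=%r clamped to 0", raw)
    z = math.sqrt(max(raw, 0.0))
    return AssociationResult(
        z=z,
        z_squared_raw=raw,
        direction=direction,
        k_effective=k_eff,
        n_effective=n_eff,
        warnings=tuple(warnings),
    )
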