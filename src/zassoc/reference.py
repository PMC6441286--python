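"""Classical association measures used as independent oracles.

These are deliberately computed through routes that do not share code with
:mod:`zassoc.core`: chi-squared comes from :func:`scipy.stats.chi2_contingency`
and the binary Pearson correlation from an explicit 0/1 expansion, so that
equalities like "Z equals Cramér's V on k x 2 tables" are genuine
cross-checks rather than tautologies.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import ContingencyTable
from .exceptions import DegenerateMarginError, InvalidEntryError, ShapeError


def _require_positive_margins(counts: np.ndarray) -> None:
    if np.any(counts.sum(axis=1) <= 0):
        raise DegenerateMarginError("zero row marginal; drop empty rows first")
    if np.any(counts.sum(axis=0) <= 0):
        raise DegenerateMarginError("zero column marginal; drop empty columns first")


def drop_empty(table: ContingencyTable) -> ContingencyTable:
    """Remove all-zero rows and columns (labels follow)."""
    c = table.counts
    rows = c.sum(axis=1) > 0
    cols = c.sum(axis=0) > 0
    return ContingencyTable(
        c[np.ix_(rows, cols)],
        tuple(np.array(table.row_labels)[rows]),
        tuple(np.array(table.col_labels)[cols]),
    )


def chi_squared(table: ContingencyTable) -> float:
    """Pearson chi-squared statistic (no continuity correction)."""
    _require_positive_margins(table.counts)
    if 1 in table.shape:
        return 0.0  # observed == expected by construction
    stat, _, _, _ = stats.chi2_contingency(table.counts, correction=False)
    return float(stat)


def cramers_v(table: ContingencyTable) -> float:
    """Cramér's V: sqrt(chi2 / (T * min(k-1, n-1))), empties dropped first."""
    t = drop_empty(table)
    k, n = t.shape
    if min(k, n) < 2:
        raise ShapeError(f"Cramér's V needs at least 2x2 after dropping empties, got {k}x{n}")
    chi2 = chi_squared(t)
    return float(np.sqrt(chi2 / (t.total * (min(k, n) - 1))))


def phi(table: ContingencyTable) -> float:
    """Signed phi coefficient of a 2x2 table: (ad - bc) / sqrt of margin product."""
    if table.shape != (2, 2):
        raise ShapeError(f"phi is defined for 2x2 tables, got {table.shape}")
    _require_positive_margins(table.counts)
    (a, b), (c, d) = table.counts
    return float((a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d)))


def pearson_binary(table: ContingencyTable) -> float:
    """Pearson correlation of the paired 0/1 expansion of a 2x2 table.

    Each cell (i, j) contributes c_ij observations with x = i, y = j; the
    result equals :func:`phi` by the phi-Pearson identity.
    """
    if table.shape != (2, 2):
        raise ShapeError(f"pearson_binary is defined for 2x2 tables, got {table.shape}")
    _require_positive_margins(table.counts)
    counts = table.counts
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-9):
        raise InvalidEntryError("pearson_binary requires integral counts for the expansion")
    xs, ys = [], []
    for i in (0, 1):
        for j in (0, 1):
            m = int(rounded[i, j])
            xs.extend([i] * m)
            ys.extend([j] * m)
    x = np.array(xs, dtype=float)
    y = np.array(ys, dtype=float)
    # np.corrcoef is stable here because both margins are positive
    return float(np.corrcoef(x, y)[0, 1])
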