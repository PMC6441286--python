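"""Generators of contingency tables with known association structure.

Every generator returns a validated :class:`~zassoc.core.ContingencyTable`
and takes an explicit ``seed`` where randomness is involved — there is no
global random state.  Exact-mode tables may contain non-integral cells,
which the core accepts (weights, not counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core import ContingencyTable
from .exceptions import DegenerateMarginError, DimensionMismatchError, InvalidEntryError

_KINDS = ("independent", "functional", "dirichlet", "blend")


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a synthetic table (used by the CLI)."""

    kind: str
    k: int = 2
    n: int = 2
    total: float = 100.0
    seed: int = 0
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidEntryError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.k < 1 or self.n < 1 or self.total <= 0:
            raise InvalidEntryError("k, n must be >= 1 and total > 0")


def _default_labels(prefix: str, m: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(m))


def _check_marginals(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise DimensionMismatchError(f"{name}: expected a 1-d vector")
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-12:
        raise InvalidEntryError(f"{name}: must be non-negative and sum to 1")
    return v


def independent_table(
    row_marginals: Sequence[float],
    col_marginals: Sequence[float],
    total: float,
    mode: str = "exact",
    seed: int | None = None,
) -> ContingencyTable:
    """Product table (``mode='exact'``) or a multinomial sample of it.

    The exact table ``total * outer(r, c)`` has Z = 0 by construction; the
    multinomial sample converges to it as ``total`` grows.
    """
    r = _check_marginals(row_marginals, "row_marginals")
    c = _check_marginals(col_marginals, "col_marginals")
    p = np.outer(r, c)
    if mode == "exact":
        counts = total * p
    elif mode == "multinomial":
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(int(total), p.ravel()).reshape(p.shape).astype(float)
    else:
        raise InvalidEntryError(f"mode must be 'exact' or 'multinomial', got {mode!r}")
    return ContingencyTable(counts, _default_labels("A", r.size), _default_labels("B", c.size))


def functional_table(
    col_to_row: Sequence[int],
    col_marginals: Sequence[float] | None = None,
    total: float = 100.0,
) -> ContingencyTable:
    """Table in which each column determines a single row, so Z = 1.

    ``col_to_row[j]`` is the (0-based) row receiving all of column j's mass;
    at least two distinct rows must be used.
    """
    assign = np.asarray(col_to_row, dtype=int)
    n = assign.size
    if n < 1:
        raise DimensionMismatchError("col_to_row: empty assignment")
    if np.any(assign < 0):
        raise InvalidEntryError("col_to_row: negative row index")
    k = int(assign.max()) + 1
    if np.unique(assign).size < 2:
        raise DegenerateMarginError("col_to_row uses a single row: table would be degenerate")
    if col_marginals is None:
        c = np.full(n, 1.0 / n)
    else:
        c = _check_marginals(col_marginals, "col_marginals")
        if c.size != n:
            raise DimensionMismatchError("col_marginals length must match col_to_row")
    counts = np.zeros((k, n))
    counts[assign, np.arange(n)] = total * c
    return ContingencyTable(counts, _default_labels("A", k), _default_labels("B", n))


def dirichlet_table(
    k: int, n: int, concentration: float = 1.0, total: float = 100.0, seed: int = 0
) -> ContingencyTable:
    """Cell probabilities from a symmetric Dirichlet over the k*n cells."""
    if k < 2 or n < 2:
        raise DimensionMismatchError(f"dirichlet_table needs k, n >= 2, got {k}x{n}")
    if concentration <= 0:
        raise InvalidEntryError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(k * n, concentration)).reshape(k, n)
    return ContingencyTable(total * p, _default_labels("A", k), _default_labels("B", n))


def association_blend(
    epsilon: float,
    independent_base: ContingencyTable,
    functional_target: ContingencyTable,
    total: float,
) -> ContingencyTable:
    """Cellwise mix ``(1 - eps) * base + eps * target``, rescaled to ``total``.

    With a product base and a functional target sharing marginals, Z moves
    monotonically from 0 (eps=0) to 1 (eps=1).
    """
    if not (0.0 <= epsilon <= 1.0):
        raise InvalidEntryError(f"epsilon must lie in [0, 1], got {epsilon}")
    if independent_base.shape != functional_target.shape:
        raise DimensionMismatchError("base and target shapes differ")
    if (
        independent_base.row_labels != functional_target.row_labels
        or independent_base.col_labels != functional_target.col_labels
    ):
        raise DimensionMismatchError("base and target labels differ")
    base = independent_base.counts / independent_base.total
    target = functional_target.counts / functional_target.total
    mix = (1.0 - epsilon) * base + epsilon * target
    return ContingencyTable(
        total * mix / mix.sum(), independent_base.row_labels, independent_base.col_labels
    )


def generate(spec: GeneratorSpec) -> ContingencyTable:
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    p = spec.parameters
    if spec.kind == "independent":
        r = p.get("row_marginals", np.full(spec.k, 1.0 / spec.k))
        c = p.get("col_marginals", np.full(spec.n, 1.0 / spec.n))
        return independent_table(r, c, spec.total, p.get("mode", "exact"), spec.seed)
    if spec.kind == "functional":
        assign = p.get("col_to_row", [j % spec.k for j in range(spec.n)])
        return functional_table(assign, p.get("col_marginals"), spec.total)
    if spec.kind == "dirichlet":
        return dirichlet_table(spec.k, spec.n, p.get("concentration", 1.0), spec.total, spec.seed)
    # blend: uniform product base vs cyclic functional target of the same shape
    eps = p.get("epsilon", 0.5)
    base = independent_table(
        np.full(spec.k, 1.0 / spec.k), np.full(spec.n, 1.0 / spec.n), spec.total
    )
    target_counts = np.zeros((spec.k, spec.n))
    target_counts[np.arange(spec.n) % spec.k, np.arange(spec.n)] = spec.total / spec.n
    target = ContingencyTable(target_counts, base.row_labels, base.col_labels)
    return association_blend(eps, base, target, spec.total)
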