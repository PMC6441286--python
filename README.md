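# zassoc

Directional (asymmetric) **Z association coefficient** for k×n contingency
tables, with per-cell singular coefficients, ranked association lists,
arbitrary category grouping, classical oracle measures (χ², Cramér's V, φ,
binary Pearson) and synthetic table generators.

For a joint distribution `p` with row marginals `r` and column marginals
`c`, the squared coefficient is

```
Z²(rows:cols) = 1 − Σ_i  r[i] · Π_j  p[i,j] / (r[i] · c[j])
```

(rows with zero marginal are skipped, columns with zero marginal excluded
from every product) and `Z = sqrt(max(Z², 0))`. `Z` is 0 for independent
variables, 1 when each column determines a single row, equals Cramér's V on
tables with two columns and |φ| (= the binary Pearson correlation) on 2×2
tables, and is asymmetric for anything larger. Note that the raw square can
be genuinely negative for some tables with ≥ 3 columns (e.g.
`[[1,1,4],[1,1,6]]` → −0.00382); such values are clamped to 0 with an
explicit warning, never silently.

## Library

```python
import zassoc as za

t = za.make_table([[2, 1], [1, 2], [2, 2]], ["A1", "A2", "A3"], ["B1", "B2"])
za.z_coefficient(t).z                                # 0.258199
za.z_coefficient(t, direction="cols_given_rows").z   # 0.333333 (asymmetry)

g = za.GroupingMap("rows", {"A1": "g1", "A2": "g1", "A3": "g2"})
za.z_coefficient(t, row_groups=g).z                  # 0.0 (collapses to a product)

za.z_matrix(t).values        # per-cell singular Z via 2x2 collapse
za.z_ranks(t, top=3)         # the same, ranked
```

## CLI

Tables are delimited text (tab for `.tsv`, comma for `.csv`): first row =
column labels, first column = row labels. Grouping files are two columns
(category, group) without a header.

```sh
zassoc z table.tsv [--row-groups g.tsv] [--direction rows|cols] [--json]
zassoc matrix table.tsv              # singular-Z matrix as TSV
zassoc ranks table.tsv --top 10      # ranked list: row, col, z
zassoc oracle table.tsv --measure chi2|cramers-v|phi
zassoc simulate --kind independent|functional|dirichlet|blend --seed 1 ...
```

Exit status 0 on success, 2 on validation/usage errors; logs go to stderr;
`--precision` controls decimal places (default 6).

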