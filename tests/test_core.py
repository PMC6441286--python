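import numpy as np
import pytest

from zassoc import (
    Axis,
    Direction,
    GroupingMap,
    collapse,
    error_rate_ratio,
    make_table,
    normalize,
    row_term,
    transpose,
    z_coefficient,
    z_squared,
)
from zassoc.exceptions import (
    ContractViolationError,
    DimensionMismatchError,
    DuplicateLabelError,
    EmptyTableError,
    GroupingCoverageError,
    InvalidEntryError,
    UndefinedRatioError,
)


class TestMakeTable:
    def test_valid_2x2(self):
        t = make_table([[3, 2], [1, 4]], ["a", "abar"], ["b", "bbar"])
        assert t.shape == (2, 2)
        assert t.total == 10

    def test_negative_entry(self):
        with pytest.raises(InvalidEntryError, match="negative"):
            make_table([[1, -1]], ["a"], ["b", "c"])

    def test_nan_entry(self):
        with pytest.raises(InvalidEntryError, match="non-finite"):
            make_table([[1, float("nan")]], ["a"], ["b", "c"])

    def test_all_zero(self):
        with pytest.raises(EmptyTableError):
            make_table([[0, 0], [0, 0]], ["a", "b"], ["c", "d"])

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError, match="row_labels"):
            make_table([[1, 2]], ["a", "b"], ["c", "d"])

    def test_duplicate_labels(self):
        with pytest.raises(DuplicateLabelError, match="col_labels"):
            make_table([[1, 2]], ["a"], ["c", "c"])


class TestNormalize:
    def test_worked(self, table_2x2):
        d = normalize(table_2x2)
        np.testing.assert_allclose(d.p, [[0.3, 0.2], [0.1, 0.4]])
        np.testing.assert_allclose(d.row_marginals, [0.5, 0.5])
        np.testing.assert_allclose(d.col_marginals, [0.4, 0.6])

    def test_uniform(self):
        d = normalize(make_table([[1, 1], [1, 1]], ["a", "b"], ["c", "d"]))
        np.testing.assert_allclose(d.p, 0.25)
        np.testing.assert_allclose(d.row_marginals, 0.5)

    def test_3x2(self, table_3x2):
        d = normalize(table_3x2)
        np.testing.assert_allclose(d.row_marginals, [0.3, 0.3, 0.4])
        np.testing.assert_allclose(d.col_marginals, [0.5, 0.5])


class TestCollapse:
    def test_row_merge(self, table_3x2):
        g = GroupingMap(Axis.ROWS, {"A1": "g1", "A2": "g1", "A3": "g2"})
        c = collapse(table_3x2, g)
        np.testing.assert_array_equal(c.counts, [[3, 3], [2, 2]])
        assert c.row_labels == ("g1", "g2")

    def test_identity(self, table_3x2):
        g = GroupingMap(Axis.ROWS, {l: l for l in table_3x2.row_labels})
        c = collapse(table_3x2, g)
        np.testing.assert_array_equal(c.counts, table_3x2.counts)
        assert c.row_labels == table_3x2.row_labels

    def test_col_merge(self):
        t = make_table([[18, 18, 4], [7, 7, 46]], ["A1", "A2"], ["B1", "B2", "B3"])
        g = GroupingMap(Axis.COLS, {"B1": "m", "B2": "m", "B3": "s"})
        c = collapse(t, g)
        np.testing.assert_array_equal(c.counts, [[36, 4], [14, 46]])
        assert c.col_labels == ("m", "s")

    def test_unmapped_label(self, table_3x2):
        g = GroupingMap(Axis.ROWS, {"A1": "g1", "A2": "g1"})
        with pytest.raises(GroupingCoverageError, match="A3"):
            collapse(table_3x2, g)

    def test_unknown_label(self, table_3x2):
        g = GroupingMap(Axis.ROWS, {"A1": "g", "A2": "g", "A3": "g", "A4": "g"})
        with pytest.raises(GroupingCoverageError, match="A4"):
            collapse(table_3x2, g)

    def test_first_appearance_order(self):
        t = make_table([[1, 1], [2, 2], [3, 3]], ["x", "y", "z"], ["B1", "B2"])
        g = GroupingMap(Axis.ROWS, {"x": "late", "y": "early", "z": "late"})
        c = collapse(t, g)
        assert c.row_labels == ("late", "early")
        np.testing.assert_array_equal(c.counts, [[4, 4], [2, 2]])


class TestTranspose:
    def test_basic(self, table_3x2):
        t = transpose(table_3x2)
        np.testing.assert_array_equal(t.counts, [[2, 1, 2], [1, 2, 2]])
        assert t.row_labels == ("B1", "B2")

    def test_involution(self, table_3x2):
        t = transpose(transpose(table_3x2))
        np.testing.assert_array_equal(t.counts, table_3x2.counts)
        assert t.row_labels == table_3x2.row_labels

    def test_1xn(self):
        t = transpose(make_table([[1, 2, 3]], ["a"], ["x", "y", "z"]))
        assert t.shape == (3, 1)


class TestErrorRateRatio:
    def test_arithmetic(self):
        assert error_rate_ratio(0.8, 0.5) == pytest.approx(0.4)

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.99])
    def test_independence_identity(self, p):
        assert error_rate_ratio(p, p) == pytest.approx(1.0)

    def test_perfect_prediction(self):
        assert error_rate_ratio(1.0, 0.5) == 0.0

    def test_degenerate(self):
        with pytest.raises(UndefinedRatioError):
            error_rate_ratio(0.5, 1.0)


class TestRowTerm:
    def test_uninformative_row(self, table_3x2):
        # P(A3|B1) = P(A3|B2) = 0.4 = p_3., so the term is the marginal itself
        assert row_term(normalize(table_3x2), 2) == pytest.approx(0.4, abs=1e-12)

    def test_informative_row(self, table_3x2):
        assert row_term(normalize(table_3x2), 0) == pytest.approx(0.3 * (4 / 3) * (2 / 3), abs=1e-12)

    def test_zero_cell_annihilates(self, table_diag):
        # each row of the diagonal table has a zero cell in a supported column
        assert row_term(normalize(table_diag), 0) == 0.0
        assert row_term(normalize(table_diag), 1) == 0.0

    def test_zero_marginal_contract(self):
        t = make_table([[0, 0], [1, 1]], ["A1", "A2"], ["B1", "B2"])
        with pytest.raises(ContractViolationError):
            row_term(normalize(t), 0)


class TestZSquared:
    def test_2x2(self, table_2x2):
        assert z_squared(normalize(table_2x2)) == pytest.approx(1 / 6, abs=1e-12)

    def test_3x2(self, table_3x2):
        assert z_squared(normalize(table_3x2)) == pytest.approx(1 / 15, abs=1e-12)

    def test_asymmetry(self, table_3x2):
        assert z_squared(normalize(transpose(table_3x2))) == pytest.approx(1 / 9, abs=1e-12)

    def test_product_zero(self, product_table):
        assert z_squared(normalize(product_table)) == pytest.approx(0.0, abs=1e-12)


class TestZCoefficient:
    def test_2x2(self, table_2x2):
        res = z_coefficient(table_2x2)
        assert res.z == pytest.approx(0.408248, abs=1e-6)
        assert res.k_effective == res.n_effective == 2
        assert res.warnings == ()

    def test_grouped_to_independence(self, table_3x2):
        g = GroupingMap(Axis.ROWS, {"A1": "g1", "A2": "g1", "A3": "g2"})
        assert z_coefficient(table_3x2, row_groups=g).z == pytest.approx(0.0, abs=1e-12)

    def test_maximal(self, table_diag):
        assert z_coefficient(table_diag).z == 1.0

    def test_single_column_degenerate(self):
        res = z_coefficient(make_table([[3], [7]], ["a", "b"], ["only"]))
        assert res.z == 0.0
        assert res.n_effective == 1
        assert any("degenerate" in w for w in res.warnings)

    def test_single_row_degenerate(self):
        res = z_coefficient(make_table([[3, 7]], ["only"], ["a", "b"]))
        assert res.z == 0.0
        assert any("degenerate" in w for w in res.warnings)

    def test_direction_flag_matches_transpose(self, table_3x2):
        rev = z_coefficient(table_3x2, direction=Direction.COLS_GIVEN_ROWS)
        fwd_t = z_coefficient(transpose(table_3x2))
        assert rev.z == pytest.approx(fwd_t.z, abs=0)
        assert rev.direction is Direction.COLS_GIVEN_ROWS

    def test_wrong_axis_grouping_rejected(self, table_3x2):
        g = GroupingMap(Axis.COLS, {"B1": "g", "B2": "g"})
        with pytest.raises(GroupingCoverageError):
            z_coefficient(table_3x2, row_groups=g)
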