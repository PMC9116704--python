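"""Matrix data model, I/O round trips, missingness, initialization, errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloimpute import (
    DistanceMatrix,
    column_order,
    initial_guess,
    inject_missing,
    read_distance_matrix,
    set_difference_error,
    write_distance_matrix,
)
from phyloimpute.errors import (
    DiagonalMissingError,
    DistanceMatrixError,
    DuplicateLabelError,
    NegativeDistanceError,
    NonSquareMatrixError,
)
from phyloimpute.matrix_core import max_missing_pairs


def _write(tmp_path, text, name="m.phy"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestRead:
    def test_fully_observed_2x2(self, tmp_path):
        path = _write(tmp_path, "2\nA 0 0.5\nB 0.5 0\n")
        m, mask = read_distance_matrix(path)
        assert m.labels == ("A", "B")
        np.testing.assert_allclose(m.values, [[0, 0.5], [0.5, 0]])
        assert not mask.any()

    def test_single_sentinel_sets_mask(self, tmp_path):
        path = _write(tmp_path, "2\nA 0 0.5\nB NA 0\n")
        m, mask = read_distance_matrix(path)
        assert mask[1, 0] and mask.sum() == 1
        assert np.isnan(m.values[1, 0])

    @pytest.mark.parametrize("token", ["NA", "?", "-1"])
    def test_all_default_sentinels(self, tmp_path, token):
        path = _write(tmp_path, f"2\nA 0 {token}\nB 0.5 0\n")
        _, mask = read_distance_matrix(path)
        assert mask[0, 1]

    @pytest.mark.parametrize(
        "text,exc",
        [
            ("3\nA 0 1\nB 1 0\n", NonSquareMatrixError),
            ("2\nA 0 1 2\nB 1 0 2\n", NonSquareMatrixError),
            ("2\nA 0 1\nA 1 0\n", DuplicateLabelError),
            ("2\nA NA 1\nB 1 0\n", DiagonalMissingError),
            ("2\nA 0 -0.5\nB -0.5 0\n", NegativeDistanceError),
        ],
    )
    def test_distinct_parse_errors(self, tmp_path, text, exc):
        with pytest.raises(exc):
            read_distance_matrix(_write(tmp_path, text))

    def test_error_names_row_and_column(self, tmp_path):
        path = _write(tmp_path, "2\nA 0 -0.5\nB -0.5 0\n")
        with pytest.raises(NegativeDistanceError, match="'A'.*'B'"):
            read_distance_matrix(path)


class TestWriteRoundTrip:
    def test_phylip_skeleton(self, tmp_path, small_matrix):
        path = str(tmp_path / "m.phy")
        write_distance_matrix(small_matrix, None, path)
        lines = open(path).read().splitlines()
        assert lines[0].strip() == "4"
        assert all(len(ln.split()) == 5 for ln in lines[1:])

    def test_masked_cell_emits_na(self, tmp_path, small_matrix):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        path = str(tmp_path / "m.phy")
        write_distance_matrix(small_matrix, mask, path)
        assert open(path).read().splitlines()[1].split()[2] == "NA"

    @pytest.mark.parametrize("fmt,name", [("phylip_square", "m.phy"), ("csv", "m.csv")])
    def test_round_trip_identity(self, tmp_path, fmt, name, rng):
        n = 6
        v = rng.uniform(0.1, 5, (n, n))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0)
        m = DistanceMatrix([f"otu{i}" for i in range(n)], v)
        mask = np.zeros((n, n), dtype=bool)
        mask[0, 2] = mask[2, 0] = True
        path = str(tmp_path / name)
        write_distance_matrix(m, mask, path, format=fmt)
        m2, mask2 = read_distance_matrix(path, format=fmt)
        assert m2.labels == m.labels
        np.testing.assert_array_equal(mask2, mask)
        np.testing.assert_array_equal(m2.values[~mask], m.values[~mask])


class TestInjectMissing:
    def test_floor_to_zero_gives_empty_mask(self, small_matrix, rng):
        # floor(0.1 * 6 pairs) = 0
        assert not inject_missing(small_matrix, 0.1, rng).any()

    def test_count_formula_9x9_5pct(self):
        inst_labels = [f"o{i}" for i in range(9)]
        v = np.abs(np.arange(81).reshape(9, 9) - np.arange(81).reshape(9, 9).T) / 10.0
        m = DistanceMatrix(inst_labels, v)
        mask = inject_missing(m, 0.05, 7)
        assert mask.sum() == 2  # floor(0.05 * 36) = 1 pair, two cells

    @pytest.mark.parametrize("fraction", [0.05, 0.2, 0.5])
    def test_mask_invariants(self, fraction, rng):
        n = 10
        v = rng.uniform(0.5, 3, (n, n))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0)
        m = DistanceMatrix([f"o{i}" for i in range(n)], v)
        mask = inject_missing(m, fraction, np.random.default_rng(3))
        assert mask.sum() == 2 * math.floor(fraction * n * (n - 1) / 2)
        np.testing.assert_array_equal(mask, mask.T)
        assert not np.diag(mask).any()
        off = ~np.eye(n, dtype=bool)
        assert ((~mask & off).sum(axis=0) >= 1).all()

    def test_determinism_under_seed(self, small_matrix):
        a = inject_missing(small_matrix, 0.5, 11)
        b = inject_missing(small_matrix, 0.5, 11)
        np.testing.assert_array_equal(a, b)

    def test_infeasible_fraction_raises(self, small_matrix):
        with pytest.raises(DistanceMatrixError):
            inject_missing(small_matrix, 1.0, 0)  # 6 pairs > max 4 for n=4

    def test_max_missing_pairs_bound(self):
        assert max_missing_pairs(4) == 4
        assert max_missing_pairs(9) == 31


class TestInitialGuess:
    def test_identity_on_complete_symmetric(self, small_matrix):
        mask = np.zeros((4, 4), dtype=bool)
        out = initial_guess(small_matrix, mask)
        np.testing.assert_array_equal(out.values, small_matrix.values)

    def test_two_step_hand_trace(self):
        # d(0,1)=d(1,0) missing; column 0 observes {4}, column 1 observes {6}
        v = np.array([[0.0, np.nan, 4.0], [np.nan, 0.0, 6.0], [4.0, 6.0, 0.0]])
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        out = initial_guess(DistanceMatrix(("a", "b", "c"), v), mask)
        # step 1: d(0,1) <- 6 (col-1 mean), d(1,0) <- 4; step 2: both <- 5
        assert out.values[0, 1] == out.values[1, 0] == 5.0

    def test_output_symmetric_for_random_masks(self, rng):
        n = 7
        v = rng.uniform(0.1, 2, (n, n))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0)
        m = DistanceMatrix([f"o{i}" for i in range(n)], v)
        mask = inject_missing(m, 0.3, rng)
        out = initial_guess(m, mask)
        assert out.is_symmetric()
        assert (np.diag(out.values) == 0).all()
        obs = ~mask
        np.testing.assert_array_equal(out.values[obs], m.values[obs])

    def test_fully_missing_column_raises(self):
        v = np.zeros((4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:, 0] = mask[0, 1:] = True
        with pytest.raises(DistanceMatrixError, match="remove"):
            initial_guess(DistanceMatrix(("a", "b", "c", "d"), np.where(mask, np.nan, v)), mask)


class TestColumnOrder:
    @pytest.mark.parametrize(
        "cols,expected",
        [
            # counts [2,0,1] -> order [2,0], column 1 skipped
            ([(1, 0), (2, 0), (1, 2)], [2, 0]),
        ],
    )
    def test_sort_skips_complete_columns(self, cols, expected):
        mask = np.zeros((3, 3), dtype=bool)
        for r, c in cols:
            mask[r, c] = True
        assert column_order(mask).order.tolist() == expected

    def test_tie_broken_by_lowest_index(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[[1, 0, 3, 2], [0, 1, 2, 3]] = True  # one missing per column
        assert column_order(mask).order.tolist() == [0, 1, 2, 3]

    def test_all_observed_gives_empty_order(self):
        assert column_order(np.zeros((5, 5), dtype=bool)).order.size == 0


class TestSetDifferenceError:
    def test_zero_iff_equal(self, small_matrix):
        assert set_difference_error(small_matrix, small_matrix) == 0.0

    def test_direct_arithmetic(self):
        x_new = np.array([[0.0, 2.0], [2.0, 0.0]])
        x_old = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert set_difference_error(x_new, x_old) == pytest.approx(0.25)

    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_scale_invariance(self, k):
        x_new = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 3.0], [1.0, 3.0, 0.0]])
        x_old = x_new + 0.5
        base = set_difference_error(x_new, x_old + 0)
        assert set_difference_error(k * x_new, k * (x_old)) == pytest.approx(base, rel=1e-9)

    def test_all_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            set_difference_error(np.zeros((2, 2)), np.ones((2, 2)))
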