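"""Compositional primitives: closure, PLR matrix, clr, SBP contrasts,
balance round trips and variance bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plrspca import (
    CompositionTable,
    SbpScheme,
    balances_to_composition,
    center_columns,
    close,
    clr_matrix,
    contrast_from_sbp,
    plr_matrix,
    plr_variance_ranks,
    total_variance,
)
from plrspca.coda import (
    PlrMatrix,
    composition_to_balances,
    read_composition_csv,
    read_sbp_csv,
    write_composition_csv,
    write_sbp_csv,
)
from conftest import random_composition


class TestClose:
    @pytest.mark.parametrize(
        "row, constant, expected",
        [
            ([2, 3, 5], 1.0, [0.2, 0.3, 0.5]),
            ([1, 1, 1, 1], 100.0, [25, 25, 25, 25]),
        ],
    )
    def test_normalises_rows(self, row, constant, expected):
        table = close(np.array([row], dtype=float), constant)
        np.testing.assert_allclose(table.values[0], expected)

    def test_idempotent_and_ratio_preserving(self, rng):
        raw = np.exp(rng.normal(size=(5, 4)))
        once = close(raw, 1.0)
        twice = close(once, 1.0)
        np.testing.assert_allclose(once.values, twice.values)
        # ratios within each row survive closure
        np.testing.assert_allclose(once.values[:, 0] / once.values[:, 1], raw[:, 0] / raw[:, 1])

    def test_rejects_nonpositive_entries(self):
        with pytest.raises(ValueError, match="row 1, column 2"):
            close(np.array([[1.0, 2, 3], [1, 2, 0]]), 1.0)


class TestPlrMatrix:
    def test_column_count_and_lexicographic_order(self, rng):
        table = random_composition(rng, 4, 10)
        m = plr_matrix(table)
        assert m.P == 45  # D(D-1)/2 stored, D(D-1)=90 up to sign
        names = table.part_names
        expected = [(names[i], names[j]) for i in range(10) for j in range(i + 1, 10)]
        assert list(m.pairs) == expected

    def test_equal_parts_give_zero_row(self):
        table = CompositionTable(np.array([[3.0, 3, 3, 3]]), ("a", "b", "c", "d"))
        np.testing.assert_allclose(plr_matrix(table).values[0], 0.0)

    def test_log_arithmetic(self):
        e = np.e
        table = CompositionTable(np.array([[e**2, e, 1.0]]), ("a", "b", "c"))
        np.testing.assert_allclose(plr_matrix(table).values[0], [1.0, 2.0, 1.0])

    def test_plr_equals_clr_difference(self, rng):
        table = random_composition(rng, 6, 5)
        m = plr_matrix(table)
        clr = clr_matrix(table)
        idx = {name: j for j, name in enumerate(table.part_names)}
        for p, (a, b) in enumerate(m.pairs):
            np.testing.assert_allclose(m.values[:, p], clr[:, idx[a]] - clr[:, idx[b]], atol=1e-10)

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, factor):
        rng = np.random.default_rng(seed)
        table = random_composition(rng, 5, 4)
        scaled = CompositionTable(
            table.values * np.r_[factor, np.ones(4)][:, None], table.part_names
        )
        np.testing.assert_allclose(
            plr_matrix(table).values, plr_matrix(scaled).values, atol=1e-9
        )


class TestCenterAndVariance:
    def test_centering(self, rng):
        m = plr_matrix(random_composition(rng, 7, 4))
        c = center_columns(m)
        assert c.centered
        np.testing.assert_allclose(c.values.mean(axis=0), 0.0, atol=1e-10)
        # already-centred input passes through numerically unchanged
        np.testing.assert_allclose(center_columns(c).values, c.values, atol=1e-12)

    def test_single_row_centres_to_zero(self):
        table = CompositionTable(np.array([[1.0, 2, 3]]), ("a", "b", "c"))
        np.testing.assert_allclose(center_columns(plr_matrix(table)).values, 0.0)

    def test_total_variance_matches_brute_force(self, rng):
        m = center_columns(plr_matrix(random_composition(rng, 3, 3)))
        brute = sum(np.var(m.values[:, p], ddof=1) for p in range(m.P))
        assert total_variance(m) == pytest.approx(brute, rel=1e-12)

    def test_total_variance_scale_invariant(self, rng):
        table = random_composition(rng, 8, 5)
        closed = close(table, 100.0)
        tv1 = total_variance(center_columns(plr_matrix(table)))
        tv2 = total_variance(center_columns(plr_matrix(closed)))
        assert tv1 == pytest.approx(tv2, rel=1e-10)

    def test_constant_composition_has_zero_variance(self):
        table = CompositionTable(np.full((4, 3), 2.0), ("a", "b", "c"))
        assert total_variance(center_columns(plr_matrix(table))) == 0.0

    def test_variance_ranks(self, rng):
        m = center_columns(plr_matrix(random_composition(rng, 20, 5)))
        ranks = plr_variance_ranks(m)
        variances = m.values.var(axis=0, ddof=1)
        assert sorted(ranks) == list(range(1, m.P + 1))
        assert ranks[np.argmax(variances)] == 1
        # brute-force sort agreement
        order = np.argsort(-variances, kind="stable")
        np.testing.assert_array_equal(np.argsort(ranks), order)

    def test_variance_rank_ties_follow_pair_order(self):
        values = np.array([[1.0, -1.0, 1.0], [-1.0, 1.0, -1.0]])
        m = PlrMatrix(values, (("a", "b"), ("a", "c"), ("b", "c")), centered=True)
        np.testing.assert_array_equal(plr_variance_ranks(m), [1, 2, 3])


class TestClr:
    def test_examples(self):
        e = np.e
        table = CompositionTable(np.array([[e, e, e], [e**2, 1.0, 1.0]]), ("a", "b", "c"))
        clr = clr_matrix(table)
        np.testing.assert_allclose(clr[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(clr[1], [4 / 3, -2 / 3, -2 / 3])

    def test_rows_sum_to_zero(self, rng):
        clr = clr_matrix(random_composition(rng, 10, 6))
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-10)


def _random_sbp(rng: np.random.Generator, D: int) -> SbpScheme:
    """Random binary tree over D parts, encoded as an SBP sign matrix."""
    signs = np.zeros((D, D - 1), dtype=int)
    col = 0
    groups = [list(range(D))]
    while groups:
        grp = groups.pop()
        if len(grp) < 2:
            continue
        cut = int(rng.integers(1, len(grp)))
        perm = rng.permutation(grp)
        pos, neg = perm[:cut], perm[cut:]
        signs[pos, col] = 1
        signs[neg, col] = -1
        col += 1
        groups.extend([pos.tolist(), neg.tolist()])
    return SbpScheme(signs, tuple(f"p{j}" for j in range(D)))


class TestSbpAndContrast:
    def test_two_part_balance_coefficients(self):
        scheme = SbpScheme(np.array([[1], [-1]]), ("a", "b"))
        contrast = contrast_from_sbp(scheme)
        np.testing.assert_allclose(contrast.coefficients, [[np.sqrt(0.5), -np.sqrt(0.5)]])

    def test_three_part_coefficients(self):
        scheme = SbpScheme(np.array([[1, 1], [1, -1], [-1, 0]]), ("a", "b", "c"))
        V = contrast_from_sbp(scheme).coefficients
        np.testing.assert_allclose(
            V,
            [
                [np.sqrt(1 / 6), np.sqrt(1 / 6), -np.sqrt(2 / 3)],
                [np.sqrt(1 / 2), -np.sqrt(1 / 2), 0.0],
            ],
        )

    @given(st.integers(0, 2**31 - 1), st.integers(3, 9))
    def test_random_sbp_contrast_is_orthonormal_zero_sum(self, seed, D):
        scheme = _random_sbp(np.random.default_rng(seed), D)
        V = contrast_from_sbp(scheme).coefficients
        np.testing.assert_allclose(V @ V.T, np.eye(D - 1), atol=1e-10)
        np.testing.assert_allclose(V.sum(axis=1), 0.0, atol=1e-10)

    def test_rejects_column_without_both_signs(self):
        signs = np.array([[1, 1], [1, 0], [-1, 0]])
        with pytest.raises(ValueError, match="at least one"):
            SbpScheme(signs, ("a", "b", "c"))

    def test_rejects_non_nested_partition(self):
        # two overlapping, non-hierarchical splits of 4 parts
        signs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 0]])
        with pytest.raises(ValueError):
            SbpScheme(signs, ("a", "b", "c", "d"))


class TestBalanceTransforms:
    def test_zero_coordinates_give_uniform_composition(self):
        scheme = SbpScheme(np.array([[1, 1], [1, -1], [-1, 0]]), ("a", "b", "c"))
        table = balances_to_composition(np.zeros((2, 2)), contrast_from_sbp(scheme), 1.0)
        np.testing.assert_allclose(table.values, 1 / 3)

    @given(st.integers(0, 2**31 - 1), st.integers(3, 8))
    def test_round_trip(self, seed, D):
        rng = np.random.default_rng(seed)
        scheme = _random_sbp(rng, D)
        contrast = contrast_from_sbp(scheme)
        coords = rng.normal(size=(4, D - 1))
        table = balances_to_composition(coords, contrast, 1.0)
        np.testing.assert_allclose(composition_to_balances(table, contrast), coords, atol=1e-8)

    def test_one_vs_one_balance_ratio_formula(self):
        # a 1-vs-1 balance b between parts (a, b) fixes their ratio to
        # a/b = exp(sqrt(2) * b), independent of the other coordinates
        scheme = SbpScheme(np.array([[1, 1], [1, -1], [-1, 0]]), ("a", "b", "c"))
        b = 0.73
        table = balances_to_composition(
            np.array([[0.4, b]]), contrast_from_sbp(scheme), 1.0
        )
        assert table.values[0, 0] / table.values[0, 1] == pytest.approx(np.exp(np.sqrt(2) * b))

    def test_dimension_mismatch_raises(self):
        scheme = SbpScheme(np.array([[1, 1], [1, -1], [-1, 0]]), ("a", "b", "c"))
        with pytest.raises(ValueError, match="balances"):
            balances_to_composition(np.zeros((2, 3)), contrast_from_sbp(scheme), 1.0)


class TestIO:
    def test_composition_csv_round_trip(self, rng, tmp_path):
        table = random_composition(rng, 5, 4)
        path = tmp_path / "comp.csv"
        write_composition_csv(table, path)
        back = read_composition_csv(path)
        np.testing.assert_allclose(back.values, table.values)
        assert back.part_names == table.part_names
        assert back.sample_ids == table.sample_ids

    def test_tab_delimiter_sniffing(self, rng, tmp_path):
        table = random_composition(rng, 3, 3)
        path = tmp_path / "comp.tsv"
        write_composition_csv(table, path, delimiter="\t")
        back = read_composition_csv(path)
        np.testing.assert_allclose(back.values, table.values)

    def test_sbp_csv_round_trip(self, tmp_path):
        scheme = SbpScheme(np.array([[1, 1], [1, -1], [-1, 0]]), ("a", "b", "c"))
        path = tmp_path / "sbp.csv"
        write_sbp_csv(scheme, path)
        back = read_sbp_csv(path)
        np.testing.assert_array_equal(back.signs, scheme.signs)
        assert back.part_names == scheme.part_names

    def test_composition_requires_three_parts(self):
        with pytest.raises(ValueError, match="3 parts"):
            CompositionTable(np.array([[1.0, 2.0]]), ("a", "b"))
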