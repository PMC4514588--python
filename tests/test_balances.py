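"""Variation matrix, balances, and the exhaustive balance screen."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilcoda import reference
from soilcoda.balances import (
    Balance,
    balance_coefficients,
    balance_screen,
    balance_values,
    balance_variance_from_T,
    clr_cov_from_T,
    enumerate_balances,
    sbp_basis,
    variation_matrix,
    vr_pair,
)


class TestVrPair:
    def test_proportional_series_have_zero_variance(self):
        a = np.array([1.0, 2.0, 5.0, 0.3])
        assert vr_pair(a, 3 * a) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.lognormal(size=40), rng.lognormal(size=40)
        assert vr_pair(a, b) == pytest.approx(vr_pair(b, a), abs=1e-14)

    def test_monte_carlo_recovers_stated_variance(self):
        # ln(a/b) iid N(0, 0.85) at n=50000 must estimate 0.85 closely
        rng = np.random.default_rng(42)
        z = rng.normal(0.0, np.sqrt(0.85), size=50000)
        a = np.exp(z)
        b = np.ones_like(a)
        assert vr_pair(a, b) == pytest.approx(0.85, abs=0.02)

    @pytest.mark.parametrize("a,b", [([1.0], [2.0]), ([1, -1, 2], [1, 1, 1])])
    def test_invalid_inputs(self, a, b):
        with pytest.raises(ValueError):
            vr_pair(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


class TestVariationMatrix:
    def test_proportional_columns_give_zero_matrix(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([base, 2 * base, 0.5 * base])
        np.testing.assert_allclose(variation_matrix(X), 0.0, atol=1e-12)

    def test_matches_pairwise_definition(self, random_table):
        # independent oracle: direct loop over the defining pairwise variances
        T = variation_matrix(random_table)
        d = random_table.shape[1]
        for i, j in itertools.combinations(range(d), 2):
            direct = np.var(np.log(random_table[:, i] / random_table[:, j]), ddof=1)
            assert T[i, j] == pytest.approx(direct, abs=1e-12)
        np.testing.assert_allclose(T, T.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(T), 0.0, atol=1e-14)

    def test_subcompositional_coherence(self, random_table):
        T_full = variation_matrix(random_table)
        sub = variation_matrix(random_table[:, [0, 1, 2]])
        np.testing.assert_allclose(sub, T_full[np.ix_([0, 1, 2], [0, 1, 2])], atol=1e-12)


class TestClrCovFromT:
    def test_zero_matrix_maps_to_zero(self):
        np.testing.assert_allclose(clr_cov_from_T(np.zeros((4, 4))), 0.0, atol=1e-14)

    def test_round_trip_identity(self, ref_T):
        S = clr_cov_from_T(ref_T)
        d = ref_T.shape[0]
        v = np.diag(S)
        T_back = v[:, None] + v[None, :] - 2 * S
        np.fill_diagonal(T_back, 0.0)
        np.testing.assert_allclose(T_back, ref_T, atol=1e-8)

    def test_equals_empirical_clr_covariance(self, random_table):
        from soilcoda import coda

        S_from_T = clr_cov_from_T(variation_matrix(random_table))
        S_emp = np.cov(coda.clr(random_table), rowvar=False, ddof=1)
        np.testing.assert_allclose(S_from_T, S_emp, atol=1e-10)

    def test_rows_sum_to_zero(self, ref_T):
        S = clr_cov_from_T(ref_T)
        np.testing.assert_allclose(S.sum(axis=0), 0.0, atol=1e-10)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            clr_cov_from_T(bad)


class TestBalanceCoefficients:
    def test_one_vs_one_closed_form(self):
        b = balance_coefficients([0], [1], 2)
        np.testing.assert_allclose(b.coefficients, [np.sqrt(0.5), -np.sqrt(0.5)])

    def test_one_vs_two_closed_form(self):
        b = balance_coefficients([0], [1, 2], 5)
        c = np.sqrt(2 / 3)
        np.testing.assert_allclose(b.coefficients, [c, -c / 2, -c / 2, 0, 0])

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_zero_sum_unit_norm(self, data):
        d = data.draw(st.integers(2, 7))
        parts = list(range(d))
        k = data.draw(st.integers(2, d))
        subset = data.draw(st.permutations(parts).map(lambda p: p[:k]))
        split = data.draw(st.integers(1, k - 1))
        b = balance_coefficients(subset[:split], subset[split:], d)
        assert b.coefficients.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(b.coefficients) == pytest.approx(1.0, abs=1e-12)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            balance_coefficients([0, 1], [1, 2], 4)


class TestBalanceValues:
    def test_equal_parts_give_zero(self):
        b = balance_coefficients([0, 2], [1], 3)
        assert balance_values(np.array([[0.2, 0.2, 0.2]]) / 0.6, b)[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_pair_closed_form(self, random_table):
        b = balance_coefficients([1], [3], 5)
        expect = np.log(random_table[:, 1] / random_table[:, 3]) / np.sqrt(2)
        np.testing.assert_allclose(balance_values(random_table, b), expect, atol=1e-12)

    def test_matches_scaled_gmean_ratio_definition(self, random_table):
        # independent oracle: sqrt(rs/(r+s)) * ln(gmean(plus)/gmean(minus))
        from scipy.stats import gmean

        b = balance_coefficients([0, 3], [1, 2, 4], 5)
        r, s = 2, 3
        direct = np.sqrt(r * s / (r + s)) * np.log(
            gmean(random_table[:, [0, 3]], axis=1) / gmean(random_table[:, [1, 2, 4]], axis=1)
        )
        np.testing.assert_allclose(balance_values(random_table, b), direct, atol=1e-12)


class TestBalanceVarianceFromT:
    def test_published_intermediate_rows(self, ref_T):
        # printed ranking: var(w2 | w1·w3) = 0.45 and var(w2·w3 | w1) = 0.50
        b1 = balance_coefficients([1], [0, 2], 5)
        b2 = balance_coefficients([1, 2], [0], 5)
        assert balance_variance_from_T(ref_T, b1) == pytest.approx(0.45, abs=0.005)
        assert balance_variance_from_T(ref_T, b2) == pytest.approx(0.50, abs=0.005)

    def test_zero_T_gives_zero(self):
        b = balance_coefficients([0], [1, 2], 4)
        assert balance_variance_from_T(np.zeros((4, 4)), b) == 0.0

    def test_in_sample_identity(self, random_table):
        # var of the balance coordinate == quadratic form in the empirical T
        T = variation_matrix(random_table)
        for b in enumerate_balances(5, range(2, 6))[::7]:
            z = balance_values(random_table, b)
            assert np.var(z, ddof=1) == pytest.approx(
                balance_variance_from_T(T, b), abs=1e-10
            )

    def test_nonnegative_on_data_derived_T(self, random_table):
        T = variation_matrix(random_table)
        for b in enumerate_balances(5):
            assert balance_variance_from_T(T, b) >= -1e-12


def brute_force_count(d, sizes):
    seen = set()
    for k in sizes:
        for subset in itertools.combinations(range(d), k):
            for mask in range(1, 2**k - 1):
                plus = frozenset(subset[i] for i in range(k) if mask >> i & 1)
                minus = frozenset(subset[i] for i in range(k) if not mask >> i & 1)
                seen.add(frozenset((plus, minus)))
    return len(seen)


class TestEnumerateBalances:
    def test_five_part_count_is_90(self):
        assert len(enumerate_balances(5, range(2, 6))) == 90

    def test_two_part_single_balance(self):
        assert len(enumerate_balances(2, [2])) == 1

    def test_three_part_brute_force(self):
        assert len(enumerate_balances(3, range(2, 4))) == brute_force_count(3, range(2, 4)) == 6

    @pytest.mark.parametrize("d", [2, 3, 4, 5, 6])
    def test_count_formula_and_uniqueness(self, d):
        bals = enumerate_balances(d)
        import math

        formula = sum(math.comb(d, k) * (2 ** (k - 1) - 1) for k in range(2, d + 1))
        assert len(bals) == formula == brute_force_count(d, range(2, d + 1))
        keys = {(b.plus, b.minus) for b in bals}
        assert len(keys) == len(bals)

    def test_canonical_orientation(self):
        for b in enumerate_balances(5):
            assert min(b.plus) < min(b.minus)

    def test_invalid_size_range(self):
        with pytest.raises(ValueError):
            enumerate_balances(4, [1, 2])


class TestBalanceScreen:
    def test_reference_extremes(self, ref_T):
        df = balance_screen(ref_T, labels=reference.LAYERS, from_variation=True)
        assert len(df) == 90
        first, last = df.iloc[0], df.iloc[-1]
        assert {first["plus_parts"], first["minus_parts"]} == {"w1", "w2"}
        assert last["plus_parts"] == "w1;w2;w3" and last["minus_parts"] == "w4;w5"
        assert df["variance"].is_monotonic_increasing

    def test_all_proportional_table(self):
        base = np.linspace(1, 3, 10)
        X = np.column_stack([base, 2 * base, 5 * base])
        df = balance_screen(X)
        np.testing.assert_allclose(df["variance"], 0.0, atol=1e-12)

    def test_two_part_rows_are_half_vr(self, ref_T):
        # var(z) for a pair balance is VR/2 exactly
        df = balance_screen(ref_T, labels=reference.LAYERS, from_variation=True)
        pairs = df[df["size"] == 2]
        for _, row in pairs.iterrows():
            i = reference.LAYERS.index(row["plus_parts"])
            j = reference.LAYERS.index(row["minus_parts"])
            assert row["variance"] == pytest.approx(ref_T[i, j] / 2, abs=1e-12)


class TestSbp:
    def test_two_part_basis(self):
        tree = sbp_basis((0, 1))
        np.testing.assert_allclose(
            tree.contrast_matrix, [[np.sqrt(0.5), -np.sqrt(0.5)]]
        )

    def test_five_part_tree_has_four_orthonormal_balances(self):
        tree = sbp_basis(((0, 1), (2, (3, 4))))
        M = tree.contrast_matrix
        assert M.shape == (4, 5)
        np.testing.assert_allclose(M @ M.T, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(M.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize("bad", [((0, 1), (1, 2)), ((0, 1), 2, 3), (0, (1, (2,)))])
    def test_invalid_partitions_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            sbp_basis(bad)
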