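"""Dispersion statistics: analytic values, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkgini.metrics import (
    DEFAULT_BIN_EDGES,
    bin_by_expression,
    coefficient_of_variation,
    gini,
    gini_matrix,
    gini_sorted,
    tau,
)

value_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False, allow_infinity=False),
    min_size=1,
    max_size=200,
)


class TestGini:
    @pytest.mark.parametrize(
        "vector,expected",
        [
            ([5, 5, 5, 5], 0.0),                 # perfect equality
            ([0, 0, 0, 7], 0.75),                # single holder: (n-1)/n
            ([0, 0, 0, 0.001], 0.75),            # scale plays no role
            ([1, 2, 3, 4], 0.25),                # pairwise sum 20 / (2*16*2.5)
            ([0, 0, 0, 0], 0.0),                 # all-zero convention
            ([3], 0.0),                          # single observation
        ],
    )
    def test_known_values(self, vector, expected):
        assert gini(vector) == pytest.approx(expected, abs=1e-12)
        assert gini_sorted(vector) == pytest.approx(expected, abs=1e-12)

    def test_sorted_form_matches_pairwise_oracle(self):
        """O(n log n) rank identity agrees with the brute-force pairwise
        definition to 1e-12 relative tolerance on 1,000 random vectors."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 201))
            kind = rng.integers(0, 3)
            if kind == 0:
                v = rng.random(n) * rng.choice([1e-3, 1.0, 1e4])
            elif kind == 1:
                v = np.exp(rng.normal(0, 2, n))
            else:
                v = rng.random(n) * (rng.random(n) < 0.3)  # many zeros
            expected = gini(v)
            got = gini_sorted(v)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(value_vectors)
    @settings(max_examples=200, deadline=None)
    def test_sorted_form_property(self, values):
        v = np.asarray(values)
        assert gini_sorted(v) == pytest.approx(gini(v), rel=1e-12, abs=1e-12)

    @given(value_vectors, st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_and_permutation_invariance(self, values, c):
        v = np.asarray(values)
        g = gini_sorted(v)
        assert gini_sorted(c * v) == pytest.approx(g, rel=1e-9, abs=1e-9)
        rng = np.random.default_rng(0)
        assert gini_sorted(rng.permutation(v)) == pytest.approx(g, rel=1e-9, abs=1e-9)

    @given(value_vectors)
    @settings(max_examples=200, deadline=None)
    def test_upper_bound(self, values):
        v = np.asarray(values)
        n = v.size
        assert gini_sorted(v) <= (n - 1) / n + 1e-12

    def test_progressive_transfer_never_increases_gini(self):
        """Moving mass from a richer to a poorer entry (without crossing)
        weakly decreases inequality (Pigou-Dalton principle)."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            v = rng.random(20) * 10
            i, j = np.argmax(v), np.argmin(v)
            gap = v[i] - v[j]
            delta = rng.random() * gap / 2
            w = v.copy()
            w[i] -= delta
            w[j] += delta
            assert gini_sorted(w) <= gini_sorted(v) + 1e-12

    def test_unbiased_form_rescales_by_n_over_n_minus_1(self):
        v = [1, 2, 3, 4]
        assert gini(v, unbiased=True) == pytest.approx(0.25 * 4 / 3)
        assert gini_sorted(v, unbiased=True) == pytest.approx(0.25 * 4 / 3)

    @pytest.mark.parametrize("bad", [[], [-1, 2], [np.nan, 1], [np.inf]])
    def test_invalid_input_raises(self, bad):
        with pytest.raises(ValueError):
            gini(bad)
        with pytest.raises(ValueError):
            gini_sorted(bad)

    def test_matrix_form_matches_rowwise(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 1, (30, 17)))
        x[5] = 0.0
        got = gini_matrix(x)
        for i in range(x.shape[0]):
            assert got[i] == pytest.approx(gini(x[i]), rel=1e-12, abs=1e-12)

    def test_matrix_min_n_yields_nan(self):
        assert np.isnan(gini_matrix(np.ones((3, 1)), min_n=2)).all()


class TestCV:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_population_sd_convention(self):
        # sd([0,10]) = 5 with ddof=0; mean 5 -> CV 1
        assert coefficient_of_variation([0, 10]) == pytest.approx(1.0)

    def test_zero_mean_is_nan_not_error(self):
        assert np.isnan(coefficient_of_variation([0, 0, 0]))


class TestTau:
    @pytest.mark.parametrize(
        "vector,expected",
        [
            ([3, 3, 3, 3], 0.0),
            ([0, 0, 9], 1.0),
            ([2, 4, 8], 0.625),  # ((1-.25)+(1-.5)+0)/2
        ],
    )
    def test_known_values(self, vector, expected):
        assert tau(vector) == pytest.approx(expected, abs=1e-12)

    def test_undefined_cases_are_nan(self):
        assert np.isnan(tau([0, 0, 0]))
        assert np.isnan(tau([4]))

    @given(value_vectors.filter(lambda v: max(v) > 0 and len(v) > 1),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, values, c):
        v = np.asarray(values)
        assert tau(c * v) == pytest.approx(tau(v), rel=1e-9, abs=1e-9)


class TestExpressionBins:
    def test_default_edges_give_twelve_groups(self):
        assert len(DEFAULT_BIN_EDGES) == 11
        groups = {bin_by_expression(e, DEFAULT_BIN_EDGES) for e in DEFAULT_BIN_EDGES}
        groups |= {bin_by_expression(0.0), bin_by_expression(1e9)}
        assert bin_by_expression(1e9) == 11  # top of 12 groups (0..11)

    def test_edge_value_goes_to_higher_bin(self):
        assert bin_by_expression(0.1) == bin_by_expression(0.15)
        assert bin_by_expression(0.1) == bin_by_expression(0.0999) + 1

    def test_highly_expressed_goes_to_top_group(self):
        assert bin_by_expression(150.0) == 11

    def test_non_ascending_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_by_expression(1.0, edges=[1, 1, 2])
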