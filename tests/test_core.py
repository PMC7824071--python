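"""Core statistics: per-subject summaries and closed-form limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from bamr import (
    RatingsMatrix,
    classical_ba,
    expected_sd_ratio,
    extended_loa,
    loa_factor,
    subject_stats,
)

finite_ratings = arrays(
    np.float64,
    st.tuples(st.integers(2, 8), st.integers(2, 6)),
    elements=st.floats(-1e3, 1e3, allow_nan=False, width=32),
)


class TestRatingsMatrix:
    def test_defaults_and_shape(self):
        r = RatingsMatrix(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
        assert r.n == 3 and r.m == 2
        assert r.subject_ids == ("S1", "S2", "S3")
        assert r.rater_ids == ("R1", "R2")

    @pytest.mark.parametrize(
        "values, message",
        [
            (np.zeros((1, 3)), "2 subjects"),
            (np.zeros((5, 1)), "2 raters"),
            (np.array([[1.0, np.nan], [2.0, 3.0]]), "non-finite"),
            (np.zeros(4), "2-D"),
        ],
    )
    def test_invalid_inputs_rejected(self, values, message):
        with pytest.raises(ValueError, match=message):
            RatingsMatrix(values)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            RatingsMatrix(np.zeros((2, 2)), subject_ids=("a", "a"))

    def test_values_are_read_only(self, small_ratings):
        with pytest.raises(ValueError):
            small_ratings.values[0, 0] = 99.0


class TestSubjectStats:
    def test_frozen_examples(self, small_ratings):
        out = subject_stats(small_ratings)
        assert [s.subject_id for s in out] == ["a", "b", "c", "d"]
        # identical ratings -> sd 0, tie attributed to the first rater
        assert out[0].mean == 5.0 and out[0].sd == 0.0
        assert out[0].max_dev_rater == "R1"
        assert out[1].mean == pytest.approx(1.0)
        assert out[1].sd == pytest.approx(1.0)

    def test_definitional_sd(self):
        # direct formula sqrt(sum((x - xbar)^2) / (m - 1)) on (0, 1, 2, 3)
        r = RatingsMatrix(np.array([[0.0, 1.0, 2.0, 3.0], [0.0, 0.0, 0.0, 0.0]]))
        s = subject_stats(r)[0]
        assert s.mean == pytest.approx(1.5)
        assert s.sd == pytest.approx(1.29099, abs=1e-5)

    def test_two_rater_identity(self):
        # for m = 2 the subject SD is |difference| / sqrt(2)
        r = RatingsMatrix(np.array([[1.0, 3.0], [5.0, 5.0]]))
        out = subject_stats(r)
        assert out[0].mean == pytest.approx(2.0)
        assert out[0].sd == pytest.approx(abs(1 - 3) / np.sqrt(2))

    def test_max_dev_attribution(self, small_ratings):
        # subject d = (3, 4, 8): mean 5, rater 3 deviates most
        assert subject_stats(small_ratings)[3].max_dev_rater == "R3"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(values=finite_ratings)
    def test_rater_permutation_invariance(self, values):
        base = subject_stats(RatingsMatrix(values))
        perm = np.random.default_rng(0).permutation(values.shape[1])
        shuffled = subject_stats(RatingsMatrix(values[:, perm]))
        for a, b in zip(base, shuffled):
            assert a.mean == pytest.approx(b.mean, rel=1e-12, abs=1e-12)
            assert a.sd == pytest.approx(b.sd, rel=1e-12, abs=1e-12)


class TestLoaFactor:
    def test_reference_values(self):
        # frozen 6-decimal multipliers for m = 2..5
        assert round(loa_factor(2), 6) == 1.959964
        assert round(loa_factor(3), 6) == 1.730818
        assert round(loa_factor(4), 6) == 1.613973
        assert round(loa_factor(5), 6) == 1.540108

    def test_m2_is_half_normal_quantile(self):
        # chi with 1 df is a half-normal, so the factor is the 0.975 z-quantile
        assert loa_factor(2) == pytest.approx(stats.norm.ppf(0.975), abs=1e-12)

    def test_strictly_decreasing_in_m(self):
        factors = [loa_factor(m) for m in range(2, 30)]
        assert all(a > b for a, b in zip(factors, factors[1:]))
        assert all(f > 0 for f in factors)

    @pytest.mark.parametrize("bad", [1, 0, -3, 2.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            loa_factor(bad)


class TestExpectedSdRatio:
    def test_against_chi_mean_oracle(self):
        # E[s]*sqrt(m-1)/sigma equals the chi_{m-1} mean sqrt(2)*G(m/2)/G((m-1)/2)
        from math import gamma, sqrt

        for m in range(2, 10):
            oracle = sqrt(2) * gamma(m / 2) / gamma((m - 1) / 2) / sqrt(m - 1)
            assert expected_sd_ratio(m) == pytest.approx(oracle, rel=1e-12)

    def test_monte_carlo(self, rng):
        s = rng.standard_normal((200_000, 3)).std(axis=1, ddof=1)
        assert s.mean() == pytest.approx(expected_sd_ratio(3), abs=0.005)


class TestExtendedLoa:
    def test_perfect_agreement_gives_zero_with_warning(self):
        r = RatingsMatrix(np.tile(np.arange(5.0)[:, None], (1, 3)))
        with pytest.warns(UserWarning, match="agree exactly"):
            out = extended_loa(r)
        assert out.estimate == 0.0
        assert out.method == "extended_chi"
        assert not out.has_ci

    def test_hand_computed_estimate(self):
        # three subjects engineered to have SDs exactly (1, 2, 3) * k
        base = np.array([-1.0, 0.0, 1.0])  # sd = 1
        values = np.vstack([10 + base, 20 + 2 * base, 30 + 3 * base])
        out = extended_loa(RatingsMatrix(values))
        assert out.mean_sd == pytest.approx(2.0)
        expected = loa_factor(3) * 2.0 / expected_sd_ratio(3)
        assert out.estimate == pytest.approx(expected, rel=1e-12)

    def test_large_n_convergence_to_sigma_times_factor(self, rng):
        # the plugged-in scale is consistent for sigma, so for N(0, 1) errors
        # the limit converges to the bare chi multiplier
        values = rng.standard_normal((100_000, 2))
        out = extended_loa(RatingsMatrix(values))
        assert out.estimate == pytest.approx(loa_factor(2), rel=0.01)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(values=finite_ratings, shift=st.floats(-1e3, 1e3), scale=st.floats(0.01, 100))
    @pytest.mark.filterwarnings("ignore:all raters agree")
    def test_location_invariance_and_scale_equivariance(self, values, shift, scale):
        base = extended_loa(RatingsMatrix(values)).estimate
        # adding any per-subject constants leaves the limit unchanged
        shifts = shift * np.arange(values.shape[0])[:, None]
        shifted = extended_loa(RatingsMatrix(values + shifts)).estimate
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        # multiplying all ratings by c > 0 multiplies the limit by c
        scaled = extended_loa(RatingsMatrix(values * scale)).estimate
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-9)


class TestClassicalBa:
    def test_constant_differences_degenerate(self):
        values = np.column_stack([np.arange(5.0), np.arange(5.0) - 2.0])
        out = classical_ba(RatingsMatrix(values))
        assert out.bias == pytest.approx(2.0)
        assert out.sd_diff == 0.0
        assert out.loa_lower == out.loa_upper == pytest.approx(2.0)

    def test_exact_t_factor(self, rng):
        # n=10, sd_d=1, mean 0 -> upper limit t_{0.975,9} * sqrt(1.1)
        # = 2.2621572 * 1.0488088 = 2.3725704 (scipy t quantile, hand product)
        d = rng.standard_normal(10)
        d = (d - d.mean()) / d.std(ddof=1)
        values = np.column_stack([d, np.zeros(10)])
        out = classical_ba(RatingsMatrix(values))
        assert out.bias == pytest.approx(0.0, abs=1e-12)
        assert out.loa_upper == pytest.approx(2.3725704, abs=1e-6)
        assert out.loa_lower == pytest.approx(-2.3725704, abs=1e-6)

    def test_column_swap_antisymmetry(self, two_rater_ratings):
        fwd = classical_ba(two_rater_ratings)
        rev = classical_ba(RatingsMatrix(two_rater_ratings.values[:, ::-1]))
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.loa_upper == pytest.approx(-fwd.loa_lower)
        assert rev.loa_lower == pytest.approx(-fwd.loa_upper)

    def test_symmetry_about_bias(self, two_rater_ratings):
        out = classical_ba(two_rater_ratings)
        assert out.loa_upper - out.bias == pytest.approx(out.bias - out.loa_lower)
        assert out.bias == pytest.approx(out.differences.mean())

    def test_requires_two_raters(self, small_ratings):
        with pytest.raises(ValueError, match="exactly 2 raters"):
            classical_ba(small_ratings)


def test_m2_bridge_between_extended_and_classical(two_rater_ratings):
    """For m = 2 the subject SDs are exactly |d_i|/sqrt(2)."""
    d = two_rater_ratings.values[:, 0] - two_rater_ratings.values[:, 1]
    sds = np.array([s.sd for s in subject_stats(two_rater_ratings)])
    np.testing.assert_allclose(sds, np.abs(d) / np.sqrt(2), rtol=1e-12)
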