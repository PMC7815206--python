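"""Grid layouts, the Q_P statistic, p-values, periodograms, discontinuities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cspgram import (
    CSPVariant,
    TimeCourse,
    compute_csp,
    find_k_discontinuities,
    make_layout,
    qp_pvalue_neglog10,
    qp_statistic,
)
from cspgram.csp import largest_discontinuity


def qp_loop_oracle(values, P, variant, P_max=None):
    """Pure-Python grid evaluation of Q_P, independent of the implementation."""
    N = len(values)
    if variant == "greedy":
        K = N / P
        cols = [[values[r * P + h] for r in range(-(-(N - h) // P))] for h in range(P)]
        included = list(values)
    else:
        K = N // P if variant == "standard" else N // P_max
        cols = [[values[r * P + h] for r in range(K)] for h in range(P)]
        included = list(values[: K * P])
    m = sum(included) / len(included)
    col_means = [sum(c) / len(c) for c in cols]
    num = K * len(included) * sum((cm - m) ** 2 for cm in col_means)
    den = sum((x - m) ** 2 for x in included)
    return num / den


class TestMakeLayout:
    def test_standard_floor(self):
        lay = make_layout(680, 226, "standard")
        assert (lay.K, lay.D, lay.included_count) == (3.0, 2, 678)
        assert np.all(lay.column_counts == 3)

    def test_greedy_row_major_fill(self):
        lay = make_layout(7, 2, "greedy")
        assert lay.K == pytest.approx(3.5)
        assert lay.D == 0
        np.testing.assert_array_equal(lay.column_counts, [4, 3])
        assert lay.included_count == 7

    def test_conservative_uses_pmax(self):
        lay = make_layout(300, 200, "conservative", P_max=300)
        assert (lay.K, lay.D, lay.included_count) == (1.0, 100, 200)

    @pytest.mark.parametrize("variant", list(CSPVariant))
    def test_full_period_is_one_row(self, variant):
        lay = make_layout(8, 8, variant, P_max=8)
        assert (lay.K, lay.D) == (1.0, 0)

    def test_conservative_k_zero_rejected(self):
        with pytest.raises(ValueError, match="shorter than test period"):
            make_layout(250, 200, "conservative", P_max=300)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(N=st.integers(4, 500), P=st.integers(1, 500))
    def test_layout_invariants(self, N, P):
        if P > N:
            P = P % N + 1
        for variant in ("standard", "greedy"):
            lay = make_layout(N, P, variant, P_max=P)
            assert lay.included_count == int(lay.column_counts.sum())
            assert lay.included_count + lay.D == N
            if variant == "standard":
                assert lay.K == N // P
                assert np.all(lay.column_counts == lay.K)
            else:
                assert lay.K == pytest.approx(N / P)
                assert lay.D == 0
                # row-major: exactly the first N mod P columns get the extra point
                base, extra = divmod(N, P)
                np.testing.assert_array_equal(
                    lay.column_counts, [base + 1] * extra + [base] * (P - extra)
                )


class TestQpStatistic:
    def test_hand_example_alternating(self):
        tc = TimeCourse([1, 3, 1, 3, 1, 3, 1, 3], 0.1)
        qp, df = qp_statistic(tc, make_layout(8, 2, "standard"))
        assert qp == pytest.approx(8.0)
        assert df == 1

    def test_full_period_identity(self, rng):
        # P = N: column means are the data, so Q_P = N for any non-constant series
        x = rng.normal(size=50)
        tc = TimeCourse(x, 0.1)
        qp, df = qp_statistic(tc, make_layout(50, 50, "standard"))
        assert qp == pytest.approx(50.0)
        assert df == 49

    def test_greedy_unequal_columns_vs_oracle(self):
        values = [1.0, 3.0, 1.0, 3.0, 1.0, 3.0, 1.0]
        tc = TimeCourse(values, 0.1)
        lay = make_layout(7, 2, "greedy")
        qp, df = qp_statistic(tc, lay)
        assert qp == pytest.approx(qp_loop_oracle(values, 2, "greedy"), rel=1e-12)
        assert df == 1

    def test_constant_series_rejected(self):
        tc = TimeCourse([2.0] * 10, 0.1)
        with pytest.raises(ValueError, match="degenerate"):
            qp_statistic(tc, make_layout(10, 2, "standard"))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        N=st.integers(10, 200),
        P=st.integers(2, 60),
        seed=st.integers(0, 2**16),
        variant=st.sampled_from(["standard", "conservative", "greedy"]),
    )
    def test_vectorized_matches_loop_oracle(self, N, P, seed, variant):
        """The vectorized grid evaluation equals a naive double loop."""
        P = min(P, N // 2)
        if P < 2:
            P = 2
        values = np.random.default_rng(seed).normal(size=N)
        P_max = min(N, P + 10)
        tc = TimeCourse(values, 0.1)
        lay = make_layout(N, P, variant, P_max=P_max)
        qp, _ = qp_statistic(tc, lay)
        assert qp == pytest.approx(
            qp_loop_oracle(list(values), P, variant, P_max=P_max), rel=1e-12
        )


class TestPValue:
    def test_zero_statistic_means_p_one(self):
        assert qp_pvalue_neglog10(0.0, 5) == pytest.approx(0.0)

    def test_chi2_critical_value(self):
        # 3.841 is the 5% critical value of chi-square with 1 df
        assert qp_pvalue_neglog10(3.841, 1) == pytest.approx(-np.log10(0.05), abs=1e-3)

    def test_no_underflow_for_huge_statistic(self):
        v = qp_pvalue_neglog10(5000.0, 10)
        assert np.isfinite(v) and v > 300


class TestComputeCsp:
    def test_noiseless_peak_at_true_period(self, noiseless_sine_72h):
        pg = compute_csp(noiseless_sine_72h, "standard")
        assert pg.test_period_h[np.argmax(pg.neg_log10_p)] == pytest.approx(24.0)

    def test_period_grid_covers_18_to_30(self, noiseless_sine_72h):
        pg = compute_csp(noiseless_sine_72h, "standard")
        assert pg.test_period_h[0] == pytest.approx(18.0)
        assert pg.test_period_h[-1] == pytest.approx(30.0)
        assert len(pg.test_period_h) == 121

    def test_conservative_k_constant_and_depends_on_pmax(self, noiseless_sine_72h):
        pg = compute_csp(noiseless_sine_72h, "conservative", 18.0, 30.0)
        assert np.unique(pg.K).size == 1
        assert pg.K[0] == 720 // 300
        pg2 = compute_csp(noiseless_sine_72h, "conservative", 18.0, 24.0)
        assert pg2.K[0] == 720 // 240
        assert pg2.K[0] != pg.K[0]

    def test_greedy_uses_all_points(self, noiseless_sine_72h):
        pg = compute_csp(noiseless_sine_72h, "greedy")
        assert np.all(pg.D == 0)

    def test_too_short_for_pmax_rejected(self):
        tc = TimeCourse(np.sin(np.arange(240) * 0.1), 0.1)  # 24 h
        with pytest.raises(ValueError, match="needs"):
            compute_csp(tc, "standard", 18.0, 30.0)

    def test_single_noisy_replicate_largest_jump(self):
        """68-h amplitude-2 simulation: the biggest periodogram jump is at 22.6 h."""
        from cspgram import SimulationSpec, simulate_timecourse

        spec = SimulationSpec(period_h=24, amplitude=2, length_h=68, seed=3)
        pg = compute_csp(simulate_timecourse(spec), "standard")
        loc, _ = largest_discontinuity(pg)
        assert loc == pytest.approx(22.6)

    def test_continuity_greedy_smoother_than_standard(self, noiseless_sine_72h):
        """Across each K change point the greedy statistic jumps strictly less."""
        pg_s = compute_csp(noiseless_sine_72h, "standard")
        pg_g = compute_csp(noiseless_sine_72h, "greedy")
        for P_before, _, _ in find_k_discontinuities(720, 180, 300):
            i = np.searchsorted(pg_s.test_period_h, P_before * 0.1)
            jump_s = abs(pg_s.statistic[i + 1] - pg_s.statistic[i])
            jump_g = abs(pg_g.statistic[i + 1] - pg_g.statistic[i])
            assert jump_g < jump_s

    def test_serialization_schema(self, noiseless_sine_72h, tmp_path):
        pg = compute_csp(noiseless_sine_72h, "greedy")
        out = tmp_path / "pg.csv"
        pg.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "test_period_h,statistic,df,neg_log10_p,K,D,method"


class TestNullDistribution:
    def test_null_mean_qp_matches_theory(self, rng):
        """Over pure-noise series E[Q_P] = N_inc (P-1) / (N_inc - 1), about P-1."""
        N, P = 680, 226
        lay = make_layout(N, P, "standard")
        qs = np.array(
            [qp_statistic(TimeCourse(rng.normal(size=N), 0.1), lay)[0] for _ in range(1000)]
        )
        n_inc = lay.included_count
        expect = n_inc * (P - 1) / (n_inc - 1)
        se = qs.std(ddof=1) / np.sqrt(qs.size)
        assert abs(qs.mean() - expect) < 3 * se

    def test_null_pvalues_uniform(self, rng):
        """With K = 50 rows the upper-tail p-values are Uniform(0,1) by KS test."""
        N, P = 2000, 40
        lay = make_layout(N, P, "standard")
        pvals = [
            stats.chi2.sf(*qp_statistic(TimeCourse(rng.normal(size=N), 0.1), lay))
            for _ in range(1000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestKDiscontinuities:
    @pytest.mark.parametrize(
        "N,expected",
        [
            (680, [(226, 3, 2)]),
            (760, [(190, 4, 3), (253, 3, 2)]),
        ],
    )
    def test_known_change_points(self, N, expected):
        assert find_k_discontinuities(N, 180, 300) == expected

    def test_matches_exhaustive_floor_scan(self):
        N = 720
        found = find_k_discontinuities(N, 180, 300)
        brute = [
            (P, N // P, N // (P + 1))
            for P in range(180, 300)
            if N // (P + 1) < N // P
        ]
        assert found == brute

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            find_k_discontinuities(100, 50, 200)
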