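"""Nonparametric group statistics: Wilcoxon, Cliff's delta, BH-FDR."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_minimal_summary
from triadyn.stats import (
    bh_fdr,
    cliffs_delta,
    compare_real_vs_surrogate,
    compare_states,
    permutation_gap_test,
    wilcoxon_signed_rank,
)
from triadyn.triads import STATE_ORDER


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        # exhaustive enumeration oracle: 2 of 2^10 sign patterns reach
        # rank sum 0 on either side -> two-sided p = 2/1024
        y = np.arange(10.0)
        stat, p = wilcoxon_signed_rank(y + 1.0, y)
        assert stat == 0.0
        assert p == pytest.approx(2 / 1024)

    def test_textbook_negative_rank_sum(self):
        # diffs [+1,-2,+3,+4,-5,+6]: |d| are their own ranks,
        # W- = 2 + 5 = 7 is the smaller rank sum
        x = np.array([1.0, -2.0, 3.0, 4.0, -5.0, 6.0])
        stat, _ = wilcoxon_signed_rank(x, np.zeros(6))
        assert stat == 7.0

    def test_degenerate_pairing_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(x, x)

    def test_too_few_nonzero_pairs_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 0.0])
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_signed_rank(x, y)

    def test_tied_ranks_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 4, size=30).astype(float)
        mask = x != y
        stat, p = wilcoxon_signed_rank(x[mask][:20], y[mask][:20])
        assert 0.0 < p <= 1.0


class TestCliffsDelta:
    def test_complete_dominance(self):
        assert cliffs_delta([5, 6, 7], [1, 2]) == 1.0

    def test_identical_multisets(self):
        assert cliffs_delta([1, 2, 2, 3], [1, 2, 2, 3]) == 0.0

    def test_brute_force_example(self):
        # pairs: (1,1)=tie, (1,3)<, (2,1)>, (2,3)< -> (1-2)/4
        assert cliffs_delta([1, 2], [1, 3]) == pytest.approx(-0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=20),
        st.lists(st.floats(-10, 10), min_size=1, max_size=20),
    )
    def test_antisymmetry_and_bounds(self, x, y):
        d = cliffs_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-cliffs_delta(y, x))


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.005, 0.9], [0.01, 0.9]),
            ([0.9, 0.005], [0.9, 0.01]),  # input order preserved
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    def test_monotonicity_properties(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


def _cohort(rng, n=10, planted_balance_advantage=0.0):
    summaries = []
    for _ in range(n):
        lifetimes = {}
        for s in STATE_ORDER:
            base = rng.lognormal(mean=2.0, sigma=0.3)
            if s.is_balanced:
                base += planted_balance_advantage
            lifetimes[s.symbol] = base
        summaries.append(make_minimal_summary(lifetimes))
    return summaries


class TestCompareStates:
    def test_planted_balance_advantage_recovered(self):
        rng = np.random.default_rng(42)
        result = compare_states(_cohort(rng, planted_balance_advantage=15.0))
        for a, b in itertools.product(["+++", "-+-"], ["+-+", "---"]):
            try:
                comp = result.get(f"{a} vs {b}", metric="lifetime")
                delta = comp.cliffs_delta
            except KeyError:  # stored in canonical state order
                comp = result.get(f"{b} vs {a}", metric="lifetime")
                delta = -comp.cliffs_delta
            assert comp.q_value < 0.05
            assert delta > 0
        assert len(result.comparisons) == 12  # 6 pairs x 2 metrics

    def test_identical_subjects_surface_degenerate_error(self):
        # every subject carries the same value for every state, so all
        # paired differences vanish: the failure must be loud, not silent
        summ = make_minimal_summary({s.symbol: 2.0 for s in STATE_ORDER})
        with pytest.raises(ValueError, match="degenerate"):
            compare_states([summ] * 8)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(7)
        cohort = _cohort(rng, planted_balance_advantage=5.0)
        a = compare_states(cohort).to_dataframe()
        b = compare_states(list(reversed(cohort))).to_dataframe()
        assert a.equals(b)

    def test_subjects_missing_states_are_dropped(self):
        rng = np.random.default_rng(3)
        cohort = _cohort(rng, n=6)
        incomplete = make_minimal_summary({"+++": 1.0})  # other states absent
        result = compare_states(cohort + [incomplete])
        assert all(c.n_subjects == 6 for c in result.comparisons)
        with pytest.raises(ValueError, match=">= 5 subjects"):
            compare_states([incomplete] * 6)

    def test_type_one_error_calibration_under_null(self):
        """Without planted differences, the FDR family rejects rarely."""
        rng = np.random.default_rng(2024)
        rejections = total = 0
        for _ in range(50):
            result = compare_states(_cohort(rng), metrics=("lifetime",))
            for c in result.comparisons:
                total += 1
                rejections += c.q_value < 0.05
        assert rejections / total <= 0.07


class TestCompareRealVsSurrogate:
    def test_self_comparison_is_degenerate(self):
        rng = np.random.default_rng(5)
        cohort = _cohort(rng)
        with pytest.raises(ValueError, match="degenerate"):
            compare_real_vs_surrogate(cohort, cohort)

    def test_swapping_arguments_flips_deltas(self):
        rng = np.random.default_rng(6)
        real = _cohort(rng, planted_balance_advantage=10.0)
        null = _cohort(rng)
        fwd = compare_real_vs_surrogate(real, null)
        rev = compare_real_vs_surrogate(null, real)
        for cf, cr in zip(fwd.comparisons, rev.comparisons):
            assert cf.cliffs_delta == pytest.approx(-cr.cliffs_delta)

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="mismatch"):
            compare_real_vs_surrogate(_cohort(rng, n=6), _cohort(rng, n=5))

    def test_gap_test_structure(self):
        rng = np.random.default_rng(9)
        real = _cohort(rng, planted_balance_advantage=20.0)
        null = _cohort(rng)
        result = compare_real_vs_surrogate(real, null)
        gap = result.get("balance gap real vs surrogate")
        assert gap.cliffs_delta > 0
        assert gap.p_value < 0.05
        assert len(result.comparisons) == 5


class TestPermutationGapTest:
    def test_detects_separation(self):
        real = np.full(10, 12.0) + np.arange(10) * 0.1
        null = np.full(10, 2.0)
        assert permutation_gap_test(real, null, seed=1) < 0.01

    def test_null_gaps_not_significant(self):
        rng = np.random.default_rng(10)
        d = rng.standard_normal(10)
        p = permutation_gap_test(d, np.zeros(10), n_permutations=2000, seed=2)
        assert 0.0 < p <= 1.0
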