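"""Triad classification, energy, and episode extraction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import triadyn as td
from triadyn.triads import (
    STATE_ORDER,
    TriadState,
    classify_triad,
    enumerate_triangles,
    extract_episodes,
    subject_summary,
    triad_energy,
)
from triadyn.windows import DynamicNetwork, WindowParams

weights_st = st.floats(min_value=-1.0, max_value=1.0, allow_nan=False)


def naive_episode_oracle(states):
    """Brute-force run-length scan: list of (state, start, length)."""
    runs = []
    start = 0
    for t in range(1, len(states) + 1):
        if t == len(states) or states[t] != states[start]:
            runs.append((states[start], start, t - start))
            start = t
    return runs


class TestEnumeration:
    def test_single_triangle(self):
        assert enumerate_triangles(3) == [(0, 1, 2)]

    def test_matches_brute_force_count_and_order(self):
        tris = enumerate_triangles(5)
        assert tris == sorted(set(tris))
        assert len(tris) == math.comb(5, 3) == 10
        assert tris[0] == (0, 1, 2) and tris[-1] == (2, 3, 4)

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            enumerate_triangles(2)


class TestClassification:
    @pytest.mark.parametrize(
        "w, expected, balanced",
        [
            ((0.5, 0.5, 0.5), TriadState.PPP, True),
            ((-1, -1, -1), TriadState.NNN, False),
            ((-0.3, 0.2, -0.4), TriadState.NPN, True),
            ((0.9, -0.1, 0.2), TriadState.PNP, False),
            ((0.0, 0.5, 0.5), TriadState.PPP, True),  # exact zero counts positive
        ],
    )
    def test_examples(self, w, expected, balanced):
        state = classify_triad(*w)
        assert state is expected
        assert state.is_balanced == balanced

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_triad(np.nan, 0.1, 0.2)

    @given(weights_st, weights_st, weights_st)
    def test_permutation_invariance(self, a, b, c):
        states = {classify_triad(*p) for p in itertools.permutations((a, b, c))}
        energies = {triad_energy(*p) for p in itertools.permutations((a, b, c))}
        assert len(states) == 1
        assert max(energies) - min(energies) < 1e-15

    def test_exactly_four_states(self):
        assert len(list(TriadState)) == 4
        assert {s for s in TriadState if s.is_balanced} == {
            TriadState.PPP,
            TriadState.NPN,
        }


class TestEnergy:
    @pytest.mark.parametrize(
        "w, expected",
        [((1, 1, 1), -1.0), ((-1, -1, -1), 1.0), ((0.5, 0.5, 0.5), -0.5)],
    )
    def test_exact_values(self, w, expected):
        assert triad_energy(*w) == pytest.approx(expected, abs=1e-15)

    def test_signed_cube_root_oracle(self):
        # independent oracle: -sign(p) * exp(ln|p| / 3)
        p = 0.2 * -0.3 * 0.5
        expected = -np.sign(p) * np.exp(np.log(abs(p)) / 3.0)
        assert triad_energy(0.2, -0.3, 0.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.31072, abs=1e-5)

    def test_rejects_out_of_range_weights(self):
        with pytest.raises(ValueError):
            triad_energy(1.5, 0.2, 0.1)
        with pytest.raises(ValueError):
            triad_energy(0.1, np.inf, 0.1)

    @given(weights_st, weights_st, weights_st)
    def test_bounds_and_sign_class_consistency(self, a, b, c):
        e = triad_energy(a, b, c)
        assert -1.0 <= e <= 1.0
        balanced = classify_triad(a, b, c).is_balanced
        if balanced:
            assert e <= 0.0
        else:
            assert e >= 0.0
        if e == 0.0:
            # zero energy iff the edge product is zero (exact zero edge,
            # or underflow of a subnormal product)
            assert a * b * c == 0.0


class TestEpisodes:
    def test_hand_trace_runs(self):
        A, B = TriadState.PPP, TriadState.NNN
        eps = extract_episodes([A, A, B, A], [-0.1, -0.2, 0.3, -0.4])
        assert [(e.state, e.lifetime) for e in eps] == [(A, 2), (B, 1), (A, 1)]
        assert sum(e.lifetime for e in eps) == 4
        assert eps[0].left_censored and not eps[0].right_censored
        assert eps[-1].right_censored and not eps[-1].left_censored
        assert not (eps[1].left_censored or eps[1].right_censored)
        assert [e.start_window for e in eps] == [0, 2, 3]

    def test_peak_energy_is_max_absolute(self):
        A = TriadState.NPN
        eps = extract_episodes([A, A, A], [-0.1, -0.7, -0.3])
        assert len(eps) == 1
        assert eps[0].lifetime == 3
        assert eps[0].abs_peak_energy == pytest.approx(0.7)
        assert eps[0].left_censored and eps[0].right_censored

    def test_single_window(self):
        eps = extract_episodes([TriadState.PNP], [0.2])
        assert len(eps) == 1 and eps[0].lifetime == 1

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            extract_episodes([], [])
        with pytest.raises(ValueError):
            extract_episodes([TriadState.PPP], [0.1, 0.2])

    @given(
        st.lists(st.sampled_from(STATE_ORDER), min_size=1, max_size=200),
        st.randoms(use_true_random=False),
    )
    def test_matches_naive_run_length_oracle(self, states, rnd):
        energies = [
            (-1 if s.is_balanced else 1) * rnd.random() for s in states
        ]
        eps = extract_episodes(states, energies)
        oracle = naive_episode_oracle(states)
        assert [(e.state, e.start_window, e.lifetime) for e in eps] == oracle
        assert sum(e.lifetime for e in eps) == len(states)
        for e in eps:
            window = energies[e.start_window : e.start_window + e.lifetime]
            assert e.abs_peak_energy == pytest.approx(max(abs(x) for x in window))


def _dyn_from_edge_signs(edge_values):
    """DynamicNetwork over 3 regions from per-window (w01, w02, w12)."""
    T = len(edge_values)
    weights = np.zeros((T, 3, 3))
    for t, (a, b, c) in enumerate(edge_values):
        weights[t, 0, 1] = weights[t, 1, 0] = a
        weights[t, 0, 2] = weights[t, 2, 0] = b
        weights[t, 1, 2] = weights[t, 2, 1] = c
    return DynamicNetwork(
        weights=weights,
        window_starts=np.arange(T),
        params=WindowParams(3, 1),
        tr_seconds=0.72,
    )


class TestSubjectSummary:
    def test_hand_trace_single_triangle(self):
        dyn = _dyn_from_edge_signs([(0.5, 0.5, 0.5), (0.6, 0.6, 0.6), (-0.5, -0.5, -0.5)])
        summ = subject_summary(dyn)
        assert summ.mean_lifetime[TriadState.PPP] == pytest.approx(2.0)
        assert summ.mean_lifetime[TriadState.NNN] == pytest.approx(1.0)
        assert summ.mean_lifetime[TriadState.PNP] is None
        assert summ.occurrence[TriadState.PPP] == 2
        assert summ.occurrence[TriadState.NNN] == 1
        i, j = TriadState.PPP.index, TriadState.NNN.index
        assert summ.transition_counts[i, j] == 1
        assert summ.transition_counts.sum() == 1
        assert summ.mean_abs_peak_energy[TriadState.PPP] == pytest.approx(0.6)

    def test_constant_network_one_episode_per_triangle(self):
        rng = np.random.default_rng(0)
        w = np.abs(rng.uniform(0.2, 0.9, size=(4, 4)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        weights = np.repeat(w[None], 7, axis=0)
        dyn = DynamicNetwork(weights, np.arange(7), WindowParams(3, 1), 0.72)
        summ = subject_summary(dyn)
        assert summ.transition_counts.sum() == 0
        assert summ.mean_lifetime[TriadState.PPP] == pytest.approx(7.0)
        assert summ.episode_counts[TriadState.PPP] == 4  # C(4,3) triangles

    def test_occurrence_partitions_triangle_window_pairs(self):
        rng = np.random.default_rng(3)
        weights = rng.uniform(-1, 1, size=(9, 5, 5))
        weights = (weights + np.transpose(weights, (0, 2, 1))) / 2
        weights[:, np.arange(5), np.arange(5)] = 0.0
        dyn = DynamicNetwork(weights, np.arange(9), WindowParams(3, 1), 0.72)
        summ = subject_summary(dyn)
        total = sum(summ.occurrence[s] for s in STATE_ORDER)
        assert total == summ.n_triangles * summ.n_windows == 10 * 9

    def test_censoring_flag_excludes_boundary_episodes_from_means(self):
        dyn = _dyn_from_edge_signs(
            [(0.5, 0.5, 0.5), (0.5, 0.5, 0.5), (-0.5, 0.5, 0.5), (0.5, 0.5, 0.5)]
        )
        summ = subject_summary(dyn, include_censored=False)
        # only the interior +-+ episode survives the censoring filter
        assert summ.mean_lifetime[TriadState.PNP] == pytest.approx(1.0)
        assert summ.mean_lifetime[TriadState.PPP] is None
        # occurrence still uses the complete partition
        assert sum(summ.occurrence[s] for s in STATE_ORDER) == 4
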