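"""Generator matrix, transition probabilities, observation model and the
pruning recursion, checked against closed forms and an exhaustive
path-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from fossildes.likelihood import (AnageneticRates, DESParameters,
                                  PreservationRates, TimeFrame,
                                  build_q_matrix, dataset_log_likelihood,
                                  emission_probabilities,
                                  false_absence_probability,
                                  lineage_log_likelihood,
                                  observed_state_weights,
                                  transition_probabilities)
from fossildes.ranges import (CODE_A, CODE_AB, CODE_B, CODE_EMPTY,
                              ObservedRangeMatrix, build_time_grid)

from conftest import enumerate_lineage_loglik

rates_st = st.floats(min_value=0.0, max_value=2.0)
prob_st = st.floats(min_value=0.0, max_value=1.0)


class TestQMatrix:
    def test_structure(self):
        q = build_q_matrix(AnageneticRates(d_ab=0.1, d_ba=0.2,
                                           e_a=0.05, e_b=0.07))
        assert np.allclose(q[0], 0.0)  # empty range is absorbing
        assert np.allclose(q[1], [0.05, -0.15, 0.0, 0.1])
        assert np.allclose(q[3], [0.0, 0.07, 0.05, -0.12])
        assert q[1, 2] == 0.0 and q[2, 1] == 0.0  # no direct A<->B jump
        assert q[3, 0] == 0.0  # no simultaneous loss of both areas

    def test_zero_rates_give_zero_matrix(self):
        q = build_q_matrix(AnageneticRates(0, 0, 0, 0))
        assert np.allclose(q, 0.0)

    @given(rates_st, rates_st, rates_st, rates_st)
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_zero(self, d_ab, d_ba, e_a, e_b):
        q = build_q_matrix(AnageneticRates(d_ab, d_ba, e_a, e_b))
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            AnageneticRates(-0.1, 0, 0, 0)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        q = build_q_matrix(AnageneticRates(0.3, 0.2, 0.1, 0.4))
        assert np.allclose(transition_probabilities(q, 0.0), np.eye(4))

    def test_single_rate_closed_form(self):
        # only A -> AB possible at rate 0.2; over dt=5 the event happens
        # with probability 1 - exp(-1)
        q = build_q_matrix(AnageneticRates(d_ab=0.2, d_ba=0, e_a=0, e_b=0))
        p = transition_probabilities(q, 5.0)
        assert p[1, 3] == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert p[1, 1] == pytest.approx(np.exp(-1), abs=1e-12)

    # moderate rates/times keep the truncated series itself accurate
    @given(*([st.floats(min_value=0.0, max_value=0.5)] * 4),
           st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=40, deadline=None)
    def test_matches_taylor_series_oracle(self, d_ab, d_ba, e_a, e_b, dt):
        q = build_q_matrix(AnageneticRates(d_ab, d_ba, e_a, e_b))
        p = transition_probabilities(q, dt)
        series = np.eye(4)
        term = np.eye(4)
        for n in range(1, 41):
            term = term @ (q * dt) / n
            series = series + term
        assert np.allclose(p, series, atol=1e-10)

    @given(rates_st, rates_st, rates_st, rates_st,
           st.floats(min_value=0.0, max_value=5.0),
           st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=40, deadline=None)
    def test_stochastic_absorbing_chapman_kolmogorov(self, d_ab, d_ba,
                                                     e_a, e_b, t1, t2):
        q = build_q_matrix(AnageneticRates(d_ab, d_ba, e_a, e_b))
        p1 = transition_probabilities(q, t1)
        p2 = transition_probabilities(q, t2)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p1 >= -1e-12) and np.all(p1 <= 1 + 1e-12)
        assert np.allclose(p1[0], [1, 0, 0, 0], atol=1e-12)
        assert np.allclose(p1 @ p2, transition_probabilities(q, t1 + t2),
                           atol=1e-10)

    def test_kernel_expm_matches_scipy(self):
        from fossildes._kernels import expm4
        rng = np.random.default_rng(0)
        for _ in range(25):
            q = build_q_matrix(AnageneticRates(*rng.uniform(0, 3, 4)))
            dt = rng.uniform(0, 8)
            assert np.allclose(expm4(q * dt), expm(q * dt), atol=1e-12)


class TestObservationModel:
    def test_false_absence_closed_form(self):
        s = false_absence_probability(0.1, 5.0)
        assert s == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert 1 - s == pytest.approx(0.39346934, abs=1e-7)

    def test_false_absence_monotone(self):
        assert (false_absence_probability(0.2, 5.0)
                < false_absence_probability(0.1, 5.0))
        assert (false_absence_probability(0.1, 10.0)
                < false_absence_probability(0.1, 5.0))
        assert false_absence_probability(200.0, 5.0) < 1e-12

    @given(prob_st, prob_st,
           st.sampled_from([CODE_EMPTY, CODE_A, CODE_B, CODE_AB]))
    @settings(max_examples=60, deadline=None)
    def test_true_range_weights_sum_to_one(self, s_a, s_b, code):
        w = observed_state_weights(code, s_a, s_b)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)

    def test_true_range_weight_examples(self):
        assert np.allclose(observed_state_weights(CODE_AB, 0.3, 0.9),
                           [0, 0, 0, 1])
        assert np.allclose(observed_state_weights(CODE_A, 0.5, 0.0),
                           [0, 1, 0, 0])
        assert np.allclose(observed_state_weights(CODE_EMPTY, 0.5, 0.5),
                           [0.25, 0.25, 0.25, 0.25])

    @given(prob_st, prob_st)
    @settings(max_examples=60, deadline=None)
    def test_emissions_normalise_over_observations(self, s_a, s_b):
        """For every true range, the four observable codes partition the
        outcome space, so their emission probabilities sum to one."""
        total = np.zeros(4)
        for code in (CODE_EMPTY, CODE_A, CODE_B, CODE_AB):
            total += emission_probabilities(code, s_a, s_b)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_emission_structure(self):
        e = emission_probabilities(CODE_A, 0.25, 0.5)
        # observing A requires A in the true range and sampling in A
        assert e[0] == 0 and e[2] == 0
        assert e[1] == pytest.approx(0.75)
        assert e[3] == pytest.approx(0.75 * 0.5)
        with pytest.raises(ValueError):
            emission_probabilities(7, 0.5, 0.5)


def _constant(rates, q, root=30.0):
    return DESParameters.constant(root, rates, q)


class TestLineageLikelihood:
    def test_certain_history_has_likelihood_one(self):
        # no events possible, perfect sampling: the only possible history
        # is "always in A", with probability 1
        grid = build_time_grid(30, 5)
        params = _constant(AnageneticRates(0, 0, 0, 0),
                           PreservationRates(1e4, 1e4))
        codes = np.full(grid.n_bins, CODE_A, dtype=np.int8)
        ll = lineage_log_likelihood(codes, CODE_A, params, grid)
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_single_interval_reduces_to_matrix_entry(self):
        grid = build_time_grid(5, 5)
        rates = AnageneticRates(0.12, 0.05, 0.2, 0.08)
        params = _constant(rates, PreservationRates(1e4, 1e4), root=5.0)
        codes = np.array([CODE_A], dtype=np.int8)
        ll = lineage_log_likelihood(codes, CODE_A, params, grid)
        p = transition_probabilities(build_q_matrix(rates), 5.0)
        assert ll == pytest.approx(np.log(p[1, 1]), abs=1e-10)

    def test_matches_path_enumeration_oracle(self):
        """Pruning recursion equals the exhaustive sum over all 4^k true
        state paths, for random rates and observation vectors."""
        rng = np.random.default_rng(21)
        grid = build_time_grid(30, 5)  # 6 bins
        for trial in range(30):
            rates = AnageneticRates(*rng.uniform(0.01, 0.8, 4))
            q = PreservationRates(*rng.uniform(0.05, 1.0, 2))
            params = _constant(rates, q)
            first = int(rng.integers(0, grid.n_bins))
            codes = np.full(grid.n_bins, -1, dtype=np.int8)
            codes[first] = rng.choice([CODE_A, CODE_B, CODE_AB])
            for k in range(first + 1, grid.n_bins):
                codes[k] = rng.integers(0, 4)
            present = int(rng.integers(0, 4))
            got = lineage_log_likelihood(codes, present, params, grid)
            want = enumerate_lineage_loglik(codes, present, params, grid)
            assert got == pytest.approx(want, abs=1e-8)

    def test_stratified_matches_oracle(self):
        rng = np.random.default_rng(9)
        grid = build_time_grid(30, 5)
        frames = []
        bounds = [30.0, 15.0, 0.0]
        for start, end in zip(bounds, bounds[1:]):
            frames.append(TimeFrame(
                start, end, AnageneticRates(*rng.uniform(0.01, 0.5, 4)),
                PreservationRates(*rng.uniform(0.1, 1.0, 2))))
        params = DESParameters(tuple(frames))
        codes = np.array([CODE_B, CODE_EMPTY, CODE_AB, CODE_EMPTY,
                          CODE_A, CODE_EMPTY], dtype=np.int8)
        got = lineage_log_likelihood(codes, CODE_A, params, grid)
        want = enumerate_lineage_loglik(codes, CODE_A, params, grid)
        assert got == pytest.approx(want, abs=1e-8)

    def test_impossible_configuration_is_minus_infinity(self):
        # extinct at present but observed in the last bin with zero
        # extinction rates: probability zero, not an exception
        grid = build_time_grid(10, 5)
        params = _constant(AnageneticRates(0, 0, 0, 0),
                           PreservationRates(0.5, 0.5), root=10.0)
        codes = np.array([CODE_A, CODE_A], dtype=np.int8)
        assert lineage_log_likelihood(codes, CODE_EMPTY, params,
                                      grid) == -np.inf


class TestDatasetLikelihood:
    def test_duplicated_taxon_doubles_loglik(self, tiny_dataset):
        mat = tiny_dataset.matrix
        params = _constant(AnageneticRates(0.1, 0.1, 0.1, 0.1),
                           PreservationRates(0.5, 0.5),
                           root=mat.grid.edges[0])
        one = ObservedRangeMatrix(mat.taxa[:1], mat.grid, mat.codes[:1],
                                  mat.present[:1])
        two = ObservedRangeMatrix(("a", "b"), mat.grid,
                                  np.vstack([mat.codes[:1]] * 2),
                                  np.repeat(mat.present[:1], 2))
        assert dataset_log_likelihood(two, params) == pytest.approx(
            2 * dataset_log_likelihood(one, params), abs=1e-10)

    def test_taxon_order_irrelevant(self, tiny_dataset):
        mat = tiny_dataset.matrix
        params = _constant(AnageneticRates(0.2, 0.1, 0.15, 0.05),
                           PreservationRates(0.4, 0.8),
                           root=mat.grid.edges[0])
        perm = np.random.default_rng(3).permutation(mat.n_taxa)
        shuffled = ObservedRangeMatrix(
            tuple(mat.taxa[i] for i in perm), mat.grid, mat.codes[perm],
            mat.present[perm])
        assert dataset_log_likelihood(shuffled, params) == pytest.approx(
            dataset_log_likelihood(mat, params), abs=1e-10)

    def test_tied_frames_equal_constant_rate(self, tiny_dataset):
        mat = tiny_dataset.matrix
        root = mat.grid.edges[0]
        rates = AnageneticRates(0.08, 0.21, 0.12, 0.3)
        q = PreservationRates(0.3, 0.6)
        constant = _constant(rates, q, root=root)
        split = DESParameters((
            TimeFrame(root, 25.0, rates, q),
            TimeFrame(25.0, 10.0, rates, q),
            TimeFrame(10.0, 0.0, rates, q)))
        assert dataset_log_likelihood(mat, split) == pytest.approx(
            dataset_log_likelihood(mat, constant), abs=1e-10)

    def test_kernel_agrees_with_reference(self, small_dataset):
        from fossildes import _kernels
        from fossildes.mcmc import _pack_data
        mat = small_dataset.matrix
        rng = np.random.default_rng(17)
        codes, present, first, fob, n_frames, dt = _pack_data(mat, None)
        for _ in range(5):
            rates = AnageneticRates(*rng.uniform(0.01, 0.6, 4))
            q = PreservationRates(*rng.uniform(0.05, 1.0, 2))
            params = _constant(rates, q, root=mat.grid.edges[0])
            p = np.empty((1, 4, 4))
            _kernels._frame_transition(
                np.array([rates.d_ab, rates.d_ba, rates.e_a, rates.e_b]),
                dt, p[0])
            s_a = np.array([np.exp(-q.q_a * dt)])
            s_b = np.array([np.exp(-q.q_b * dt)])
            got = _kernels.dataset_loglik(codes, present, first, fob,
                                          p, s_a, s_b)
            assert got == pytest.approx(
                dataset_log_likelihood(mat, params), rel=1e-10)

    def test_frame_validation(self):
        with pytest.raises(ValueError, match="tile"):
            DESParameters((
                TimeFrame(50, 30, AnageneticRates(0, 0, 0, 0),
                          PreservationRates(1, 1)),
                TimeFrame(20, 0, AnageneticRates(0, 0, 0, 0),
                          PreservationRates(1, 1))))
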