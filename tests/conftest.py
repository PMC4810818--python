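"""Shared fixtures: small simulated datasets and the (single, shared)
simulation-recovery experiment used by the validation tests."""

from __future__ import annotations

import numpy as np
import pytest

from fossildes import SimulationConfig, simulate_dataset
from fossildes.mcmc import ChainConfig
from fossildes.summaries import accuracy_experiment


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, coarse dataset for fast MCMC tests."""
    return simulate_dataset(SimulationConfig(
        seed=7, bin_size=5.0, n_lineages=(10, 15)))


@pytest.fixture(scope="session")
def recovery_experiment():
    """Simulation-recovery runs at the study's four bin sizes.

    Full-length chains (26 000 iterations, 6 000 burn-in, sampled every
    10); 100 datasets at bin sizes 5 and 2.5 Myr, 50 at 1 and 0.5 Myr.
    Computed once per session and shared by the accuracy tests.
    """
    chain = ChainConfig()
    reports = {}
    for bin_size, n_data, seed in [(5.0, 100, 10), (2.5, 100, 11),
                                   (1.0, 50, 12), (0.5, 50, 13)]:
        cfg = SimulationConfig(bin_size=bin_size)
        reports[bin_size] = accuracy_experiment(
            cfg, n_data, chain=chain, seed=seed)
    return reports


def enumerate_lineage_loglik(codes, present, params, grid):
    """Independent oracle: exhaustive sum over all true-state paths.

    Enumerates every assignment of true ranges to the coded bins,
    weighting the first-appearance state by the ancestral-state prior
    (probability of each true range given the observed range there) and
    every later bin by its observation probability, with per-step
    transition probabilities and the present-day state fixed.
    Exponential in the number of coded bins; use for <= 6 bins.
    """
    from itertools import product

    from fossildes.likelihood import (build_q_matrix, emission_probabilities,
                                      false_absence_probability,
                                      observed_state_weights,
                                      transition_probabilities)

    codes = np.asarray(codes)
    observed = np.nonzero(codes != -1)[0]
    first = int(observed[0])
    k_bins = grid.n_bins
    shift = params.shift_times
    frame_of_bin = (grid.frame_index(shift) if len(shift)
                    else np.zeros(k_bins, dtype=int))
    p_frames = [transition_probabilities(build_q_matrix(f.rates),
                                         grid.bin_size)
                for f in params.frames]
    s_frames = [(false_absence_probability(f.preservation.q_a,
                                           grid.bin_size),
                 false_absence_probability(f.preservation.q_b,
                                           grid.bin_size))
                for f in params.frames]
    total = 0.0
    n_steps = k_bins - first
    for path in product(range(4), repeat=n_steps):
        states = list(path) + [present]
        prob = 1.0
        for i, k in enumerate(range(first, k_bins)):
            f = frame_of_bin[k]
            s_a, s_b = s_frames[f]
            if k == first:
                prob *= observed_state_weights(int(codes[k]), s_a, s_b)[
                    states[i]]
            else:
                prob *= emission_probabilities(int(codes[k]), s_a, s_b)[
                    states[i]]
            prob *= p_frames[f][states[i], states[i + 1]]
        total += prob
    return -np.inf if total <= 0 else float(np.log(total))
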