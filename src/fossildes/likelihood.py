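"""DES likelihood: CTMC range evolution filtered through Poisson sampling.

The latent geographic range of a lineage evolves on the state space
(empty, A, B, AB) under a continuous-time Markov chain whose generator
collects the four anagenetic rates: dispersal ``d_AB`` (A gains B, i.e.
A -> AB), ``d_BA`` (B -> AB), and local extinction ``e_A`` (loss of A:
A -> empty, AB -> B), ``e_B`` (loss of B).  The empty range is absorbing
(global extinction).  Fossil sampling in each area is an independent
homogeneous Poisson process with rate ``q``; a lineage present in an
area throughout a bin of length dt leaves no record with probability
``s = exp(-q * dt)`` (a *false absence*).

The likelihood of one lineage's observed code vector is computed by a
backward pruning recursion from the known present-day range to the first
appearance, alternating CTMC transition steps (matrix exponentials) with
element-wise observation probabilities; at the first appearance the
recursion closes with a normalised ancestral-state prior built from the
range observed there and the preservation process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .ranges import (CODE_A, CODE_AB, CODE_B, CODE_EMPTY, CODE_NOT_YET,
                     ObservedRangeMatrix, TimeGrid)

__all__ = [
    "STATES",
    "AnageneticRates",
    "PreservationRates",
    "TimeFrame",
    "DESParameters",
    "build_q_matrix",
    "transition_probabilities",
    "false_absence_probability",
    "observed_state_weights",
    "emission_probabilities",
    "lineage_log_likelihood",
    "dataset_log_likelihood",
]

#: fixed ordering of true-range states used by every matrix and vector
STATES = ("empty", "A", "B", "AB")


@dataclass(frozen=True)
class AnageneticRates:
    """Dispersal and local-extinction rates (events / lineage / Myr)."""

    d_ab: float
    d_ba: float
    e_a: float
    e_b: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"rate {name} must be >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {"d_AB": self.d_ab, "d_BA": self.d_ba,
                "e_A": self.e_a, "e_B": self.e_b}


@dataclass(frozen=True)
class PreservationRates:
    """Area-specific fossil sampling rates (occurrences / lineage / Myr)."""

    q_a: float
    q_b: float

    def __post_init__(self) -> None:
        if self.q_a <= 0 or self.q_b <= 0:
            raise ValueError(
                f"preservation rates must be positive, got "
                f"({self.q_a}, {self.q_b})")


@dataclass(frozen=True)
class TimeFrame:
    """One time frame [start, end) Ma with its own rate set."""

    start: float
    end: float
    rates: AnageneticRates
    preservation: PreservationRates

    def __post_init__(self) -> None:
        if self.start <= self.end:
            raise ValueError(
                f"frame start {self.start} must be older than end {self.end}")


@dataclass(frozen=True)
class DESParameters:
    """Ordered frames tiling [root_age, 0]; one frame = constant-rate model."""

    frames: tuple[TimeFrame, ...]

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ValueError("need at least one time frame")
        if frames[-1].end != 0.0:
            raise ValueError("youngest frame must end at the present (0 Ma)")
        for older, younger in zip(frames, frames[1:]):
            if older.end != younger.start:
                raise ValueError(
                    f"frames do not tile: {older.end} != {younger.start}")

    @classmethod
    def constant(cls, root_age: float, rates: AnageneticRates,
                 preservation: PreservationRates) -> "DESParameters":
        return cls(frames=(TimeFrame(root_age, 0.0, rates, preservation),))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shift_times(self) -> np.ndarray:
        return np.array([f.start for f in self.frames[1:]])


def build_q_matrix(rates: AnageneticRates) -> np.ndarray:
    """Generator matrix over (empty, A, B, AB).

    Only single-area gains/losses occur: no direct A<->B jumps and no
    AB -> empty collapse; the empty row is zero (absorbing).
    """
    d_ab, d_ba, e_a, e_b = rates.d_ab, rates.d_ba, rates.e_a, rates.e_b
    q = np.array([
        [0.0,  0.0,  0.0,  0.0],
        [e_a, -(e_a + d_ab), 0.0, d_ab],
        [e_b,  0.0, -(e_b + d_ba), d_ba],
        [0.0,  e_b,  e_a, -(e_a + e_b)],
    ])
    return q


def transition_probabilities(q: np.ndarray, dt: float) -> np.ndarray:
    """P(dt) = expm(Q dt): row-stochastic range-transition probabilities."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return expm(np.asarray(q, dtype=float) * dt)


def false_absence_probability(q: float, dt: float) -> float:
    """P(no fossil in a bin of length dt | present throughout) = exp(-q dt)."""
    if q <= 0:
        raise ValueError(f"preservation rate must be positive, got {q}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return float(np.exp(-q * dt))


def observed_state_weights(observed: int, s_a: float, s_b: float,
                           ) -> np.ndarray:
    """Probability of each true range given the observed code of a bin.

    ``s_a``/``s_b`` are the per-bin false-absence probabilities.  A
    sampled presence is taken as true; an unsampled area may be a true
    absence (prob. 1-s) or a false absence (prob. s), treated
    independently per area, so each vector sums to one over the true
    states.  This is the interpretive table of the model; the
    likelihood recursion itself uses the complementary observation
    probabilities of :func:`emission_probabilities`.
    """
    if not (0.0 <= s_a <= 1.0 and 0.0 <= s_b <= 1.0):
        raise ValueError(f"s values must be in [0,1], got ({s_a}, {s_b})")
    if observed == CODE_EMPTY:
        return np.array([(1 - s_a) * (1 - s_b), s_a * (1 - s_b),
                         (1 - s_a) * s_b, s_a * s_b])
    if observed == CODE_A:
        return np.array([0.0, 1 - s_b, 0.0, s_b])
    if observed == CODE_B:
        return np.array([0.0, 0.0, 1 - s_a, s_a])
    if observed == CODE_AB:
        return np.array([0.0, 0.0, 0.0, 1.0])
    raise ValueError(f"invalid observed code {observed}")


def emission_probabilities(observed: int, s_a: float, s_b: float,
                           ) -> np.ndarray:
    """Probability of a bin's observed code given each true range.

    Under the Poisson preservation process, a lineage present in an
    area throughout a bin is sampled there with probability ``1 - s``
    and missed with probability ``s``; absent areas are never sampled.
    Observed presences are therefore subsets of the true range:
    incompatible combinations (an observation outside the true range)
    get probability zero, the empty range emits only the observed-empty
    code.  These per-bin factors make preservation rates identifiable —
    every recorded presence rewards ``1 - s`` and every gap over an
    occupied area costs ``s``.
    """
    if not (0.0 <= s_a <= 1.0 and 0.0 <= s_b <= 1.0):
        raise ValueError(f"s values must be in [0,1], got ({s_a}, {s_b})")
    if observed == CODE_EMPTY:
        return np.array([1.0, s_a, s_b, s_a * s_b])
    if observed == CODE_A:
        return np.array([0.0, 1 - s_a, 0.0, (1 - s_a) * s_b])
    if observed == CODE_B:
        return np.array([0.0, 0.0, 1 - s_b, s_a * (1 - s_b)])
    if observed == CODE_AB:
        return np.array([0.0, 0.0, 0.0, (1 - s_a) * (1 - s_b)])
    raise ValueError(f"invalid observed code {observed}")


def _per_bin_tables(params: DESParameters, grid: TimeGrid,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transition matrix and (s_a, s_b) per bin, resolved via frames."""
    shift = params.shift_times
    edge_set = {round(float(e), 9) for e in grid.edges}
    snapped = []
    for t in shift:
        if round(float(t), 9) not in edge_set:
            near = grid.edges[np.argmin(np.abs(grid.edges - t))]
            warnings.warn(
                f"rate-shift time {t} Ma is not a bin edge; snapped to "
                f"{near} Ma", stacklevel=3)
            t = near
        snapped.append(float(t))
    frame_of_bin = grid.frame_index(np.array(snapped)) if snapped else \
        np.zeros(grid.n_bins, dtype=np.int64)
    p_frames = [transition_probabilities(build_q_matrix(f.rates),
                                         grid.bin_size)
                for f in params.frames]
    s_frames = np.array(
        [[false_absence_probability(f.preservation.q_a, grid.bin_size),
          false_absence_probability(f.preservation.q_b, grid.bin_size)]
         for f in params.frames])
    p_bins = np.stack([p_frames[f] for f in frame_of_bin])
    s_bins = s_frames[frame_of_bin]
    return p_bins, s_bins[:, 0], s_bins[:, 1]


def lineage_log_likelihood(codes: np.ndarray, present: int,
                           params: DESParameters, grid: TimeGrid) -> float:
    """Log-likelihood of one lineage's observed code vector.

    Pruning recursion from the present backwards: the conditional
    likelihood vector starts as a point mass on the known present-day
    range (empty for extinct lineages) and is propagated through each
    bin's transition matrix and multiplied by that bin's observation
    probabilities.  At the first-appearance bin the vector is averaged
    over the ancestral-state prior :func:`observed_state_weights` — the
    probability of each true range given the range observed there —
    rather than summed with emission weights: the ancestral state is
    conditioned on its observation, not emitted, and using a normalised
    prior keeps the likelihood from being inflated when several
    ancestral states can reproduce the data.  Returns ``-inf`` for
    configurations of probability zero.
    """
    codes = np.asarray(codes)
    if len(codes) != grid.n_bins:
        raise ValueError("code vector length does not match the grid")
    observed = np.nonzero(codes != CODE_NOT_YET)[0]
    if len(observed) == 0:
        raise ValueError("lineage has no observed bins")
    first = int(observed[0])
    if codes[first] == CODE_EMPTY:
        raise ValueError("first coded state must be non-empty")
    root = params.frames[0].start
    if root + 1e-9 < grid.edges[first]:
        raise ValueError(
            f"model frames start at {root} Ma but the lineage appears at "
            f"{grid.edges[first]} Ma")
    p_bins, s_a, s_b = _per_bin_tables(params, grid)
    v = np.zeros(4)
    v[present] = 1.0
    log_scale = 0.0
    for k in range(grid.n_bins - 1, first, -1):
        v = p_bins[k] @ v
        v = v * emission_probabilities(int(codes[k]), s_a[k], s_b[k])
        peak = v.max()
        if peak <= 0.0:
            return -np.inf
        v /= peak
        log_scale += np.log(peak)
    v = p_bins[first] @ v
    root_prior = observed_state_weights(int(codes[first]), s_a[first],
                                        s_b[first])
    total = float(root_prior @ v)
    if total <= 0.0:
        return -np.inf
    return float(log_scale + np.log(total))


def dataset_log_likelihood(data: ObservedRangeMatrix,
                           params: DESParameters) -> float:
    """Sum of lineage log-likelihoods (ranges evolve independently)."""
    total = 0.0
    for i, taxon in enumerate(data.taxa):
        try:
            total += lineage_log_likelihood(
                data.codes[i], int(data.present[i]), params, data.grid)
        except ValueError as err:
            raise ValueError(f"taxon {taxon!r}: {err}") from err
        if total == -np.inf:
            return -np.inf
    return total
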