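"""Synthetic fossil biogeography datasets.

Each lineage's true range history is simulated forward in time as a
continuous-time Markov chain on (empty, A, B, AB) using competing
exponential clocks for the allowed transitions (Gillespie algorithm).
Fossil occurrences are then laid down by an independent homogeneous
Poisson process per area, with rate q over exactly the time the lineage
occupied that area, and the occurrences are binned into an observed
range matrix.  Generating parameters are drawn once per dataset from
the study distributions and stored alongside the data.

Default study conditions: 50 Myr span, origination times uniform over
the span, initial range uniform over {A, B}, dispersal and extinction
rates ~ U(0.01, 0.3), preservation rates ~ U(0.05, 1) (one expected
occurrence per lineage per 20 Myr up to one per Myr), and 20-200
lineages per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import AnageneticRates, PreservationRates
from .ranges import (CODE_A, CODE_AB, CODE_B, CODE_EMPTY, FossilOccurrence,
                     ObservedRangeMatrix, PresentRange, assign_point_ages,
                     build_time_grid, code_ranges)

__all__ = [
    "SimulationConfig",
    "LineageHistory",
    "TrueParameters",
    "SimulatedDataset",
    "simulate_history",
    "sample_fossils",
    "simulate_dataset",
]

# transitions allowed from each true state: (target, rate attribute)
_TRANSITIONS = {
    CODE_A: ((CODE_EMPTY, "e_a"), (CODE_AB, "d_ab")),
    CODE_B: ((CODE_EMPTY, "e_b"), (CODE_AB, "d_ba")),
    CODE_AB: ((CODE_B, "e_a"), (CODE_A, "e_b")),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one batch of simulated datasets."""

    span: float = 50.0
    bin_size: float = 2.5
    n_lineages: tuple[int, int] = (20, 200)
    d_range: tuple[float, float] = (0.01, 0.3)
    e_range: tuple[float, float] = (0.01, 0.3)
    q_range: tuple[float, float] = (0.05, 1.0)
    include_ab_initial: bool = False
    age_blur: float = 0.0  # half-width (Myr) of optional stratigraphic blur
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.span <= 0 or self.bin_size <= 0:
            raise ValueError("span and bin_size must be positive")
        for name in ("n_lineages", "d_range", "e_range", "q_range"):
            low, high = getattr(self, name)
            if not (0 <= low <= high):
                raise ValueError(f"invalid {name} bounds ({low}, {high})")
        if self.q_range[0] <= 0:
            raise ValueError("preservation rates must be positive")


@dataclass(frozen=True)
class LineageHistory:
    """Piecewise-constant true range trajectory of one lineage.

    ``changes`` is the list of (time Ma, state) change points starting
    at origination, times strictly decreasing; an entry with state
    ``CODE_EMPTY`` marks global extinction (the trajectory then stays
    empty to the present).
    """

    origin: float
    changes: tuple[tuple[float, int], ...]

    @property
    def extinction_time(self) -> float | None:
        for t, state in self.changes:
            if state == CODE_EMPTY:
                return t
        return None

    @property
    def extant(self) -> bool:
        return self.extinction_time is None

    def state_at(self, age: float) -> int:
        """True range at a given age (Ma); origin-exclusive ages only."""
        if age > self.origin:
            raise ValueError(f"age {age} predates origination {self.origin}")
        state = self.changes[0][1]
        for t, new_state in self.changes[1:]:
            if t >= age:
                state = new_state
            else:
                break
        return state

    def occupancy(self, area_code: int) -> list[tuple[float, float]]:
        """Intervals (older, younger) during which the lineage occupied
        the given single area (CODE_A or CODE_B)."""
        times = [t for t, _ in self.changes] + [0.0]
        states = [s for _, s in self.changes]
        out = []
        for start, end, state in zip(times[:-1], times[1:], states):
            if state == area_code or state == CODE_AB:
                out.append((start, end))
        return out


def simulate_history(rates: AnageneticRates, origin: float, initial: int,
                     rng: np.random.Generator) -> LineageHistory:
    """Gillespie simulation of one lineage's range history from
    ``origin`` (Ma) down to the present or to global extinction."""
    if origin <= 0:
        raise ValueError(f"origination time must be > 0 Ma, got {origin}")
    if initial not in (CODE_A, CODE_B, CODE_AB):
        raise ValueError(f"initial range must be non-empty, got {initial}")
    t = origin
    state = initial
    changes = [(origin, initial)]
    while state != CODE_EMPTY:
        moves = _TRANSITIONS[state]
        move_rates = np.array([getattr(rates, attr) for _, attr in moves])
        total = move_rates.sum()
        if total <= 0.0:
            break
        t = t - rng.exponential(1.0 / total)
        if t <= 0.0:
            break
        state = moves[rng.choice(len(moves), p=move_rates / total)][0]
        changes.append((t, state))
    return LineageHistory(origin=origin, changes=tuple(changes))


def sample_fossils(history: LineageHistory, q: PreservationRates,
                   rng: np.random.Generator,
                   taxon: str = "t0") -> list[FossilOccurrence]:
    """Poisson fossil sampling over the lineage's occupancy of each area.

    Occurrence ages are exact (min_age == max_age == point_age); the
    expected count in an area is q times the total time spent there.
    """
    out = []
    for area, area_code, rate in (("A", CODE_A, q.q_a),
                                  ("B", CODE_B, q.q_b)):
        for older, younger in history.occupancy(area_code):
            n = rng.poisson(rate * (older - younger))
            for age in rng.uniform(younger, older, size=n):
                out.append(FossilOccurrence(
                    taxon=taxon, area=area, min_age=float(age),
                    max_age=float(age), point_age=float(age)))
    out.sort(key=lambda occ: -occ.point_age)
    return out


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters stored with every simulated dataset."""

    rates: AnageneticRates
    preservation: PreservationRates
    n_lineages: int

    def as_dict(self) -> dict[str, float]:
        d = self.rates.as_dict()
        d["q_A"] = self.preservation.q_a
        d["q_B"] = self.preservation.q_b
        return d


@dataclass(frozen=True)
class SimulatedDataset:
    params: TrueParameters
    matrix: ObservedRangeMatrix
    histories: tuple[LineageHistory, ...] = field(repr=False)
    occurrences: tuple[FossilOccurrence, ...] = field(repr=False)
    present: tuple[PresentRange, ...] = field(repr=False)


def simulate_dataset(cfg: SimulationConfig,
                     rng: np.random.Generator | int | None = None,
                     max_retries: int = 100) -> SimulatedDataset:
    """Draw one dataset: parameters, true histories, fossils, coded matrix.

    Lineages never sampled in the fossil record are dropped (they have
    no first appearance); a dataset in which no lineage was sampled is
    re-drawn, up to ``max_retries`` times.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(cfg.seed if rng is None else rng))
    for _ in range(max_retries):
        rates = AnageneticRates(
            d_ab=rng.uniform(*cfg.d_range), d_ba=rng.uniform(*cfg.d_range),
            e_a=rng.uniform(*cfg.e_range), e_b=rng.uniform(*cfg.e_range))
        q = PreservationRates(q_a=rng.uniform(*cfg.q_range),
                              q_b=rng.uniform(*cfg.q_range))
        n = int(rng.integers(cfg.n_lineages[0], cfg.n_lineages[1] + 1))
        initial_states = ((CODE_A, CODE_B, CODE_AB)
                          if cfg.include_ab_initial else (CODE_A, CODE_B))
        histories = []
        occurrences: list[FossilOccurrence] = []
        present: list[PresentRange] = []
        kept_histories = []
        for i in range(n):
            origin = float(rng.uniform(0.0, cfg.span))
            history = simulate_history(
                rates, origin, int(rng.choice(initial_states)), rng)
            histories.append(history)
            occs = sample_fossils(history, q, rng, taxon=f"t{i}")
            if not occs:
                continue
            if cfg.age_blur > 0.0:
                occs = assign_point_ages(
                    _blur_ages(occs, cfg.age_blur, cfg.span), rng)
            occurrences.extend(occs)
            final = (CODE_EMPTY if not history.extant
                     else history.state_at(0.0))
            present.append(PresentRange(taxon=f"t{i}", range_code=final))
            kept_histories.append(history)
        if present:
            grid = build_time_grid(cfg.span, cfg.bin_size)
            matrix = code_ranges(occurrences, present, grid)
            params = TrueParameters(rates=rates, preservation=q,
                                    n_lineages=n)
            return SimulatedDataset(
                params=params, matrix=matrix,
                histories=tuple(kept_histories),
                occurrences=tuple(occurrences), present=tuple(present))
    raise RuntimeError(
        f"no lineage was sampled in {max_retries} attempted datasets")


def _blur_ages(occs: list[FossilOccurrence], half_width: float,
               span: float) -> list[FossilOccurrence]:
    """Widen exact occurrence dates into stratigraphic-style ranges
    (clipped to [0, span]); exercises downstream age resampling."""
    out = []
    for occ in occs:
        out.append(FossilOccurrence(
            taxon=occ.taxon, area=occ.area,
            min_age=max(0.0, occ.point_age - half_width),
            max_age=min(span, occ.point_age + half_width),
            point_age=None))
    return out
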