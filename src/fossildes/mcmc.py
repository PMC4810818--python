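"""Posterior sampling and marginal likelihoods for the DES model.

Priors: each dispersal and extinction rate gets an exponential prior
Exp(g) whose rate g is itself estimated under a Gamma(a, b) hyper-prior
(g is shared across all time frames); each false-absence probability s
gets a flat Beta(1, 1) prior, which induces an exponential prior on the
corresponding preservation rate q = -ln(s)/dt.

Sampling: block Metropolis-Hastings — multiplier proposals for rates,
sliding-window proposals reflected at 0 and 1 for the s parameters, and
a direct conjugate Gibbs draw for g from Gamma(a + n, b + sum(x)) where
n counts the dispersal/extinction parameters and x is their vector.

Model comparison: thermodynamic integration along a power-posterior
path (likelihood tempered by beta in [0, 1]), integrating the per-beta
mean log-likelihood by the trapezoidal rule; Bayes factors are reported
as differences of marginal log-likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .likelihood import DESParameters
from .ranges import ObservedRangeMatrix

__all__ = [
    "PriorConfig",
    "ChainConfig",
    "log_prior_density",
    "gibbs_update_g",
    "propose_multiplier",
    "propose_reflected",
    "run_mcmc",
    "power_posterior_betas",
    "marginal_log_likelihood",
    "log_bayes_factor",
    "param_columns",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyper-prior Gamma(a, b) on the exponential rate g; flat prior on s."""

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(
                f"hyper-prior shape/rate must be positive, got "
                f"({self.a}, {self.b})")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings (defaults follow the simulation-study protocol)."""

    iterations: int = 26_000
    sampling_freq: int = 10
    burn_in: int = 6_000
    multiplier_window: float = 2.0 * math.log(1.2)
    slide_window: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.multiplier_window <= 0 or self.slide_window <= 0:
            raise ValueError("proposal windows must be positive")


def log_prior_density(params: DESParameters, g: float,
                      priors: PriorConfig) -> float:
    """Joint log prior of a full parameter set and the hyper-rate g."""
    if g <= 0:
        raise ValueError(f"hyper-rate g must be positive, got {g}")
    total = 0.0
    for frame in params.frames:
        for rate in frame.rates.as_dict().values():
            if rate < 0:
                return -np.inf
            total += math.log(g) - g * rate
    # flat Beta(1,1) on each s contributes 0
    total += (priors.a * math.log(priors.b) - math.lgamma(priors.a)
              + (priors.a - 1.0) * math.log(g) - priors.b * g)
    return total


def gibbs_update_g(rates: Sequence[float], priors: PriorConfig,
                   rng: np.random.Generator) -> float:
    """Draw g from its conjugate conditional Gamma(a + n, b + sum(x))."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    shape = priors.a + rates.size
    rate = priors.b + rates.sum()
    return float(rng.gamma(shape, 1.0 / rate))


def propose_multiplier(value: float, tuning: float,
                       rng: np.random.Generator) -> tuple[float, float]:
    """Multiplier proposal value * exp(tuning (u - 1/2)); returns
    (proposal, log Hastings ratio = log multiplier)."""
    if value <= 0:
        raise ValueError(f"multiplier proposal needs value > 0, got {value}")
    mult = math.exp(tuning * (rng.random() - 0.5))
    return value * mult, math.log(mult)


def propose_reflected(value: float, window: float,
                      rng: np.random.Generator) -> float:
    """Sliding-window proposal on [0, 1] with reflection at both edges
    (symmetric, so the Hastings ratio is zero)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"reflected proposal needs value in [0,1], "
                         f"got {value}")
    x = value + window * (rng.random() - 0.5)
    while x < 0.0 or x > 1.0:
        x = -x if x < 0.0 else 2.0 - x
    return x


def _pack_data(data: ObservedRangeMatrix,
               shift_times: Sequence[float] | None,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                          int, float]:
    """Arrays the kernels consume: codes, present, first-appearance bin,
    frame index per bin, frame count, bin size."""
    shift = np.asarray(shift_times if shift_times is not None else [],
                       dtype=float)
    if len(shift):
        if np.any(np.diff(shift) >= 0):
            raise ValueError("shift times must be strictly decreasing (Ma)")
        if shift.max() >= data.grid.edges[0] or shift.min() <= 0:
            raise ValueError("shift times must lie inside (root_age, 0)")
        frame_of_bin = data.grid.frame_index(shift)
    else:
        frame_of_bin = np.zeros(data.grid.n_bins, dtype=np.int64)
    n_frames = int(frame_of_bin.max()) + 1
    return (np.ascontiguousarray(data.codes, dtype=np.int8),
            data.present.astype(np.int64),
            data.first_bin.astype(np.int64),
            frame_of_bin.astype(np.int64),
            n_frames,
            float(data.grid.bin_size))


def param_columns(n_frames: int) -> list[str]:
    """Per-frame parameter column names (frame 0 = oldest)."""
    base = ["d_AB", "d_BA", "e_A", "e_B", "s_A", "s_B"]
    if n_frames == 1:
        return base
    return [f"{name}_f{f}" for f in range(n_frames) for name in base]


def _init_state(codes, present, first, frame_of_bin, n_frames, dt,
                rng: np.random.Generator, max_retries: int = 50,
                ) -> tuple[np.ndarray, np.ndarray, float]:
    for _ in range(max_retries):
        rates = rng.exponential(0.1, size=(n_frames, 4))
        s = rng.uniform(0.2, 0.8, size=(n_frames, 2))
        p = np.empty((n_frames, 4, 4))
        for f in range(n_frames):
            _kernels._frame_transition(rates[f], dt, p[f])
        ll = _kernels.dataset_loglik(codes, present, first, frame_of_bin,
                                     p, s[:, 0].copy(), s[:, 1].copy())
        if np.isfinite(ll):
            return rates, s, 1.0
    raise RuntimeError(
        "could not find starting parameters with finite likelihood")


def _samples_frame(raw: np.ndarray, n_frames: int, dt: float,
                   ) -> pd.DataFrame:
    cols = ["iteration", "log_likelihood", "log_prior"]
    cols += param_columns(n_frames) + ["g"]
    df = pd.DataFrame(raw, columns=cols)
    df["iteration"] = df["iteration"].astype(int)
    df["log_posterior"] = df["log_likelihood"] + df["log_prior"]
    for col in list(df.columns):
        if col.startswith("s_"):
            df["q" + col[1:]] = -np.log(df[col]) / dt
    return df


def run_mcmc(data: ObservedRangeMatrix,
             shift_times: Sequence[float] | None = None,
             priors: PriorConfig | None = None,
             chain: ChainConfig | None = None,
             beta: float = 1.0) -> pd.DataFrame:
    """Sample the DES posterior; returns the full chain log as a DataFrame.

    One row per retained sample with the log-likelihood, log-prior,
    per-frame rates, false-absence probabilities s, the derived
    preservation rates q = -ln(s)/dt, and the hyper-rate g.  Burn-in
    rows are included (downstream summaries drop them); two runs with
    the same seed are identical.
    """
    priors = priors or PriorConfig()
    chain = chain or ChainConfig()
    packed = _pack_data(data, shift_times)
    codes, present, first, frame_of_bin, n_frames, dt = packed
    ss = np.random.SeedSequence(chain.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    kernel_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
    rates0, s0, g0 = _init_state(codes, present, first, frame_of_bin,
                                 n_frames, dt, init_rng)
    raw, _, _, _ = _kernels.run_chain(
        codes, present, first, frame_of_bin, n_frames, dt,
        rates0, s0, g0, priors.a, priors.b,
        chain.multiplier_window, chain.slide_window,
        chain.iterations, chain.sampling_freq, float(beta), kernel_seed)
    return _samples_frame(raw, n_frames, dt)


def power_posterior_betas(k: int = 10, shape: float = 0.3) -> np.ndarray:
    """K tempering values: quantiles of Beta(shape, 1), i.e.
    ``(i/(K-1))**(1/shape)``, spanning 0 to 1 and clustered near 0."""
    if k < 2:
        raise ValueError(f"need at least 2 beta values, got {k}")
    return (np.arange(k) / (k - 1)) ** (1.0 / shape)


def marginal_log_likelihood(data: ObservedRangeMatrix,
                            shift_times: Sequence[float] | None = None,
                            priors: PriorConfig | None = None,
                            chain: ChainConfig | None = None,
                            betas: np.ndarray | None = None,
                            ) -> tuple[float, pd.DataFrame]:
    """Marginal log-likelihood by thermodynamic integration.

    Runs one power-posterior chain per beta (``chain.iterations``
    iterations each, 10% of retained samples discarded as burn-in,
    successive chains warm-started from the previous beta's end state)
    and integrates the mean sampled log-likelihood over beta by the
    trapezoidal rule.  Returns the estimate and the per-beta path table.
    """
    priors = priors or PriorConfig()
    chain = chain or ChainConfig()
    betas = np.sort(np.asarray(
        betas if betas is not None else power_posterior_betas()))
    packed = _pack_data(data, shift_times)
    codes, present, first, frame_of_bin, n_frames, dt = packed
    ss = np.random.SeedSequence(chain.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    rates, s, g = _init_state(codes, present, first, frame_of_bin,
                              n_frames, dt, init_rng)
    seeds = ss.generate_state(len(betas), dtype=np.uint32) % (2**31 - 1)
    means = np.empty(len(betas))
    for i, beta in enumerate(betas):
        raw, rates, s, g = _kernels.run_chain(
            codes, present, first, frame_of_bin, n_frames, dt,
            rates, s, float(g), priors.a, priors.b,
            chain.multiplier_window, chain.slide_window,
            chain.iterations, chain.sampling_freq, float(beta),
            int(seeds[i]))
        if not np.all(np.isfinite(raw[:, 1])):
            raise RuntimeError(
                f"power-posterior chain at beta={beta} produced non-finite "
                "log-likelihoods")
        keep = raw[len(raw) // 10:, 1]
        means[i] = keep.mean()
    path = pd.DataFrame({"beta": betas, "mean_log_likelihood": means})
    return float(np.trapezoid(means, betas)), path


def log_bayes_factor(marglik_1: float, marglik_2: float) -> float:
    """Log Bayes factor: difference of marginal log-likelihoods."""
    if not (np.isfinite(marglik_1) and np.isfinite(marglik_2)):
        raise ValueError("marginal log-likelihoods must be finite")
    return float(marglik_1 - marglik_2)


def sample_power_posterior(log_likelihood: Callable[[float], float],
                           x0: float, n_iter: int, beta: float,
                           rng: np.random.Generator,
                           log_prior: Callable[[float], float],
                           propose: Callable[
                               [float, np.random.Generator],
                               tuple[float, float]],
                           ) -> np.ndarray:
    """Generic scalar power-posterior Metropolis sampler.

    Targets prior(x) * likelihood(x)**beta with a user-supplied proposal
    returning (candidate, log Hastings ratio).  Returns the sampled
    log-likelihood trace; used to validate the thermodynamic-integration
    quadrature against analytically tractable toy targets.
    """
    x = x0
    ll = log_likelihood(x)
    lp = log_prior(x)
    trace = np.empty(n_iter)
    for i in range(n_iter):
        cand, hastings = propose(x, rng)
        lp_new = log_prior(cand)
        if np.isfinite(lp_new):
            ll_new = log_likelihood(cand)
            if (math.log(rng.random())
                    < beta * (ll_new - ll) + lp_new - lp + hastings):
                x, ll, lp = cand, ll_new, lp_new
        trace[i] = ll
    return trace
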