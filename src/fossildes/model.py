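"""Model / Results interface for DES analyses.

:class:`DESModel` wraps an observed range matrix (plus optional rate-
shift times for the time-stratified variant) and exposes ``loglike``,
``fit`` (MCMC) and ``marginal_likelihood`` (thermodynamic integration).
``fit`` returns a :class:`DESResults` carrying the posterior samples
with MAP estimates, HPD intervals, asymmetry tests and a summary table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .likelihood import DESParameters, dataset_log_likelihood
from .mcmc import (ChainConfig, PriorConfig, marginal_log_likelihood,
                   param_columns, run_mcmc)
from .ranges import (FossilOccurrence, ObservedRangeMatrix, PresentRange,
                     assign_point_ages, build_time_grid, code_ranges,
                     read_occurrences, read_present_ranges)
from .summaries import (asymmetry_significant, combine_replicates,
                        effective_sample_size, hpd_interval, map_estimate)

__all__ = ["DESModel", "DESResults"]


class DESModel:
    """Dispersal-extinction-sampling model for a binned fossil dataset.

    Parameters
    ----------
    data
        Observed range matrix (taxa x time bins).
    shift_times
        Rate-shift times in Ma, strictly decreasing, for the stratified
        variant; ``None`` or empty for the constant-rate model.
    priors
        Hyper-prior settings (defaults: Gamma(1, 1) on g, flat on s).
    """

    def __init__(self, data: ObservedRangeMatrix,
                 shift_times: Sequence[float] | None = None,
                 priors: PriorConfig | None = None) -> None:
        self.data = data
        self.shift_times = (tuple(float(t) for t in shift_times)
                            if shift_times else ())
        self.priors = priors or PriorConfig()

    @property
    def n_frames(self) -> int:
        return len(self.shift_times) + 1

    @classmethod
    def from_occurrences(cls, occurrences: Sequence[FossilOccurrence],
                         present: Sequence[PresentRange],
                         bin_size: float,
                         root_age: float | None = None,
                         shift_times: Sequence[float] | None = None,
                         priors: PriorConfig | None = None,
                         age_seed: int | np.random.Generator = 0,
                         ) -> "DESModel":
        """Build the model from dated occurrences and present-day ranges.

        Occurrences without a point age are resampled uniformly within
        their stratigraphic range (deterministic given ``age_seed``).
        ``root_age`` defaults to the oldest point age, rounded up to a
        bin edge.
        """
        if any(o.point_age is None for o in occurrences):
            occurrences = assign_point_ages(list(occurrences), age_seed)
        oldest = max(o.point_age for o in occurrences)
        grid = build_time_grid(root_age if root_age is not None else oldest,
                               bin_size)
        matrix = code_ranges(list(occurrences), list(present), grid)
        return cls(matrix, shift_times=shift_times, priors=priors)

    @classmethod
    def from_tsv(cls, occurrence_path: str | Path,
                 present_path: str | Path, bin_size: float,
                 area_map: dict[str, str] | None = None,
                 **kwargs) -> "DESModel":
        return cls.from_occurrences(
            read_occurrences(occurrence_path, area_map=area_map),
            read_present_ranges(present_path), bin_size, **kwargs)

    def loglike(self, params: DESParameters) -> float:
        """DES log-likelihood of the data at a given parameter set."""
        return dataset_log_likelihood(self.data, params)

    def fit(self, chain: ChainConfig | None = None,
            seed: int | None = None, **chain_kwargs) -> "DESResults":
        """Sample the posterior by MCMC and wrap it in a results object."""
        if chain is None:
            if seed is not None:
                chain_kwargs.setdefault("seed", seed)
            chain = ChainConfig(**chain_kwargs)
        samples = run_mcmc(self.data, shift_times=self.shift_times or None,
                           priors=self.priors, chain=chain)
        return DESResults(self, samples, chain)

    def marginal_likelihood(self, chain: ChainConfig | None = None,
                            betas: np.ndarray | None = None,
                            ) -> tuple[float, pd.DataFrame]:
        """Thermodynamic-integration marginal log-likelihood and path."""
        return marginal_log_likelihood(
            self.data, shift_times=self.shift_times or None,
            priors=self.priors, chain=chain, betas=betas)


class DESResults:
    """Posterior sample of a DES analysis with summaries.

    ``samples`` holds the full chain log; ``posterior`` the post-burn-in
    draws.  Point estimates are posterior modes (MAP proxy); intervals
    are 95% HPDs.
    """

    def __init__(self, model: DESModel, samples: pd.DataFrame,
                 chain: ChainConfig) -> None:
        self.model = model
        self.samples = samples
        self.chain = chain

    @property
    def param_names(self) -> list[str]:
        names = param_columns(self.model.n_frames)
        return [n.replace("s_", "q_") for n in names] + ["g"]

    @property
    def posterior(self) -> pd.DataFrame:
        return self.samples[self.samples["iteration"] > self.chain.burn_in]

    @classmethod
    def pooled(cls, results: Sequence["DESResults"]) -> "DESResults":
        """Combine age-resampling replicates into one posterior pool."""
        if not results:
            raise ValueError("no results to pool")
        pooled = combine_replicates([r.posterior for r in results])
        out = cls(results[0].model, pooled, results[0].chain)
        # pooled draws are already post burn-in
        object.__setattr__(out, "_pooled", True)
        return out

    @property
    def map_estimates(self) -> pd.Series:
        post = self._draws()
        return pd.Series({p: map_estimate(post[p].to_numpy())
                          for p in self.param_names})

    def hpd(self, mass: float = 0.95) -> pd.DataFrame:
        post = self._draws()
        rows = {p: hpd_interval(post[p].to_numpy(), mass)
                for p in self.param_names}
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def _draws(self) -> pd.DataFrame:
        if getattr(self, "_pooled", False):
            return self.samples
        return self.posterior

    def rate_asymmetries(self, mass: float = 0.95) -> pd.DataFrame:
        """Between-area asymmetry tests per frame: a pair of rates is
        credibly asymmetric when 0 falls outside the HPD of the
        per-draw difference of their posterior samples."""
        post = self._draws()
        pairs = [("d_AB", "d_BA"), ("e_A", "e_B"), ("q_A", "q_B")]
        rows = []
        for f in range(self.model.n_frames):
            suffix = "" if self.model.n_frames == 1 else f"_f{f}"
            for left, right in pairs:
                sig, (low, high) = asymmetry_significant(
                    post[left + suffix].to_numpy(),
                    post[right + suffix].to_numpy(), mass)
                rows.append({"frame": f, "pair": f"{left}-{right}",
                             "hpd_lower": low, "hpd_upper": high,
                             "significant": sig})
        return pd.DataFrame(rows)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        """MAP, posterior median, HPD bounds and ESS per parameter."""
        post = self._draws()
        rows = []
        for p in self.param_names:
            draws = post[p].to_numpy()
            low, high = hpd_interval(draws, mass)
            rows.append({
                "parameter": p,
                "map": map_estimate(draws),
                "median": float(np.median(draws)),
                f"hpd_{mass:.0%}_lower": low,
                f"hpd_{mass:.0%}_upper": high,
                "ess": effective_sample_size(draws),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def __str__(self) -> str:
        header = (f"DES model: {self.model.data.n_taxa} taxa, "
                  f"{self.model.data.grid.n_bins} bins of "
                  f"{self.model.data.grid.bin_size:g} Myr, "
                  f"{self.model.n_frames} time frame(s)")
        return header + "\n" + self.summary().to_string(
            float_format=lambda v: f"{v:.4f}")

    def to_tsv(self, path: str | Path) -> None:
        """Write the chain log (17 significant digits, round-trippable)."""
        self.samples.to_csv(path, sep="\t", index=False,
                            float_format="%.17g")
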