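# fossildes

Bayesian inference of dispersal, local-extinction and fossil-sampling
rates from fossil occurrence data — the dispersal–extinction–sampling
(DES) approach to historical biogeography, for people who have dated
fossil occurrences in two regions but no phylogeny.

## The problem and the model

Phylogeny-based biogeography estimates how geographic ranges evolve
from the distribution of *extant* taxa, which is blind to extinct
lineages and biased by extinction and asymmetric dispersal.  Fossils
record where lineages actually were — but with gaps, because sampling
is incomplete.  `fossildes` models both processes at once, for a system
of two discrete areas A and B:

- The true range of each lineage follows a continuous-time Markov
  chain on {∅, A, B, AB} with dispersal rates d_AB, d_BA (range
  expansion) and local-extinction rates e_A, e_B (range contraction);
  ∅ is absorbing (global extinction).  Transition probabilities over a
  time step Δt are exp(QΔt).
- Fossil sampling in each area is a Poisson process with preservation
  rate q_A or q_B (occurrences per lineage per Myr).  A lineage present
  throughout a time bin of length Δt leaves no record with the
  false-absence probability s = exp(−qΔt), so observed absences may be
  real or sampling gaps — the model tells them apart.

Occurrences are coded into equal time bins as per-bin presence sets;
each lineage contributes a pruning (hidden-Markov) likelihood from the
present back to its first appearance.  Inference is MCMC with an
exponential prior on the rates whose rate parameter g carries a gamma
hyper-prior (updated by a conjugate Gibbs step), and a flat prior on
each s.  Rates may shift at user-fixed times (a time-stratified model
with one rate set per frame); competing models are compared with Bayes
factors from thermodynamic-integration marginal likelihoods.  Point
estimates are posterior modes (MAP proxy) with 95% highest-posterior-
density intervals; dating uncertainty is handled by resampling
occurrence ages within their stratigraphic ranges and pooling
replicate posteriors.

A full account of the model, priors, algorithms and their validation
is in `docs/methods.md`.

## Worked example

Simulate a dataset under known rates, then re-estimate them:

```python
from fossildes import DESModel, SimulationConfig, simulate_dataset

data = simulate_dataset(SimulationConfig(seed=3))
print({k: round(v, 3) for k, v in data.params.as_dict().items()})
# {'d_AB': 0.035, 'd_BA': 0.079, 'e_A': 0.242, 'e_B': 0.179,
#  'q_A': 0.139, 'q_B': 0.461}

model = DESModel(data.matrix)          # constant-rate, 2.5 Myr bins
result = model.fit(seed=1)             # 26 000 MCMC iterations
print(result.map_estimates.round(3).to_dict())
# {'d_AB': 0.002, 'd_BA': 0.049, 'e_A': 0.21, 'e_B': 0.174,
#  'q_A': 0.148, 'q_B': 0.359, 'g': 3.421}
```

The extinction rates (true 0.242/0.179, estimated 0.21/0.174) and the
preservation rates (true 0.139/0.461, estimated 0.148/0.359) are
recovered well from this single 76-taxon dataset; the dispersal rates
are the hardest parameters and carry the widest intervals —
`result.summary()` prints MAP, median, HPD bounds and effective sample
sizes per parameter, and `result.rate_asymmetries()` tests whether
paired rates differ credibly between areas.

Real data enter as TSV files (one row per occurrence: taxon, area,
min_age, max_age; one row per taxon: present-day range code 0–3),
either through `DESModel.from_tsv(...)` or the command line:

```sh
fossildes infer --occurrences occ.tsv --present ranges.tsv \
    --bin-size 2.5 --shift-times 50,32,14 --replicates 100 \
    --seed 1 --out-dir run/
fossildes summarize --logs run/replicate_000.log.tsv --out-dir tables/
```

`fossildes simulate`, `code` and `marglik` cover dataset generation,
occurrence binning and marginal-likelihood model comparison.

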