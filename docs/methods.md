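# Methods

## The model

`fossildes` estimates the dynamics of geographic range evolution for a
set of lineages observed only through dated fossil occurrences in two
discrete areas, A and B.  The latent range of each lineage is a
continuous-time Markov chain on the state space (∅, A, B, AB): a
lineage in one area can expand into the other (dispersal, rates d_AB
and d_BA, events per lineage per Myr) or disappear from an area it
occupies (local extinction, rates e_A and e_B); loss of the last area
is global extinction, and ∅ is absorbing.  The generator has no direct
A↔B jump and no simultaneous loss of both areas:

```
        ∅         A          B          AB
  ∅     0         0          0          0
  A     e_A    −(e_A+d_AB)   0          d_AB
  B     e_B       0       −(e_B+d_BA)   d_BA
  AB    0         e_B        e_A     −(e_A+e_B)
```

Fossil sampling in each area is an independent homogeneous Poisson
process with area-specific preservation rate q (expected occurrences
per lineage per Myr) over exactly the time the lineage occupies that
area.  Time is discretised into uniform bins of Δt Myr; the observed
datum per lineage and bin is the set of areas with at least one
occurrence, with a pseudo-absence code (∅̄) for bins without records.
A lineage present in an area throughout a bin leaves no record there
with the false-absence probability s = exp(−qΔt).

### Likelihood

Each lineage contributes a hidden-Markov-style pruning likelihood,
computed backwards from the present (where ranges of extant taxa are
known exactly, and extinct taxa are in ∅) to the lineage's first
appearance (its oldest occurrence).  Per bin the conditional likelihood
vector is propagated through exp(QΔt) and multiplied element-wise by
the probability of the bin's observation given each true range:
observed presences must be contained in the true range; a sampled
presence contributes 1−s, an occupied but unsampled area contributes s,
and a truly absent area contributes 1 for its absence.  At the first
appearance the recursion closes with a *normalised ancestral-state
prior*: the probability of each true range given the range observed
there under the preservation process (e.g. an observed {A} is truly
{A} with probability 1−s_B and truly {A, B} with probability s_B).
Normalisation matters: closing with an improper sum over ancestral
states instead lets the likelihood grow by up to ln 4 per lineage
whenever several ancestral states can reproduce the data, which at
fine bins creates a spurious dominant mode with runaway rates (rapid
per-bin range switching masquerading as near-perfect sampling); with
the normalised prior that mode loses to the generating parameters.
Lineages are independent, so the dataset log-likelihood is the sum
over lineages.
The time-stratified variant assigns an independent rate set (four
anagenetic rates and two preservation rates) to each user-fixed time
frame; frame boundaries must coincide with bin edges (user shift times
are snapped to the nearest edge with a warning).

A note on the observation weighting.  The model's interpretive table of
"true range given observed range" (exposed as
`observed_state_weights`, columns summing to one, e.g. observed {A} is
truly {A} with probability 1−s_B and truly {A,B} with probability s_B)
is *not* usable as the per-bin likelihood factor: multiplying by that
table makes the likelihood improve without bound as the two s
parameters approach opposite corners of [0,1]², where every bin's
weight collapses to 1 on one compatible state and the data cease to
constrain preservation at all.  The recursion therefore uses the
generative observation probabilities P(observation | true range)
(`emission_probabilities`), under which all six rates are identifiable;
the interpretive table is kept for reporting and interoperability.

### Priors and sampling

Each dispersal and extinction rate has an exponential prior Exp(g)
whose rate g is itself given a Gamma(a, b) hyper-prior (defaults
a = b = 1, weakly informative; g is shared across time frames).  The
preservation parameters are proposed on the s scale with a flat
Beta(1, 1) prior on [0, 1]; reported preservation rates are
q = −ln(s)/Δt, so the induced prior on q is exponential with rate Δt.
Posterior sampling is block Metropolis–Hastings: per iteration one
uniformly chosen block is updated — a frame's four rates (independent
multiplier proposals, window 2·ln 1.2, Hastings ratio = product of
multipliers), a frame's two s values (uniform sliding window of width
0.2 reflected at 0 and 1, symmetric), or g (a direct conjugate Gibbs
draw from Gamma(a + n, b + Σx), with n the number of dispersal and
extinction parameters and x their current values).  Defaults give
roughly 20–50% acceptance on the simulation study; both windows are
configurable.  A chain of 26 000 iterations sampled every 10 with the
first 6 000 iterations discarded is the default protocol.  All
randomness flows from a single root seed through separate spawned
streams (initialisation, kernel), so runs are exactly reproducible.

The likelihood of an impossible configuration is −∞ rather than an
error, so the sampler simply rejects such proposals; per-lineage
vectors are rescaled each step with an accumulated log constant to
avoid underflow.  Initial parameter values are redrawn (up to 50 times)
until the likelihood is finite.

### Model comparison

Marginal likelihoods are estimated by thermodynamic integration: one
power-posterior chain per tempering value β (the likelihood enters the
acceptance ratio as likelihood^β), with the default 10 β values taken
as quantiles of Beta(0.3, 1) (clustered near the prior), each chain
warm-started from the previous β's end state and its first 10% of
retained samples discarded.  The per-β mean log-likelihood is
integrated over β by the trapezoidal rule; log Bayes factors are
differences of marginal log-likelihoods.  The quadrature and chain
machinery are validated against a conjugate toy target with analytic
evidence.

### Summaries

Rate posteriors press against the hard boundary at zero and are
strongly right-skewed, so point estimates use the mode of a 100-bin
histogram of the draws (a MAP proxy) rather than the mean; intervals
are 95% highest-posterior-density intervals computed by the
sliding-window-over-sorted-draws algorithm.  Between-area asymmetry of
a rate pair is called credible when 0 falls outside the 95% HPD of the
per-draw differences.  Stratigraphic age uncertainty is handled by
resampling each occurrence's age uniformly within its min/max range,
re-coding, re-running the chain, and pooling the post-burn-in draws
across replicates (default protocol: 100 replicates).

## Synthetic data

The simulator generates datasets under exactly the model assumptions:
Gillespie simulation of the range CTMC per lineage, then Poisson
fossil sampling over the occupancy intervals, then binned coding.
Study conditions (defaults): 50 Myr span; origination times uniform
over the span (no birth process — lineages are independent and need
not form a clade); initial range uniform on {A, B}; per dataset,
d_AB, d_BA, e_A, e_B ~ U(0.01, 0.3), q_A, q_B ~ U(0.05, 1) (one
expected occurrence per lineage per 20 Myr up to one per Myr), and
N ~ U{20..200} lineages.  Lineages never sampled in the fossil record
are dropped (they have no first appearance).  Occurrences are
exact-dated; an optional blur widens them into stratigraphic-style
ranges to exercise the age-resampling path.

What the simulator does *not* emulate: phylogenetic correlation among
lineages, rate heterogeneity across lineages or through time within a
frame, spatially structured sampling within an area, and taxonomic
error.  Passing recovery tests therefore show that the estimator is
correct under its own assumptions, not that those assumptions hold for
any particular fossil compilation.

## Validation experiment and problem sizes

The accuracy harness simulates datasets, runs the full-length chain on
each, takes histogram-mode MAP estimates, and aggregates mean absolute
percentage errors (MAPE, |estimate − truth|/truth) by parameter group
(dispersal, extinction, preservation, all six), plus HPD width relative
to the true value as the precision metric.  The package's standing
experiment uses 100 datasets at bin sizes 5 and 2.5 Myr and 50 at 1 and
0.5 Myr, full 26 000-iteration chains throughout — enough replication
for stable group-level MAPE while keeping a complete run in minutes on
one core.  Observed behaviour: overall MAPE near 0.3 at every bin
size and best at 2.5 Myr; dispersal rates are the hardest group
(~0.42–0.56) and preservation the easiest at fine bins (~0.12–0.15);
coarsening to 5 Myr bins degrades the preservation rates most (to
~0.22: per-bin sampling probabilities saturate towards 1, so the data
say little about q beyond "large"); HPD coverage of the generating
values is close to nominal (~0.92 at 2.5 Myr).  These are the
quantities `scripts/acceptance.py` recomputes.

## Numerical choices

- Matrix exponentials: `scipy.linalg.expm` in the reference path; the
  compiled MCMC kernel uses a 4×4 scaling-and-squaring Taylor
  exponential verified against scipy to 1e−12.
- Bins are half-open [older, younger): an occurrence exactly on an edge
  belongs to the younger bin; the present (age 0) is the closed
  terminal point.  The grid root is the oldest point age rounded up to
  a bin edge unless overridden.
- Histogram-mode ties resolve to the lowest-index bin (numpy argmax);
  the posterior median is reported alongside as a robustness check.
- HPD uses k = ceil(mass·n) order statistics; zero-width intervals are
  legal (point-mass samples).
- Degenerate inputs: taxa without occurrences are excluded at coding;
  datasets where no lineage is sampled are re-drawn (capped); chains
  that cannot find a finite starting likelihood raise after 50 tries.

## Known limitations

- Two areas only; no cladogenetic range inheritance, no ancestral-range
  reconstruction, no origination model.
- Frame shift times are user-fixed; there is no search over frame
  structure.
- ESS reporting is the only convergence diagnostic; inspect traces for
  serious work.
- The MAP proxy depends on the histogram bin count (default 100) when
  posteriors are very diffuse.
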