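# Methods

`baculorate` estimates the mutation rate per nucleotide per strand-copying
event (s/n/r) of a large double-stranded DNA virus from deep-sequencing
variant calls gathered over a serial-passage experiment in insect larvae.
The motivating system is an alphabaculovirus carrying an 11,646-bp
non-functional ("neutral") genomic insert, passaged five times through five
*Spodoptera exigua* larvae per lineage and finally amplified in 100 larvae.
This note records the model, its assumptions, the parameter choices, the
numerical decisions, and what the synthetic-data tests do and do not show.

## The neutral-evolution passage model

The genomic region of interest is a vector of `g` positions; state is the
total frequency `f_i ∈ [0, 1]` of mutated bases at position `i`.  Mutant
base identity is not tracked and reversions are not modelled: in the regime
of interest mutations are rare and a reversion reaching a detectable
frequency is vanishingly unlikely.  All mutations are assumed strictly
neutral, so every change in `f` is due to de novo mutation or drift.

One host infection consists of:

1. **Founding.**  The number of infecting occlusion-derived virions (ODVs)
   is drawn from a zero-truncated Poisson with rate `λ/ζ`; each ODV carries
   a zero-truncated Poisson (rate `ζ`) number of nucleocapsids, i.e. genome
   copies.  Truncation reflects that an uninfected or empty host
   contributes nothing; at the high doses modelled the truncation is a
   negligible correction.  We read `ζ` and `λ/ζ` as the *rate* parameters
   of the truncated distributions (so the realized capsid mean is
   `ζ/(1−e^(−ζ))`, e.g. 3.80 at `ζ = 3.71`), and we use the *realized*
   founder total — not the nominal `λ` — as the trial count of the
   founding binomial below.  The expected founder count is then ≈47.2
   rather than 46; we accept this small excess for internal consistency
   between the stochastic founder draw and the bottleneck sampling.
2. **Bottleneck.**  Mutant copies at each position are sampled as
   `Binomial(n_founders, f_i)`, independently across positions.
3. **Within-host expansion.**  Each round of replication multiplies the
   population by `1 + ρ`, where `ρ` is the number of new copies per
   template per round: `ρ = 1` is geometric (fission-like) growth, large
   `ρ` approaches "stamping-machine" replication.  Growth is capped by an
   expansion to exactly the carrying capacity `κ` in the final round.  In
   each round the `N_t − N_{t−1}` new copies inherit mutations from their
   templates, and the unmutated new copies at a position,
   `η_i = (N_t − N_{t−1})(1 − f_i)`, each mutate with probability `μ`:
   `x_i ~ Binomial(round(η_i), μ)` and `f_i ← f_i + x_i/N_t`.  (For an
   uncapped round this is algebraically the update
   `f ← (N_{t−1} f (1+ρ) + x)/N_t`; writing it additively keeps `f ≤ 1`
   exact in the capped round too.)  Once `N_t · φ > 1/μ` mutation switches
   to its deterministic expectation `x_i = η_i μ` (fractional mass
   allowed); at that point a position receives hundreds of expected mutant
   lineages per round and the binomial noise is immaterial, while the
   computation becomes pure vector arithmetic.

A passage infects several larvae in parallel with the same inoculum and
pools progeny by the unweighted per-position mean frequency.  The full
experiment is five such passages followed by one amplification passage in
100 larvae with per-host capacity `2κ` (the later-instar hosts yield about
twice the virus).  Detection applies a strict threshold: position `i`
counts as a detectable mutation when `f_i > τ`.

Default constants (changeable via `SimulationParams`): `μ = 1e-7`,
`ρ = 10`, `λ = 46` (from dose–mortality: `10 × −ln(1−0.99)`), `ζ = 3.71`,
`κ = 5.05e8` (OB yield 1.33e6/larva × 100 ODV/OB × 3.8 capsids/ODV),
`σ = 1001`, `φ = 1e4`, `g = 11,646`.

### Performance notes

Population sizes are integers, rounded each round.  In the stochastic
regime almost all positions have `f_i = 0` and share the same `η`; their
mutant total is drawn as one `Binomial(g₀·η₀, μ)` and scattered uniformly,
which is distributionally identical to per-position draws (a sum of iid
binomials with equal trial counts) and keeps a full five-passage experiment
at the study's scale under 0.1 s.  Seeding uses NumPy `SeedSequence`
spawning — one root seed, independent child streams per grid point,
simulation, passage and larva — so runs are reproducible and
order-independent.

## Pseudo-likelihood inference

The data reduce to one detectable-mutation count per evolved lineage.  For
each candidate rate on a log10 grid the experiment is simulated `n_sims`
times, giving `β_j`, the probability that a replicate shows `j − 1`
detectable positions (categories `j = 1..σ`; a parameter combination in
which any simulation exceeds `σ − 1` detectable positions is excluded).
The observed histogram `q_j` over the same categories is scored by the
multinomial log-probability `log[q!/∏q_j! · ∏β_j^{q_j}]`, and the estimate
is the grid argmax.  Because `β` is a Monte-Carlo estimate, observed but
unsimulated categories would give `−∞`; we smooth additively with
`ε = 1/n_sims` per category and renormalize.  Exact ties in the profile are
broken deterministically toward the grid point nearest the centre of the
tied set.  Confidence intervals refit bootstrap resamples of the lineage
count list against the same simulated `β` table (the table depends only on
parameters, not on data) and take 2.5/97.5 percentiles.

The estimator is exposed as a scikit-learn `BaseEstimator`
(`MutationRateEstimator`): `fit(counts)` sets `mu_hat_` and a full
`result_` profile, `get_params`/`set_params` work with sklearn model
selection, and a precomputed prediction table can be passed to `fit` so
several datasets share one simulation run.

Full-protocol defaults are a grid from −10 to −5 in steps of 0.1 with 1000
simulations per point and 1000 bootstrap resamples.  The reproduction
scripts and tests use a reduced protocol — grid −9 to −5.5 in steps of 0.5,
150 simulations per point — which separates the candidate rates cleanly
(mean simulated counts ~0.7 / 2.2 / 6.4 at −7.5 / −7 / −6.5) at a fraction
of the cost; these problem sizes are the package's documented reduced
configuration.

`ClassicRateEstimator` implements the clone-sequencing estimator
`μ = m_s/(T_s · c · α)` adapted to pooled deep sequencing: `m_s` is the
summed frequency of mutations above `τ` (summing frequencies over all
sites also removes the per-site factor 3), `T_s` the region length times
the number of replicate lineages, `c = θ·ln(κ/λ)/ln(1+ρ)` strand-copying
generations over `θ` passages, and `α = 1` because only neutral-region
mutations are counted.  Its `predict(μ)` returns the expected `m_s = μT_s c`.
This estimator ignores the detection threshold and therefore
underestimates the rate; it serves as a cross-check, not the headline
method.

`demography_grid` explores founding (`λ`) and final (`κ`) population sizes
with a reduced single-insect, five-passage design and paired random seeds
across grid cells.  Detectable-mutation accumulation rises with `κ` but is
*non-monotone* in `λ`: a mutation becomes detectable when it is sampled
into a founding population of size about `1/τ` or smaller, so intermediate
bottlenecks (near `λ ≈ 1/τ`) maximize detectable counts, while very wide
bottlenecks preserve mutations at undetectably low frequencies.

## Variant filtering

Filters reproduce the mutation-inclusion rules of the emulated analysis,
operating on called-variant tables (the upstream read processing and
variant calling are out of scope):

- base quality: forward–reverse balance > 0.05, read count > 10 (both
  strict), SNV only, frequency at or above the 0.5% calling floor;
- coverage extremes: per lineage, positions in the upper and lower 1% of
  the coverage ranking are excluded (average-rank ties; a fully tied track
  excludes nothing);
- ancestral subtraction: identities (position, ref, alt) called in the
  ancestor are not de novo and are removed;
- recurrence (`ψ`): an identity observed in more than `ψ` lineages is
  presumed a sequencing/read-mapping artifact and removed from all
  lineages (`ψ = 1` keeps only lineage-unique mutations).

Base, coverage and ancestral filters commute; the `ψ` filter is applied
last, after ancestral subtraction.  Counts are monotone non-increasing in
`τ` and non-decreasing in `ψ`.  Coordinates are 1-based and intervals
closed throughout.

## Selection and spectrum analyses

SNVs are classified synonymous / nonsynonymous (codon translation with
strand and frame), intergenic, or neutral-insert.  Site totals use
Nei–Gojobori-style counting with no transition/transversion bias: each of
a codon's nine single-nucleotide changes is weighted equally, and changes
to stop codons count as nonsynonymous.  Class rates are mutation counts
divided by site totals; dN/dS and dI/dS are ratios against the synonymous
rate, with percentile bootstrap CIs over mutation records and a one-sample
t-test of per-lineage log10 ratios against 0.  The test is flagged not
performable when any lineage lacks mutations in either class, and ratios
are flagged undefined when dS = 0.  Mutations are counted as unweighted
events above `τ`, not weighted by frequency.  Optional interval masking
accommodates repetitive (hr-like) regions prone to mapping error.

The spectrum summary tallies the 12 substitution types; A↔G and C↔T are
transitions.  Positional clustering uses a two-sided one-sample
Kolmogorov–Smirnov test of region-rescaled positions against uniform.

## Synthetic data

The generator produces a random reference with stop-free CDS intervals,
intergenic gaps and one neutral insert; true mutation frequencies from the
passage simulator; and variant/coverage tables with three noise layers:
artifact variants (rate per site `error_rate`, a `shared_fraction`
recurring in every lineage to emulate reference-tied mapping errors, the
rest lineage-private, frequencies uniform in 0.5–2%), ancestral variants
present in the ancestor and all lineages, and negative-binomial coverage
around 5500× with forced 16-fold outliers at 1% of positions so the
coverage trim is exercised.  A configurable fraction of artifact rows
fails the base quality filters.

What passing synthetic tests show: the filter chain's bookkeeping is exact
(noise-free tables reproduce the simulator's detectable counts; fully
shared artifacts vanish at `ψ = 1`), and the estimator recovers generating
rates in its informative range.  What they do not show: real sequencing
artifacts are not uniform in frequency nor perfectly shared across
lineages, coverage biases correlate with sequence context, and the
reference genome is random rather than viral — so these tests validate the
pipeline's logic, not the error model of any particular instrument.

## Known limitations and open choices

- At rates near 1e-8 and below, a five-lineage experiment is frequently
  all-zero in detectable counts; the likelihood is then maximized at the
  grid floor and bootstrap intervals collapse there.  Point and interval
  estimates at such rates are unreliable at this design size — more
  lineages or longer regions are the remedy, not estimator tuning.
- Whether `β` should be renormalized over all `σ` categories or only
  observed ones after smoothing is a modelling choice; we renormalize over
  all categories.
- The bootstrap unit is the replicate lineage for the model fit and the
  mutation record for the classical estimator and ratio CIs.
- Selection coefficients, recombination, mutant-base identity and
  within-cell infection dynamics are out of scope; the per-cell-infection
  rate parameterization (s/n/c) is not implemented.
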