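# baculorate

Mutation-rate estimation for large double-stranded DNA viruses from
serial-passage deep-sequencing data.

Estimating a viral mutation rate from passage experiments is confounded by
demography: repeated host-to-host bottlenecks and within-host expansion
decide which mutations drift to detectable frequencies, and a naive count
of observed mutations conflates mutation supply with these sampling
effects.  `baculorate` addresses this for viruses like the
alphabaculovirus AcMNPV — a large-genome insect virus passaged through
larvae — by simulating neutral evolution through the full experimental
design and fitting the simulation to the observed data.

The core quantities:

- a stochastic passage model of a neutral region of `g` sites tracking
  per-site mutant frequencies `f_i` through zero-truncated-Poisson founder
  draws, binomial bottlenecks (`Binomial(n_founders, f_i)`), and
  exponential within-host growth `N_t = λ(1+ρ)^t` capped at `κ`, with
  binomial mutation (rate `μ` per site per strand copying) switching to
  its deterministic expectation in large populations;
- a **multinomial pseudo-likelihood** over per-lineage detectable-mutation
  counts: simulated category probabilities `β_j` (a replicate shows `j−1`
  sites with `f_i > τ`) score the observed histogram `q_j`, maximized over
  a log10 `μ` grid, with bootstrap confidence intervals;
- the classical estimator `μ = m_s/(T_s·c·α)` with
  `c = θ·ln(κ/λ)/ln(1+ρ)`, adapted to pooled sequencing by summing mutation
  frequencies;
- the variant-filtering rules (quality, coverage extremes, ancestral
  subtraction, cross-lineage recurrence threshold `ψ`), dN/dS and dI/dS
  with Nei–Gojobori site counting, the transition/transversion spectrum,
  and positional-clustering (Kolmogorov–Smirnov) tests;
- a synthetic-data generator so the entire pipeline runs and is validated
  without any external data.

See `docs/methods.md` for the model in full.

## Worked example

Fit the mutation rate to the per-lineage counts of detectable
neutral-region mutations observed after five passages under the strictest
artifact filtering (each mutation unique to one lineage), using the
reduced grid:

```python
import numpy as np
from baculorate import MutationRateEstimator, ObservedCounts, SimulationParams

observed = ObservedCounts(per_replicate=(2, 2, 1, 1, 2),
                          region_length=11646, tau=0.005)
est = MutationRateEstimator(
    grid=np.arange(-9.0, -5.4, 0.5),          # log10 mu
    params=SimulationParams(rho=10.0),         # stamping-machine replication
    tau=0.005, n_sims=150, seed=1,
)
est.fit(observed)
print(f"mu_hat = {est.mu_hat_:.3g} s/n/r")
```

```
mu_hat = 1e-07 s/n/r
```

The estimate, 1×10⁻⁷ substitutions per nucleotide per strand copying, is
the rate whose simulated distribution of detectable-mutation counts best
explains seeing 1–2 mutations per lineage in an 11,646-bp neutral region.
Refitting the counts obtained under the laxest filtering (9, 8, 4, 7, 9)
raises the estimate to ~3×10⁻⁷, showing how artifact-filtering stringency
propagates into the rate.  For comparison, the classical estimator at the
same demography predicts only `m_s = μ·T_s·c ≈ 0.197` summed mutation
frequency at μ=1e-7 (`ClassicRateEstimator(rho=10).predict(1e-7)`),
because it ignores the detection threshold.

The same machinery is scriptable from the shell:

```sh
baculorate synth --seed 2 --outdir data/          # synthetic dataset
baculorate filter --variants data/variants.tsv --ancestor data/ancestor.tsv \
    --coverage data/coverage.tsv --annotation data/annotation.tsv \
    --reference data/reference.fa --region neutral-insert \
    --tau 0.005 --psi 1 --out data/filtered.tsv
baculorate fit --counts data/filtered.counts.tsv --n-sims 150 \
    --grid-min -9 --grid-max -5.5 --grid-step 0.5 --seed 1 --out fit.json
```

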