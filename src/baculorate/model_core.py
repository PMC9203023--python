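"""Stochastic simulator of neutral mutation accumulation in a serially
passaged virus population.

The model tracks, for a genomic region of ``g`` positions, the total
frequency ``f_i`` of mutated bases at each position.  A passage through one
insect host consists of

1. a founding bottleneck: the number of infecting occlusion-derived virions
   (ODVs) is drawn from a zero-truncated Poisson with rate ``lam/zeta`` and
   each ODV carries a zero-truncated Poisson (rate ``zeta``) number of
   nucleocapsids, i.e. genome copies;
2. binomial sampling of mutant genomes at every position over the realized
   founder count;
3. exponential within-host expansion with replication factor ``rho`` per
   round (``N_t = N_{t-1}(1+rho)``, capped by an expansion to exactly
   ``kappa`` in the final round), during which each newly copied genome
   acquires a mutation at each position with probability ``mu``.  Mutation is
   simulated binomially while populations are small and switched to its
   deterministic expectation once ``N_t * phi > 1/mu``.

Mutations are neutral, reversions are not modelled, and the identity of the
mutant base is not tracked.  Progeny of the hosts infected in parallel within
one passage are pooled by averaging frequencies per position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SimulationParams",
    "ExperimentDesign",
    "FounderSample",
    "ReplicationState",
    "lambda_from_mortality",
    "ztpois_mean",
    "ztpois",
    "draw_founders",
    "bottleneck_sample",
    "mutation_step",
    "within_host_replication",
    "simulate_passage",
    "simulate_experiment",
    "count_detectable",
]


@dataclass(frozen=True)
class SimulationParams:
    """Demographic and mutational constants of the passage model.

    Parameters
    ----------
    mu : float
        Mutation rate per site per strand copying (s/n/r).
    rho : float
        Replication-mode factor: new copies per template per round.
        1 is geometric growth, large values a "stamping machine".
    lam : float
        Nominal founding population size per larva (genomes).
    zeta : float
        Rate parameter of the zero-truncated Poisson distribution of
        nucleocapsids per ODV.
    kappa : float
        Final within-host population size (genomes).
    sigma : int
        One more than the maximum number of mutated positions tracked
        by downstream inference.
    phi : float
        Constant of the stochastic-to-deterministic mutation switch:
        deterministic once ``N_t * phi > 1/mu``.
    g : int
        Length in bases of the genomic region simulated.
    """

    mu: float = 1e-7
    rho: float = 10.0
    lam: float = 46.0
    zeta: float = 3.71
    kappa: float = 5.05e8
    sigma: int = 1001
    phi: float = 1e4
    g: int = 11646

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.rho < 1:
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if self.zeta <= 0:
            raise ValueError(f"zeta must be > 0, got {self.zeta}")
        if self.kappa <= self.lam:
            raise ValueError("kappa must exceed lam")
        if self.sigma < 2:
            raise ValueError(f"sigma must be >= 2, got {self.sigma}")
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")
        if self.g < 1:
            raise ValueError(f"g must be >= 1, got {self.g}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the serial-passage experiment.

    Five passages through five larvae each, followed by a final
    amplification in 100 larvae whose per-host yield is doubled.
    """

    n_passages: int = 5
    larvae_per_passage: int = 5
    final_larvae: int = 100
    final_capacity_factor: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_passages", "larvae_per_passage", "final_larvae"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.final_capacity_factor <= 0:
            raise ValueError("final_capacity_factor must be > 0")


@dataclass
class FounderSample:
    """Realized founding population of one host."""

    n_odv: int
    capsids_per_odv: np.ndarray
    n_founders: int


@dataclass
class ReplicationState:
    """Within-host population state at one replication round."""

    n_genomes: int
    generation: int
    freqs: np.ndarray = field(repr=False)


def lambda_from_mortality(dose_multiple: float, mortality: float) -> float:
    """Founding population size implied by host mortality at a given dose.

    Under single-hit dose-response, the number of founders at the reference
    dose is ``-ln(1 - mortality)``; a ``dose_multiple``-fold dose scales it
    linearly.  E.g. 10x the LD99 dose gives ``10 * -ln(0.01) ~ 46`` founders.
    """
    if not 0.0 < mortality < 1.0:
        raise ValueError(f"mortality must be in (0, 1), got {mortality}")
    if dose_multiple <= 0:
        raise ValueError(f"dose_multiple must be > 0, got {dose_multiple}")
    return dose_multiple * -math.log1p(-mortality)


def ztpois_mean(rate: float) -> float:
    """Mean of the zero-truncated Poisson distribution with the given rate.

    Equals ``rate / (1 - exp(-rate))``; at rate 3.71 this is 3.80.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    return rate / -math.expm1(-rate)


def ztpois(rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` zero-truncated Poisson variates (all >= 1).

    Inverse-CDF sampling: uniforms are mapped into the untruncated CDF above
    the zero-class mass, so no rejection loop is needed even at small rates.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    p0 = math.exp(-rate)
    u = rng.uniform(p0, 1.0, size=n)
    draws = stats.poisson.ppf(u, rate).astype(np.int64)
    # ppf can land on 0 for u numerically equal to p0
    return np.maximum(draws, 1)


def draw_founders(params: SimulationParams, rng: np.random.Generator) -> FounderSample:
    """Draw the founding population of one host.

    The ODV count follows a zero-truncated Poisson with rate ``lam/zeta``
    and each ODV's nucleocapsid count one with rate ``zeta``; founders are
    the total genome copies.
    """
    n_odv = int(ztpois(params.lam / params.zeta, 1, rng)[0])
    capsids = ztpois(params.zeta, n_odv, rng)
    return FounderSample(n_odv=n_odv, capsids_per_odv=capsids, n_founders=int(capsids.sum()))


def bottleneck_sample(
    freqs: np.ndarray, n_founders: int, rng: np.random.Generator
) -> np.ndarray:
    """Binomial founding bottleneck.

    The mutant genome count at each position is ``Binomial(n_founders, f_i)``,
    independently across positions; returned as frequencies among founders.
    """
    if n_founders < 1:
        raise ValueError(f"n_founders must be >= 1, got {n_founders}")
    freqs = np.asarray(freqs, dtype=float)
    out = np.zeros_like(freqs)
    nz = np.flatnonzero(freqs)
    if nz.size:
        out[nz] = rng.binomial(n_founders, freqs[nz]) / n_founders
    return out


def _next_population(n_prev: int, params: SimulationParams) -> int:
    n_next = int(round(n_prev * (1.0 + params.rho)))
    return min(n_next, int(round(params.kappa)))


def _mutate_round(
    freqs: np.ndarray,
    n_prev: int,
    n_next: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One replication round: copy, then mutate the unmutated new copies.

    New copies this round number ``N_t - N_{t-1}`` (``rho * N_{t-1}`` except
    in the capped final round).  Copying preserves frequencies; per position
    the unmutated templates among the new copies are
    ``eta_i = (N_t - N_{t-1}) * (1 - f_i)`` and the number of new mutants is
    ``Binomial(eta_i, mu)`` while the population is small, or its expectation
    ``eta_i * mu`` once ``N_t * phi > 1/mu``.  The frequency update is
    ``f_i <- f_i + x_i / N_t``.
    """
    mu = params.mu
    if mu == 0.0:
        return freqs
    new_copies = n_next - n_prev
    if new_copies <= 0:
        return freqs
    eta = new_copies * (1.0 - freqs)
    if n_next * params.phi > 1.0 / mu:
        x = eta * mu
        return freqs + x / n_next
    # stochastic regime: aggregate the (equal-eta) zero-frequency positions
    out = freqs.copy()
    nz = np.flatnonzero(freqs)
    zero_count = freqs.size - nz.size
    if zero_count:
        total = rng.binomial(int(round(new_copies)) * zero_count, mu)
        if total:
            zeros = np.flatnonzero(freqs == 0.0)
            hits = rng.integers(0, zero_count, size=total)
            np.add.at(out, zeros[hits], 1.0 / n_next)
    if nz.size:
        x = rng.binomial(np.rint(eta[nz]).astype(np.int64), mu)
        out[nz] += x / n_next
    return np.minimum(out, 1.0)


def mutation_step(
    state: ReplicationState, params: SimulationParams, rng: np.random.Generator
) -> ReplicationState:
    """Advance the within-host population by one replication round."""
    n_next = _next_population(state.n_genomes, params)
    freqs = _mutate_round(state.freqs, state.n_genomes, n_next, params, rng)
    return ReplicationState(n_genomes=n_next, generation=state.generation + 1, freqs=freqs)


def within_host_replication(
    freqs: np.ndarray,
    n_founders: int,
    params: SimulationParams,
    rng: np.random.Generator,
    kappa: float | None = None,
) -> np.ndarray:
    """Expand a founding population to the carrying capacity ``kappa``.

    Repeats :func:`mutation_step` until the population reaches ``kappa``
    (the final round is an expansion to exactly ``kappa``).  ``kappa`` may be
    overridden, e.g. for the doubled-yield final amplification.
    """
    if n_founders < 1:
        raise ValueError("founder count must be >= 1")
    if kappa is not None:
        params = SimulationParams(**{**params.__dict__, "kappa": kappa})
    state = ReplicationState(n_genomes=int(n_founders), generation=0, freqs=np.asarray(freqs, float))
    cap = int(round(params.kappa))
    while state.n_genomes < cap:
        state = mutation_step(state, params, rng)
    return state.freqs


def simulate_passage(
    freqs: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
    n_larvae: int = 5,
    kappa: float | None = None,
) -> np.ndarray:
    """One passage: infect ``n_larvae`` hosts in parallel and pool progeny.

    Each host gets an independent founder draw, bottleneck and within-host
    expansion; pooling takes the unweighted per-position mean frequency.
    """
    pooled = np.zeros(params.g, dtype=float)
    for _ in range(n_larvae):
        founders = draw_founders(params, rng)
        sampled = bottleneck_sample(freqs, founders.n_founders, rng)
        pooled += within_host_replication(sampled, founders.n_founders, params, rng, kappa=kappa)
    return pooled / n_larvae


def simulate_experiment(
    params: SimulationParams,
    design: ExperimentDesign,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate the full serial-passage experiment for one lineage.

    Starts from a mutation-free population, applies ``design.n_passages``
    passages of ``design.larvae_per_passage`` hosts, then a final
    amplification in ``design.final_larvae`` hosts with per-host capacity
    ``final_capacity_factor * kappa``.  Returns the final pooled frequencies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.zeros(params.g, dtype=float)
    for _ in range(design.n_passages):
        freqs = simulate_passage(freqs, params, rng, n_larvae=design.larvae_per_passage)
    freqs = simulate_passage(
        freqs,
        params,
        rng,
        n_larvae=design.final_larvae,
        kappa=design.final_capacity_factor * params.kappa,
    )
    return freqs


def count_detectable(freqs: np.ndarray, tau: float) -> int:
    """Number of positions with mutation frequency strictly above ``tau``."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    return int(np.count_nonzero(np.asarray(freqs) > tau))
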