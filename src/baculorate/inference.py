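"""Mutation-rate inference from per-lineage detectable-mutation counts.

Two estimators are provided, both shaped as scikit-learn estimators:

``MutationRateEstimator``
    Simulation-based multinomial pseudo-likelihood.  For each candidate
    mutation rate on a log10 grid, the passage model is simulated ``n_sims``
    times and the fraction ``beta_j`` of simulations showing exactly ``j-1``
    positions above the detection threshold ``tau`` is recorded.  The
    observed per-lineage counts form a histogram ``q_j`` over the same
    categories, and the fitted rate maximizes the multinomial probability
    of ``q`` under ``beta``.  Confidence intervals come from refitting
    bootstrap resamples of the lineages.

``ClassicRateEstimator``
    The classical clone-sequencing estimator ``mu = m_s / (T_s * c * alpha)``
    adapted to deep-sequencing data: ``m_s`` is the summed frequency of
    observed mutations above ``tau``, ``T_s`` the mutational target size
    (region length x replicates), ``c = theta * ln(kappa/lam) / ln(1+rho)``
    the number of strand-copying generations, and ``alpha = 1`` because only
    neutral-region mutations are counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .model_core import (
    ExperimentDesign,
    SimulationParams,
    count_detectable,
    simulate_experiment,
    simulate_passage,
)

__all__ = [
    "ObservedCounts",
    "PredictedDistribution",
    "FitResult",
    "ClassicEstimate",
    "MutationRateEstimator",
    "ClassicRateEstimator",
    "simulate_predictions",
    "pseudo_loglik",
    "fit_mutation_rate",
    "bootstrap_fit_ci",
    "classic_estimate",
    "classic_generations",
    "demography_grid",
]


@dataclass(frozen=True)
class ObservedCounts:
    """Detectable-mutation counts per evolved lineage."""

    per_replicate: tuple[int, ...]
    region_length: int
    tau: float
    psi: int = 1

    def __post_init__(self) -> None:
        if len(self.per_replicate) == 0:
            raise ValueError("per_replicate must be non-empty")
        if any(c < 0 for c in self.per_replicate):
            raise ValueError("counts must be non-negative")

    def histogram(self, sigma: int) -> np.ndarray:
        """Histogram ``q_j`` over categories j=1..sigma (j-1 mutations)."""
        counts = np.asarray(self.per_replicate)
        if counts.max() > sigma - 1:
            raise ValueError(
                f"observed count {counts.max()} exceeds model support sigma-1={sigma - 1}"
            )
        return np.bincount(counts, minlength=sigma).astype(float)


@dataclass
class PredictedDistribution:
    """Simulated distribution over detectable-mutation categories.

    ``beta[j]`` is the probability that one experimental replicate shows
    exactly ``j`` detectable mutations (category j+1 of sigma).
    """

    beta: np.ndarray
    n_sims: int
    params_used: SimulationParams
    excluded: bool = False


@dataclass
class FitResult:
    mu_hat: float
    grid: np.ndarray
    nll: np.ndarray
    excluded: np.ndarray
    ci95: tuple[float, float] | None = None
    predictions: list[PredictedDistribution] = field(default_factory=list, repr=False)


@dataclass
class ClassicEstimate:
    m_s: float
    T_s: float
    c: float
    alpha: float
    mu_hat: float
    ci95: tuple[float, float] | None = None


def simulate_predictions(
    params: SimulationParams,
    design: ExperimentDesign,
    tau: float,
    n_sims: int,
    seed: int | np.random.SeedSequence,
) -> PredictedDistribution:
    """Estimate ``beta`` by Monte-Carlo simulation of the experiment.

    Runs ``n_sims`` independent experiment simulations and histograms the
    detectable-mutation counts.  If any simulation exceeds ``sigma - 1``
    detectable positions the parameter combination is flagged excluded.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    counts = np.empty(n_sims, dtype=np.int64)
    for k in range(n_sims):
        freqs = simulate_experiment(params, design, np.random.default_rng(children[k]))
        counts[k] = count_detectable(freqs, tau)
    excluded = bool(counts.max() > params.sigma - 1)
    beta = np.zeros(params.sigma)
    if not excluded:
        beta = np.bincount(counts, minlength=params.sigma) / n_sims
    return PredictedDistribution(beta=beta, n_sims=n_sims, params_used=params, excluded=excluded)


def _smooth(beta: np.ndarray, n_sims: int) -> np.ndarray:
    """Additive smoothing so observed-but-unsimulated categories stay finite.

    Uses epsilon = 1/n_sims per category, renormalized.
    """
    eps = 1.0 / n_sims
    counts = beta * n_sims
    return (counts + eps) / (n_sims + beta.size * eps)


def pseudo_loglik(observed: ObservedCounts, pred: PredictedDistribution) -> float:
    """Log multinomial pseudo-likelihood of the observed count histogram."""
    if pred.excluded:
        raise ValueError("predicted distribution is flagged excluded")
    q = observed.histogram(pred.beta.size)
    beta = _smooth(pred.beta, pred.n_sims)
    return float(stats.multinomial.logpmf(q, n=int(q.sum()), p=beta))


def _argmax_with_tie_rule(loglik: np.ndarray, grid: np.ndarray) -> int:
    """Index of the maximum; ties go to the point nearest their centre."""
    best = np.flatnonzero(loglik == loglik.max())
    if best.size == 1:
        return int(best[0])
    centre = grid[best].mean()
    return int(best[np.argmin(np.abs(grid[best] - centre))])


class MutationRateEstimator(BaseEstimator):
    """Simulation-based pseudo-likelihood estimator of the mutation rate.

    Parameters
    ----------
    grid : array-like of float
        log10 mutation rates evaluated (default: -10 to -5, step 0.1, the
        full-protocol grid).
    params : SimulationParams, optional
        Fixed demographic parameters; ``mu`` is overridden per grid point.
    design : ExperimentDesign, optional
        Passage layout.
    tau : float
        Detection threshold applied inside the simulations.
    n_sims : int
        Simulations per grid point (full protocol: 1000).
    n_boot : int
        Bootstrap resamples of the lineages for the 95% CI; 0 disables.
    seed : int
        Root seed; all simulation streams are spawned from it.

    Attributes
    ----------
    mu_hat_ : float
        Maximum-pseudo-likelihood mutation rate (s/n/r).
    result_ : FitResult
        Grid, negative log-likelihood profile, exclusion flags and CI.
    predictions_ : list of PredictedDistribution
        Per-grid-point simulated ``beta`` distributions (reusable for
        refits of other observed datasets under identical parameters).
    """

    def __init__(
        self,
        grid=None,
        params: SimulationParams | None = None,
        design: ExperimentDesign | None = None,
        tau: float = 0.005,
        n_sims: int = 1000,
        n_boot: int = 0,
        seed: int = 0,
    ):
        self.grid = grid
        self.params = params
        self.design = design
        self.tau = tau
        self.n_sims = n_sims
        self.n_boot = n_boot
        self.seed = seed

    def _grid(self) -> np.ndarray:
        if self.grid is None:
            return np.round(np.arange(-10.0, -5.0 + 1e-9, 0.1), 10)
        grid = np.asarray(self.grid, dtype=float)
        if grid.size == 0:
            raise ValueError("grid must be non-empty")
        return grid

    def simulate(self) -> list[PredictedDistribution]:
        """Simulate the per-grid-point ``beta`` distributions only.

        Useful when several observed datasets are fitted under the same
        parameters: the simulations dominate the cost and can be shared via
        ``fit(observed, predictions=...)``.
        """
        grid = self._grid()
        params = self.params if self.params is not None else SimulationParams()
        design = self.design if self.design is not None else ExperimentDesign()
        root = np.random.SeedSequence(self.seed)
        seeds = root.spawn(grid.size)
        preds = []
        for log_mu, ss in zip(grid, seeds):
            p = SimulationParams(**{**params.__dict__, "mu": 10.0**log_mu})
            preds.append(simulate_predictions(p, design, self.tau, self.n_sims, ss))
        return preds

    def fit(self, X, y=None, predictions: list[PredictedDistribution] | None = None):
        """Fit to observed counts.

        ``X`` is an :class:`ObservedCounts` or a sequence of per-lineage
        detectable-mutation counts.
        """
        observed = self._as_observed(X)
        grid = self._grid()
        preds = predictions if predictions is not None else self.simulate()
        if len(preds) != grid.size:
            raise ValueError("predictions do not match grid")
        self.predictions_ = preds
        idx, loglik, excl = self._maximize(observed, preds, grid)
        ci = None
        if self.n_boot > 0:
            ci = self._bootstrap_ci(observed, preds, grid)
        self.mu_hat_ = float(10.0 ** grid[idx])
        self.result_ = FitResult(
            mu_hat=self.mu_hat_,
            grid=grid,
            nll=-loglik,
            excluded=excl,
            ci95=ci,
            predictions=preds,
        )
        return self

    def _as_observed(self, X) -> ObservedCounts:
        if isinstance(X, ObservedCounts):
            return X
        params = self.params if self.params is not None else SimulationParams()
        return ObservedCounts(
            per_replicate=tuple(int(c) for c in np.asarray(X).ravel()),
            region_length=params.g,
            tau=self.tau,
        )

    def _maximize(self, observed, preds, grid):
        excl = np.array([p.excluded for p in preds])
        if excl.all():
            raise ValueError("all grid points excluded (counts exceed sigma-1)")
        loglik = np.full(grid.size, np.nan)
        for i, pred in enumerate(preds):
            if not excl[i]:
                loglik[i] = pseudo_loglik(observed, pred)
        valid = ~excl
        masked = np.where(valid, loglik, -np.inf)
        return _argmax_with_tie_rule(masked, grid), loglik, excl

    def _bootstrap_ci(self, observed, preds, grid):
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xB007]))
        counts = np.asarray(observed.per_replicate)
        mu_boot = np.empty(self.n_boot)
        for b in range(self.n_boot):
            resampled = rng.choice(counts, size=counts.size, replace=True)
            obs_b = ObservedCounts(
                per_replicate=tuple(int(c) for c in resampled),
                region_length=observed.region_length,
                tau=observed.tau,
                psi=observed.psi,
            )
            idx, _, _ = self._maximize(obs_b, preds, grid)
            mu_boot[b] = 10.0 ** grid[idx]
        lo, hi = np.percentile(mu_boot, [2.5, 97.5])
        return (float(lo), float(hi))


class ClassicRateEstimator(BaseEstimator):
    """Classical mutation-rate estimator adapted to deep-sequencing data.

    ``mu_hat = m_s / (T_s * c)`` with ``m_s`` the summed frequency of
    mutations above ``tau``, ``T_s = region_length * n_replicates`` and
    ``c = theta * ln(kappa/lam) / ln(1+rho)`` strand-copying generations.
    The selection correction ``alpha`` is fixed at 1 (neutral region).

    Attributes (after :meth:`fit`): ``mu_hat_``, ``result_``.
    """

    def __init__(
        self,
        region_length: int = 11646,
        n_replicates: int = 5,
        theta: int = 5,
        params: SimulationParams | None = None,
        rho: float | None = None,
        tau: float = 0.005,
        n_boot: int = 1000,
        seed: int = 0,
    ):
        self.region_length = region_length
        self.n_replicates = n_replicates
        self.theta = theta
        self.params = params
        self.rho = rho
        self.tau = tau
        self.n_boot = n_boot
        self.seed = seed

    def _constants(self) -> tuple[float, float]:
        params = self.params if self.params is not None else SimulationParams()
        rho = self.rho if self.rho is not None else params.rho
        c = classic_generations(self.theta, params.kappa, params.lam, rho)
        T_s = float(self.region_length) * self.n_replicates
        return T_s, c

    def fit(self, X, y=None):
        """Fit from mutation frequencies.

        ``X`` is a sequence of per-mutation frequencies, or a DataFrame with
        a ``frequency`` column.  Frequencies at or below ``tau`` are dropped.
        """
        freqs = np.asarray(X["frequency"] if hasattr(X, "columns") else X, dtype=float).ravel()
        freqs = freqs[freqs > self.tau]
        T_s, c = self._constants()
        m_s = float(freqs.sum())
        mu_hat = m_s / (T_s * c)
        ci = None
        if self.n_boot > 0 and freqs.size:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xC1A55]))
            boots = np.empty(self.n_boot)
            for b in range(self.n_boot):
                boots[b] = rng.choice(freqs, size=freqs.size, replace=True).sum() / (T_s * c)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi))
        self.mu_hat_ = mu_hat
        self.result_ = ClassicEstimate(m_s=m_s, T_s=T_s, c=c, alpha=1.0, mu_hat=mu_hat, ci95=ci)
        return self

    def predict(self, mu: float) -> float:
        """Expected summed mutation frequency ``m_s = mu * T_s * c``."""
        T_s, c = self._constants()
        return float(mu) * T_s * c


def classic_generations(theta: int, kappa: float, lam: float, rho: float) -> float:
    """Strand-copying generations ``c = theta * ln(kappa/lam) / ln(1+rho)``."""
    if theta < 1:
        raise ValueError("theta must be >= 1")
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if kappa <= lam:
        raise ValueError("kappa must exceed lam")
    return theta * math.log(kappa / lam) / math.log1p(rho)


def fit_mutation_rate(
    observed: ObservedCounts,
    params_base: SimulationParams | None = None,
    design: ExperimentDesign | None = None,
    grid=None,
    n_sims: int = 1000,
    n_boot: int = 0,
    seed: int = 0,
    predictions: list[PredictedDistribution] | None = None,
) -> FitResult:
    """Functional wrapper around :class:`MutationRateEstimator`."""
    est = MutationRateEstimator(
        grid=grid,
        params=params_base,
        design=design,
        tau=observed.tau,
        n_sims=n_sims,
        n_boot=n_boot,
        seed=seed,
    )
    est.fit(observed, predictions=predictions)
    return est.result_


def bootstrap_fit_ci(
    observed: ObservedCounts,
    params_base: SimulationParams | None = None,
    design: ExperimentDesign | None = None,
    grid=None,
    n_sims: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    predictions: list[PredictedDistribution] | None = None,
) -> tuple[float, float]:
    """95% bootstrap CI of the fitted rate (resampling lineages)."""
    result = fit_mutation_rate(
        observed, params_base, design, grid, n_sims, n_boot, seed, predictions
    )
    return result.ci95


def classic_estimate(
    frequencies,
    region_length: int,
    n_replicates: int,
    theta: int,
    params: SimulationParams | None = None,
    rho: float | None = None,
    tau: float = 0.005,
    n_boot: int = 1000,
    seed: int = 0,
) -> ClassicEstimate:
    """Functional wrapper around :class:`ClassicRateEstimator`."""
    est = ClassicRateEstimator(
        region_length=region_length,
        n_replicates=n_replicates,
        theta=theta,
        params=params,
        rho=rho,
        tau=tau,
        n_boot=n_boot,
        seed=seed,
    )
    est.fit(frequencies)
    return est.result_


def demography_grid(
    params_base: SimulationParams,
    lam_values,
    kappa_values,
    tau: float,
    n_passages: int = 5,
    n_sims: int = 20,
    seed: int = 0,
    rho: float | None = None,
) -> np.ndarray:
    """Mean detectable-mutation count over a (lam, kappa) grid.

    Runs the reduced single-insect serial-passage design (``n_passages``
    passages through one larva each, no final amplification) ``n_sims``
    times per grid cell.  Seeds are paired across cells: cell (i, j) of
    simulation k uses the same spawned stream index k, so comparisons along
    either axis share their Monte-Carlo noise.
    """
    lam_values = np.asarray(lam_values, dtype=float)
    kappa_values = np.asarray(kappa_values, dtype=float)
    if lam_values.size == 0 or kappa_values.size == 0:
        raise ValueError("grids must be non-empty")
    rho = rho if rho is not None else params_base.rho
    root = np.random.SeedSequence(seed)
    sim_seeds = root.spawn(n_sims)
    out = np.zeros((lam_values.size, kappa_values.size))
    for i, lam in enumerate(lam_values):
        for j, kappa in enumerate(kappa_values):
            if kappa <= lam:
                raise ValueError("every kappa must exceed every lam")
            p = SimulationParams(
                **{**params_base.__dict__, "lam": float(lam), "kappa": float(kappa), "rho": rho}
            )
            total = 0
            for k in range(n_sims):
                # same entropy per simulation index across cells: paired noise
                rng = np.random.default_rng(sim_seeds[k])
                freqs = np.zeros(p.g)
                for _ in range(n_passages):
                    freqs = simulate_passage(freqs, p, rng, n_larvae=1)
                total += count_detectable(freqs, tau)
            out[i, j] = total / n_sims
    return out
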