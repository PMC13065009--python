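"""Genetic-algorithm tuning of the EKF hyperparameters.

The seven hyperparameters (three process-noise variances, the
measurement-noise variance, initial frequency, initial damping and the
initial covariance scale) are tuned on the first ~60 s of a recording by
minimizing the mean squared one-step innovation averaged over channels
(:func:`oscitrack.core.prediction_error_cost`).  Variance-like
parameters are searched on a log10 scale.

Operators: tournament selection (k=3), uniform crossover, Gaussian
mutation with sigma = 10% of the box width, elitism.  The search space
is small (7 genes) and the fitness cheap, so a modest population
suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DIVERGENCE_PENALTY, EKFHyperParams, prediction_error_cost
from .signals import SignalSet

__all__ = ["GAConfig", "OptimizationResult", "default_bounds", "optimize"]

#: Gene order used throughout this module.
GENES = ("q_osc", "q_freq", "q_damp", "r_meas", "f_init", "rho_init", "p0_scale")
#: Genes searched on a log10 scale.
LOG_GENES = frozenset({"q_osc", "q_freq", "q_damp", "r_meas", "p0_scale"})


def default_bounds(f_min: float, f_max: float) -> dict[str, tuple[float, float]]:
    """Per-parameter search box; ``f_init`` is confined to the analysis band."""
    return {
        "q_osc": (1e-6, 1.0),
        "q_freq": (1e-10, 1e-2),
        "q_damp": (1e-10, 1e-2),
        "r_meas": (1e-4, 1e2),
        "f_init": (f_min, f_max),
        "rho_init": (0.80, 0.999),
        "p0_scale": (1e-4, 10.0),
    }


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    ``bounds`` maps each hyperparameter name to its (low, high) box;
    variance-like entries must be strictly positive (they are searched in
    log10 space).
    """

    bounds: dict[str, tuple[float, float]]
    population_size: int = 40
    generations: int = 30
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_sigma_frac: float = 0.1
    elitism: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("need 0 <= elitism < population_size")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        missing = set(GENES) - set(self.bounds)
        if missing:
            raise ValueError(f"bounds missing for {sorted(missing)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bound for {name} must have low < high")
            if name in LOG_GENES and lo <= 0:
                raise ValueError(f"variance bound for {name} must be positive")


@dataclass
class OptimizationResult:
    best: EKFHyperParams
    best_cost: float
    history: list[float] = field(default_factory=list)


def _to_box(cfg: GAConfig) -> tuple[np.ndarray, np.ndarray]:
    lo = np.empty(len(GENES))
    hi = np.empty(len(GENES))
    for i, g in enumerate(GENES):
        a, b = cfg.bounds[g]
        if g in LOG_GENES:
            a, b = np.log10(a), np.log10(b)
        lo[i], hi[i] = a, b
    return lo, hi


def decode(genome: np.ndarray) -> EKFHyperParams:
    """Genome (internal coordinates) -> hyperparameter dataclass."""
    vals = {}
    for i, g in enumerate(GENES):
        vals[g] = 10.0 ** genome[i] if g in LOG_GENES else float(genome[i])
    return EKFHyperParams(**vals)


def encode(hp: EKFHyperParams) -> np.ndarray:
    out = np.empty(len(GENES))
    for i, g in enumerate(GENES):
        x = getattr(hp, g)
        out[i] = np.log10(x) if g in LOG_GENES else x
    return out


def optimize(head: SignalSet, cfg: GAConfig,
             initial: list[EKFHyperParams] | None = None) -> OptimizationResult:
    """Minimize the prediction-error cost over the hyperparameter box.

    Parameters
    ----------
    head : SignalSet
        Tuning segment (by convention the first 60 s of the recording).
    cfg : GAConfig
        Operator settings and the search box; ``cfg.seed`` makes the run
        reproducible.
    initial : list of EKFHyperParams, optional
        Candidates injected into the initial population (e.g. a
        previously tuned configuration).

    Raises
    ------
    RuntimeError
        If every candidate in every generation diverges.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _to_box(cfg)
    width = hi - lo
    npop, ng = cfg.population_size, len(GENES)

    pop = lo + rng.random((npop, ng)) * width
    if initial:
        for k, hp in enumerate(initial[:npop]):
            pop[k] = np.clip(encode(hp), lo, hi)

    def cost_of(genome: np.ndarray) -> float:
        return prediction_error_cost(head, decode(genome))

    costs = np.array([cost_of(g) for g in pop])
    history: list[float] = []
    best_idx = int(np.argmin(costs))
    best_genome, best_cost = pop[best_idx].copy(), float(costs[best_idx])

    for _ in range(cfg.generations):
        order = np.argsort(costs, kind="stable")
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < npop:
            # tournament selection, k=3
            parents = []
            for _p in range(2):
                contenders = rng.integers(0, npop, size=3)
                parents.append(pop[contenders[np.argmin(costs[contenders])]])
            child = parents[0].copy()
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(ng) < 0.5
                child[swap] = parents[1][swap]
            mutate = rng.random(ng) < cfg.mutation_rate
            child[mutate] += rng.normal(
                0.0, cfg.mutation_sigma_frac * width[mutate])
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        costs = np.array([cost_of(g) for g in pop])
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_cost:
            best_genome, best_cost = pop[gen_best].copy(), float(costs[gen_best])
        history.append(best_cost)

    if best_cost >= DIVERGENCE_PENALTY:
        raise RuntimeError(
            f"optimization failed: all candidates diverged "
            f"(penalty floor {DIVERGENCE_PENALTY:g})"
        )
    return OptimizationResult(best=decode(best_genome), best_cost=best_cost,
                              history=history)
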