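"""Genetic-algorithm inversion of the two-layer Kubelka-Munk skin model.

Each chromosome is a real-valued vector of the five skin parameters,
confined to its physical bounds. A generation is assembled from an elite
copied unchanged, randomly selected survivors (diversity), single-gene-swap
crossover between rank-weighted parents, a small number of single-gene
mutations applied to offspring, and fresh uniform-random individuals filling
the remainder. The default configuration is: population 100, 25
generations, RMSE fitness, 5 elites, 25 random survivors, 30 crossover
operations (60 offspring) and 2 mutations; the 10-individual remainder is
refilled at random.

Fitness metrics besides RMSE (GFC, RecP, MSAS, SSV) are provided for
completeness; lower internal cost is always better, so similarity metrics
are converted to dissimilarities for ranking.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .chromophores import PARAM_NAMES, ParameterBounds, SkinParams
from .grids import Spectrum
from .kubelka_munk import ForwardContext

__all__ = [
    "GAConfig",
    "Population",
    "fitness_rmse",
    "fitness_gfc",
    "fitness_alternates",
    "init_population",
    "evolve_step",
    "invert_spectrum",
    "accuracy_experiment",
    "LIGHT_SKIN",
    "DARK_SKIN",
]

#: Characteristic parameter sets for the retrieval-accuracy experiment
#: (lightly and darkly pigmented skin; inner-arm-like layer thicknesses).
LIGHT_SKIN = SkinParams(f_mel=0.10, d_epi=0.05, f_blood=0.02, c_oxy=0.70, d_dermis=1.0)
DARK_SKIN = SkinParams(f_mel=0.30, d_epi=0.08, f_blood=0.02, c_oxy=0.70, d_dermis=1.0)


@dataclass(frozen=True)
class GAConfig:
    """Evolution-scheme configuration (defaults: the standard scheme above)."""

    population_size: int = 100
    iterations: int = 25
    n_best: int = 5
    n_random: int = 25
    n_cross: int = 30
    n_mutate: int = 2
    fitness_metric: str = "rmse"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.iterations < 0:
            raise ValueError("population size and iterations must be positive")
        filled = self.n_best + self.n_random + 2 * self.n_cross
        if filled > self.population_size:
            raise ValueError("elite + random + offspring exceed population size")
        if self.n_mutate > 2 * self.n_cross:
            raise ValueError("cannot mutate more offspring than crossover produces")
        if self.fitness_metric not in _COSTS:
            raise ValueError(f"unknown fitness metric {self.fitness_metric!r}")

    @classmethod
    def from_json(cls, path) -> "GAConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _values(spec) -> np.ndarray:
    return spec.values if isinstance(spec, Spectrum) else np.asarray(spec, dtype=float)


def _check_same_grid(measured, simulated) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(measured, Spectrum) and isinstance(simulated, Spectrum):
        measured.grid.require_match(simulated.grid)
    m, s = _values(measured), _values(simulated)
    if m.shape != s.shape:
        raise ValueError("spectra must share one grid")
    return m, s


def fitness_rmse(measured, simulated) -> float:
    """Root-mean-squared difference between two spectra on one grid."""
    m, s = _check_same_grid(measured, simulated)
    return float(np.sqrt(np.mean((m - s) ** 2)))


def fitness_gfc(measured, simulated) -> float:
    """Goodness-of-fit coefficient |<m, s>| / (||m|| ||s||), in [0, 1]."""
    m, s = _check_same_grid(measured, simulated)
    nm, ns = np.linalg.norm(m), np.linalg.norm(s)
    if nm == 0 or ns == 0:
        raise ValueError("GFC undefined for a zero-norm spectrum")
    return float(abs(np.dot(m, s)) / (nm * ns))


def _recp(m, s) -> float:
    nm = np.linalg.norm(m)
    if nm == 0:
        raise ValueError("RecP undefined for a zero-norm reference")
    return float(100.0 * (1.0 - np.linalg.norm(m - s) / nm))


def _msas(m, s) -> float:
    mc, sc = m - m.mean(), s - s.mean()
    nm, ns = np.linalg.norm(mc), np.linalg.norm(sc)
    if nm == 0 or ns == 0:
        raise ValueError("MSAS undefined for a constant spectrum")
    return float(np.arccos(np.clip(np.dot(mc, sc) / (nm * ns), -1.0, 1.0)))


def _ssv(m, s) -> float:
    rmse = np.sqrt(np.mean((m - s) ** 2))
    if np.std(m) == 0 or np.std(s) == 0:
        raise ValueError("SSV undefined for a constant spectrum")
    r = np.corrcoef(m, s)[0, 1]
    return float(np.sqrt(rmse**2 + (1.0 - r**2) ** 2))


def fitness_alternates(measured, simulated, metric: str) -> float:
    """Evaluate one of GFC | RecP | MSAS | SSV in its native orientation."""
    m, s = _check_same_grid(measured, simulated)
    metric = metric.lower()
    if metric == "gfc":
        return fitness_gfc(m, s)
    if metric == "recp":
        return _recp(m, s)
    if metric == "msas":
        return _msas(m, s)
    if metric == "ssv":
        return _ssv(m, s)
    raise ValueError(f"unknown metric {metric!r}")


# internal minimisation costs (lower is better)
_COSTS = {
    "rmse": lambda m, S: np.sqrt(np.mean((m - S) ** 2, axis=1)),
    "gfc": lambda m, S: 1.0
    - np.abs(S @ m) / (np.linalg.norm(m) * np.linalg.norm(S, axis=1)),
    "recp": lambda m, S: np.linalg.norm(S - m, axis=1) / np.linalg.norm(m),
    "msas": lambda m, S: np.array([_msas(m, s) for s in S]),
    "ssv": lambda m, S: np.array([_ssv(m, s) for s in S]),
}


@dataclass
class Population:
    """Bounded real-valued chromosomes with their costs, sorted best-first."""

    genes: np.ndarray  # (n, 5)
    cost: np.ndarray  # (n,)
    generation: int = 0

    @property
    def size(self) -> int:
        return self.genes.shape[0]

    @property
    def best(self) -> SkinParams:
        return SkinParams.from_array(self.genes[0])

    @property
    def best_cost(self) -> float:
        return float(self.cost[0])


def _uniform(bounds: ParameterBounds, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = bounds.lower(), bounds.upper()
    return lo + (hi - lo) * rng.random((n, lo.size))


def _evaluate(genes: np.ndarray, measured: np.ndarray, ctx: ForwardContext, metric: str) -> np.ndarray:
    spectra = ctx.reflectance_batch(genes)
    return _COSTS[metric](measured, spectra)


def _sorted_population(genes, cost, generation) -> Population:
    order = np.argsort(cost, kind="stable")
    return Population(genes=genes[order], cost=cost[order], generation=generation)


def init_population(
    bounds: ParameterBounds,
    n: int,
    seed: int | np.random.Generator | None,
    measured: np.ndarray | Spectrum | None = None,
    ctx: ForwardContext | None = None,
    metric: str = "rmse",
) -> Population:
    """Uniform-random population within bounds; evaluated if a target is given."""
    if n < 1:
        raise ValueError("population size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = _uniform(bounds, n, rng)
    if measured is None:
        cost = np.full(n, np.inf)
        return Population(genes=genes, cost=cost, generation=0)
    cost = _evaluate(genes, _values(measured), ctx or ForwardContext(bounds=bounds), metric)
    return _sorted_population(genes, cost, 0)


def evolve_step(
    pop: Population,
    measured,
    cfg: GAConfig,
    ctx: ForwardContext,
    rng: np.random.Generator,
) -> Population:
    """One generation: elitism, random survivors, crossover, mutation, refill."""
    m = _values(measured)
    n = cfg.population_size
    genes = pop.genes
    n_genes = genes.shape[1]

    parts = [genes[: cfg.n_best].copy()]
    if cfg.n_random:
        parts.append(genes[rng.integers(0, pop.size, cfg.n_random)])

    # rank-weighted parents: weight proportional to (size - rank)
    weights = np.arange(pop.size, 0, -1, dtype=float)
    weights /= weights.sum()
    offspring = np.empty((2 * cfg.n_cross, n_genes))
    for i in range(cfg.n_cross):
        ia, ib = rng.choice(pop.size, size=2, replace=False, p=weights)
        a, b = genes[ia].copy(), genes[ib].copy()
        j = rng.integers(0, n_genes)
        a[j], b[j] = b[j], a[j]
        offspring[2 * i] = a
        offspring[2 * i + 1] = b
    if cfg.n_mutate and cfg.n_cross:
        lo, hi = ctx.bounds.lower(), ctx.bounds.upper()
        picks = rng.choice(offspring.shape[0], size=cfg.n_mutate, replace=False)
        for idx in picks:
            j = rng.integers(0, n_genes)
            offspring[idx, j] = lo[j] + (hi[j] - lo[j]) * rng.random()
    if cfg.n_cross:
        parts.append(offspring)

    n_fill = n - sum(p.shape[0] for p in parts)
    if n_fill > 0:
        parts.append(_uniform(ctx.bounds, n_fill, rng))

    new_genes = np.vstack(parts)
    cost = _evaluate(new_genes, m, ctx, cfg.fitness_metric)
    return _sorted_population(new_genes, cost, pop.generation + 1)


def invert_spectrum(
    measured,
    cfg: GAConfig | None = None,
    bounds: ParameterBounds | None = None,
    ctx: ForwardContext | None = None,
    seed: int | np.random.Generator | None = None,
    return_trace: bool = False,
):
    """Retrieve the skin parameters whose forward spectrum best matches ``measured``.

    Returns ``(SkinParams, best_cost)`` (plus the per-generation best-cost
    trace if requested). Deterministic for a fixed seed.
    """
    cfg = cfg or GAConfig()
    if ctx is None:
        ctx = ForwardContext(bounds=bounds)
    elif bounds is not None and ctx.bounds is not bounds:
        raise ValueError("pass bounds either directly or inside ctx, not both")
    if isinstance(measured, Spectrum):
        measured.grid.require_match(ctx.grid)
    m = _values(measured)
    if m.shape != (len(ctx.grid),):
        raise ValueError("measured spectrum does not match the model grid")
    if seed is None:
        seed = cfg.rng_seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pop = init_population(ctx.bounds, cfg.population_size, rng, m, ctx, cfg.fitness_metric)
    trace = [pop.best_cost]
    for _ in range(cfg.iterations):
        pop = evolve_step(pop, m, cfg, ctx, rng)
        trace.append(pop.best_cost)
    if return_trace:
        return pop.best, pop.best_cost, np.asarray(trace)
    return pop.best, pop.best_cost


def accuracy_experiment(
    param_sets: dict[str, SkinParams] | None = None,
    cfg: GAConfig | None = None,
    noise_amplitude: float = 0.1,
    n_repeats: int = 10,
    seed: int = 0,
    ctx: ForwardContext | None = None,
) -> pd.DataFrame:
    """Retrieval-accuracy experiment on simulated noisy spectra.

    For each parameter set: simulate the forward spectrum, add zero-mean
    Gaussian noise (sigma = amplitude/3, clipped to [0, 1]), invert, and
    record per-parameter relative errors and the RMSE of the best-fit
    spectrum against the *noise-free* target. Averages over ``n_repeats``.

    Returns a tidy frame with one row per (set, parameter) carrying the
    signed mean relative error (%), mean absolute relative error (%), and
    one ``rmse_clean`` column repeated per set.
    """
    from .synthetic import add_noise  # local import to avoid a cycle

    cfg = cfg or GAConfig()
    ctx = ctx or ForwardContext()
    if param_sets is None:
        param_sets = {"light": LIGHT_SKIN, "dark": DARK_SKIN}

    rows = []
    master = np.random.SeedSequence(seed)
    for set_name, p0 in param_sets.items():
        ctx.bounds.validate(p0)
        truth = p0.to_array()
        clean = ctx.reflectance_batch(truth[None, :])[0]
        rel_errors = np.empty((n_repeats, len(PARAM_NAMES)))
        rmse_clean = np.empty(n_repeats)
        for rep in range(n_repeats):
            tag = zlib.crc32(set_name.encode()) & 0x7FFFFFFF
            child = np.random.SeedSequence(entropy=seed, spawn_key=(tag, rep))
            rng = np.random.default_rng(child)
            noisy = add_noise(clean, noise_amplitude, rng)
            best, _ = invert_spectrum(noisy, cfg, ctx=ctx, seed=rng)
            fit = ctx.reflectance_batch(best.to_array()[None, :])[0]
            rel_errors[rep] = (best.to_array() - truth) / truth * 100.0
            rmse_clean[rep] = float(np.sqrt(np.mean((fit - clean) ** 2)))
        for j, name in enumerate(PARAM_NAMES):
            rows.append(
                {
                    "set": set_name,
                    "parameter": name,
                    "mean_rel_error_pct": float(rel_errors[:, j].mean()),
                    "mean_abs_rel_error_pct": float(np.abs(rel_errors[:, j]).mean()),
                    "rmse_clean": float(rmse_clean.mean()),
                }
            )
    return pd.DataFrame(rows)
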