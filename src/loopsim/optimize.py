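"""Barrier-parameter optimization against a reference contact matrix.

Two regimes:

* genome-wide, uniform parameters: a two-dimensional box over
  (occupancy pi_B, P_UU), minimized by sequential model-based optimization
  (Gaussian-process surrogate with expected improvement);
* per-barrier parameters: a (mu, lambda) evolution strategy over genotypes
  holding one (pi_B, P_UU) pair per barrier, with two-point crossover,
  clamped Gaussian mutation, a penalty discouraging uninformative mid-range
  occupancies, and an island phase that masks random stretches of barriers
  (plus one island that switches every weak barrier off).

Both minimize the stripe-mismatch dissimilarity of
:func:`loopsim.eval_tools.score_matrices` between the (DoG-transformed,
discretized) simulated and reference matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .barriers import ExtrusionBarrier
from .contacts import BandedContactMatrix
from .engine import run_simulation
from .eval_tools import discretize, dog_transform, score_matrices
from .genome import Chromosome, SimulationConfig

__all__ = [
    "penalty",
    "Stripe",
    "load_stripes",
    "split_stripes",
    "GwObjective",
    "optimize_gw",
    "Individual",
    "GAConfig",
    "GAFitness",
    "mutate",
    "mate",
    "run_ga",
]

REFERENCE_THRESHOLD = 1.5
SIMULATED_THRESHOLD = 0.75


# ---------------------------------------------------------------------------
# penalty
# ---------------------------------------------------------------------------


def penalty(occupancy: float | np.ndarray) -> float | np.ndarray:
    """Penalty coefficient in [1, 2] for a barrier occupancy.

    Close to 2 near 0.5 (where occupancy has little visible effect on the
    matrix and the stripe score cannot guide the search), falls rapidly to 1
    toward 0 and 1, with an extra bump right at 1 (permanently bound
    barriers are biologically implausible)::

        p(x) = min(2, 1 + exp(-(x-0.5)^2 / (2*0.12^2))
                      + 0.5*exp(-(x-1)^2 / (2*0.02^2)))
    """
    x = np.asarray(occupancy, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("occupancy must be in [0, 1]")
    p = (
        1.0
        + np.exp(-((x - 0.5) ** 2) / (2 * 0.12**2))
        + 0.5 * np.exp(-((x - 1.0) ** 2) / (2 * 0.02**2))
    )
    p = np.minimum(p, 2.0)
    return float(p) if np.isscalar(occupancy) else p


# ---------------------------------------------------------------------------
# stripes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stripe:
    """An architectural stripe interval with orientation.

    Horizontal stripes run along matrix rows (anchored on the left, blocked
    reverse extrusion); vertical stripes along columns.
    """

    chrom: str
    start: int
    end: int
    orientation: str  # 'h' or 'v'

    def __post_init__(self) -> None:
        if self.orientation not in ("h", "v"):
            raise ValueError("orientation must be 'h' or 'v'")


_ORIENTATIONS = {
    "h": "h",
    "v": "v",
    "horizontal": "h",
    "vertical": "v",
    "+": "h",
    "-": "v",
}


def load_stripes(path: str | Path) -> list[Stripe]:
    """Read a stripe BED: orientation from the name column (h/v) or strand."""
    stripes: list[Stripe] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: stripe BED needs >= 4 columns"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            key = parts[3].lower()
            if key not in _ORIENTATIONS and len(parts) >= 6:
                key = parts[5]
            if key not in _ORIENTATIONS:
                raise ValueError(
                    f"{path}: line {lineno}: cannot determine stripe orientation"
                )
            stripes.append(Stripe(chrom, start, end, _ORIENTATIONS[key]))
    return stripes


def split_stripes(
    stripes: Sequence[Stripe], seed: int
) -> tuple[list[Stripe], list[Stripe]]:
    """Random half/half split (without replacement) into training/validation."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(stripes))
    half = len(stripes) // 2
    train = [stripes[i] for i in sorted(idx[:half])]
    valid = [stripes[i] for i in sorted(idx[half:])]
    return train, valid


def _stripe_bin_masks(
    stripes: Sequence[Stripe], chrom: Chromosome, bin_size: int, nbins: int
) -> tuple[np.ndarray, np.ndarray]:
    row_mask = np.zeros(nbins, dtype=bool)  # horizontal -> row-wise scores
    col_mask = np.zeros(nbins, dtype=bool)  # vertical -> column-wise scores
    for s in stripes:
        if s.chrom != chrom.name:
            continue
        lo = s.start // bin_size
        hi = min(nbins, -(-s.end // bin_size))
        (row_mask if s.orientation == "h" else col_mask)[lo:hi] = True
    return row_mask, col_mask


# ---------------------------------------------------------------------------
# genome-wide objective + Bayesian optimization
# ---------------------------------------------------------------------------


def transform_matrix(
    matrix: BandedContactMatrix,
    sigma1: float = 1.0,
    sigma2: float = 1.6,
    threshold: float = SIMULATED_THRESHOLD,
) -> np.ndarray:
    """DoG + discretization of a banded matrix (the ``transform`` pipeline)."""
    return discretize(dog_transform(matrix.band(), sigma1, sigma2), threshold)


class GwObjective:
    """Stripe-mismatch objective for uniform (pi_B, P_UU).

    Evaluating the objective simulates the genome with every barrier set to
    the proposed parameters (same seed every call, so the objective is
    deterministic), transforms and discretizes the result, scores it against
    the pre-transformed reference, and averages the per-bin mismatch
    indicators over the bins intersecting the training stripes.
    """

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        barriers: Sequence[ExtrusionBarrier],
        reference: dict[str, np.ndarray],
        stripes: Sequence[Stripe],
        config: SimulationConfig,
        validation_stripes: Sequence[Stripe] | None = None,
        sigma1: float = 1.0,
        sigma2: float = 1.6,
        simulated_threshold: float = SIMULATED_THRESHOLD,
        infeasible_score: float = 1.0,
    ):
        self.chromosomes = list(chromosomes)
        self.barriers = list(barriers)
        self.reference = reference  # chrom -> binary band (already discretized)
        self.stripes = list(stripes)
        self.validation_stripes = list(validation_stripes or [])
        self.config = config
        self.sigma1, self.sigma2 = sigma1, sigma2
        self.simulated_threshold = simulated_threshold
        self.infeasible_score = infeasible_score
        self.log: list[dict] = []

    def _masks(self, chrom: Chromosome, nbins: int, stripes):
        return _stripe_bin_masks(stripes, chrom, self.config.bin_size, nbins)

    def __call__(self, occupancy: float, puu: float) -> float:
        score, _ = self.evaluate(occupancy, puu)
        return score

    def evaluate(self, occupancy: float, puu: float) -> tuple[float, float]:
        """(training score, validation score); both are mean mismatch in [0, 1]."""
        if not (0 < occupancy < 1) or not (0 <= puu < 1):
            self.log.append(
                {"occupancy": occupancy, "puu": puu, "train": self.infeasible_score,
                 "valid": float("nan"), "infeasible": True}
            )
            return self.infeasible_score, float("nan")
        proposed = [
            b.with_params(occupancy=occupancy, puu=puu) for b in self.barriers
        ]
        result = run_simulation(self.chromosomes, proposed, self.config)
        train_scores, valid_scores = [], []
        for chrom in self.chromosomes:
            sim = transform_matrix(
                result.matrices[chrom.name],
                self.sigma1,
                self.sigma2,
                self.simulated_threshold,
            )
            ref = self.reference[chrom.name]
            row_mis, col_mis = score_matrices(ref, sim, mode="dissimilarity")
            for stripes, sink in (
                (self.stripes, train_scores),
                (self.validation_stripes, valid_scores),
            ):
                if not stripes:
                    continue
                row_mask, col_mask = self._masks(chrom, sim.shape[1], stripes)
                if row_mask.any():
                    sink.extend(row_mis[row_mask])
                if col_mask.any():
                    sink.extend(col_mis[col_mask])
        train = float(np.mean(train_scores)) if train_scores else float("nan")
        valid = float(np.mean(valid_scores)) if valid_scores else float("nan")
        self.log.append(
            {"occupancy": occupancy, "puu": puu, "train": train, "valid": valid,
             "infeasible": False}
        )
        return train, valid


@dataclass
class GwResult:
    """Outcome of the sequential model-based minimization."""

    best_params: tuple[float, float]
    best_score: float
    trace: pd.DataFrame  # one row per call: occupancy, puu, train, valid

    @property
    def running_minimum(self) -> np.ndarray:
        return np.minimum.accumulate(self.trace["train"].to_numpy())


def optimize_gw(
    objective: GwObjective,
    bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (0.01, 0.99),
        (0.01, 0.99),
    ),
    n_calls: int = 400,
    n_initial: int = 10,
    seed: int = 0,
) -> GwResult:
    """Minimize the objective with a GP surrogate and expected improvement.

    ``bounds`` is ((occupancy_lo, occupancy_hi), (puu_lo, puu_hi)), both
    within (0, 1). Initial points are a random space-filling sample; each
    subsequent point maximizes EI over a random candidate cloud.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    (occ_lo, occ_hi), (puu_lo, puu_hi) = bounds
    if not (0 < occ_lo <= occ_hi < 1 and 0 < puu_lo <= puu_hi < 1):
        raise ValueError("bounds must lie within (0, 1)^2")
    # equal bounds pin a dimension (e.g. optimize occupancy at known P_UU)
    rng = np.random.default_rng(seed)
    lo = np.array([occ_lo, puu_lo])
    hi = np.array([occ_hi, puu_hi])

    X: list[np.ndarray] = []
    y: list[float] = []
    records = []
    n_initial = min(n_initial, n_calls)

    def _tell(x):
        train, valid = objective.evaluate(float(x[0]), float(x[1]))
        X.append(np.asarray(x, dtype=float))
        y.append(train)
        records.append(
            {"occupancy": float(x[0]), "puu": float(x[1]), "train": train,
             "valid": valid}
        )

    for _ in range(n_initial):
        _tell(lo + rng.random(2) * (hi - lo))

    kernel = ConstantKernel(1.0) * Matern(length_scale=[0.2, 0.2], nu=2.5) + WhiteKernel(
        noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1)
    )
    while len(y) < n_calls:
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        gp.fit(np.vstack(X), np.asarray(y))
        cand = lo + rng.random((512, 2)) * (hi - lo)
        mu, sd = gp.predict(cand, return_std=True)
        best = min(y)
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        from scipy.stats import norm

        ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        # a pinch of exploration: with small probability take a random point
        if rng.random() < 0.05:
            x_next = lo + rng.random(2) * (hi - lo)
        else:
            x_next = cand[int(np.argmax(ei))]
        _tell(x_next)

    trace = pd.DataFrame.from_records(records)
    ibest = int(trace["train"].idxmin())
    return GwResult(
        best_params=(trace.loc[ibest, "occupancy"], trace.loc[ibest, "puu"]),
        best_score=float(trace.loc[ibest, "train"]),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# per-barrier GA
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    """GA genotype: per-barrier occupancy and P_UU vectors."""

    occupancy: np.ndarray
    puu: np.ndarray
    fitness: float | None = None

    def copy(self) -> "Individual":
        return Individual(self.occupancy.copy(), self.puu.copy(), self.fitness)

    def key(self) -> bytes:
        return np.round(self.occupancy, 6).tobytes() + np.round(self.puu, 6).tobytes()


@dataclass
class GAConfig:
    """Evolution-strategy settings (mainland defaults mu=256, lambda=512)."""

    mu: int = 256
    lambda_: int = 512
    mutation_sd: float = 0.1
    crossover_prob: float = 0.3
    max_generations: int = 1000
    improvement_window: int = 25
    improvement_threshold: float = 0.01
    variability_floor: float = 1e-3
    n_islands: int = 3
    island_mu: int = 128
    island_lambda: int = 256
    island_max_generations: int = 1000
    mask_length_mean: float = 25.0
    mask_length_sd: float = 5.0
    weak_occupancy_threshold: float = 0.5
    max_cycles: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < self.mu or self.island_lambda < self.island_mu:
            raise ValueError("lambda must be >= mu")
        if min(self.mu, self.lambda_, self.max_generations) < 1:
            raise ValueError("population sizes and generation counts must be >= 1")


class GAFitness:
    """Fitness of a genotype against a reference matrix.

    The genotype's barriers are simulated (fixed seed, so fitness is a
    deterministic function of the genotype), the matrix is DoG-transformed
    and discretized, and each barrier contributes the mean of the row- and
    column-mismatch indicators at its bin, multiplied by
    ``penalty(occupancy)``. Fitness (minimized) is the mean contribution
    over barriers; evaluations are memoized.
    """

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        barriers: Sequence[ExtrusionBarrier],
        reference: dict[str, np.ndarray],
        config: SimulationConfig,
        sigma1: float = 1.0,
        sigma2: float = 1.6,
        simulated_threshold: float = SIMULATED_THRESHOLD,
    ):
        self.chromosomes = list(chromosomes)
        self.barriers = list(barriers)
        self.reference = reference
        self.config = config
        self.sigma1, self.sigma2 = sigma1, sigma2
        self.simulated_threshold = simulated_threshold
        self.n_barriers = len(barriers)
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, ind: Individual) -> float:
        key = ind.key()
        if key in self._cache:
            return self._cache[key]
        proposed = [
            b.with_params(occupancy=float(o), puu=float(p))
            for b, o, p in zip(self.barriers, ind.occupancy, ind.puu)
        ]
        result = run_simulation(self.chromosomes, proposed, self.config)
        scores = []
        for chrom in self.chromosomes:
            idx = [
                k for k, b in enumerate(self.barriers) if b.chrom == chrom.name
            ]
            if not idx:
                continue
            sim = transform_matrix(
                result.matrices[chrom.name],
                self.sigma1,
                self.sigma2,
                self.simulated_threshold,
            )
            row_mis, col_mis = score_matrices(
                self.reference[chrom.name], sim, mode="dissimilarity"
            )
            bins = np.array(
                [self.barriers[k].position // self.config.bin_size for k in idx]
            )
            f = 0.5 * (row_mis[bins] + col_mis[bins])
            p = penalty(ind.occupancy[idx])
            scores.extend(f * p)
        fitness = float(np.mean(scores)) if scores else float("nan")
        self._cache[key] = fitness
        self.n_evaluations += 1
        return fitness


def mutate(
    ind: Individual,
    sd: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> Individual:
    """Clamped Gaussian mutation of both gene vectors; masked genes untouched."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    out = ind.copy()
    out.fitness = None
    for vec in (out.occupancy, out.puu):
        offsets = rng.normal(0.0, sd, vec.shape) if sd > 0 else np.zeros(vec.shape)
        if mask is not None:
            offsets[mask] = 0.0
        np.clip(vec + offsets, 0.0, 1.0, out=vec)
    return out


def mate(
    parent1: Individual, parent2: Individual, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Two-point crossover on the concatenated (occupancy | puu) genotype."""
    n = parent1.occupancy.size
    if parent2.occupancy.size != n:
        raise ValueError("parents must have the same number of barriers")
    g1 = np.concatenate([parent1.occupancy, parent1.puu])
    g2 = np.concatenate([parent2.occupancy, parent2.puu])
    c1, c2 = sorted(rng.integers(0, 2 * n + 1, size=2))
    g1[c1:c2], g2[c1:c2] = g2[c1:c2].copy(), g1[c1:c2].copy()
    return (
        Individual(g1[:n], g1[n:]),
        Individual(g2[:n], g2[n:]),
    )


def _random_individual(n: int, rng: np.random.Generator) -> Individual:
    return Individual(rng.random(n), rng.random(n))


def _evolve(
    population: list[Individual],
    fitness_fn: Callable[[Individual], float],
    cfg: GAConfig,
    mu: int,
    lambda_: int,
    max_generations: int,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
    hall_of_fame: list[Individual] | None = None,
) -> tuple[list[Individual], list[float]]:
    """(mu, lambda) ES: offspring replace the population entirely each
    generation; stops on the generation budget, stagnation, or collapsed
    population variability."""
    for ind in population:
        if ind.fitness is None:
            ind.fitness = fitness_fn(ind)
    best_history = [min(ind.fitness for ind in population)]
    window = cfg.improvement_window
    for _ in range(max_generations):
        offspring: list[Individual] = []
        while len(offspring) < lambda_:
            i, j = rng.integers(0, len(population), size=2)
            if rng.random() < cfg.crossover_prob:
                c1, c2 = mate(population[i], population[j], rng)
            else:
                c1, c2 = population[i].copy(), population[j].copy()
            offspring.append(mutate(c1, cfg.mutation_sd, rng, mask))
            if len(offspring) < lambda_:
                offspring.append(mutate(c2, cfg.mutation_sd, rng, mask))
        for ind in offspring:
            ind.fitness = fitness_fn(ind)
        # truncation selection, stable order for ties
        offspring.sort(key=lambda ind: ind.fitness)
        population = offspring[:mu]
        if hall_of_fame is not None:
            hall_of_fame.extend(ind.copy() for ind in population[: max(1, mu // 8)])
            hall_of_fame.sort(key=lambda ind: ind.fitness)
            del hall_of_fame[4 * mu :]
        best_history.append(population[0].fitness)
        if len(best_history) > window:
            past = best_history[-window - 1]
            if past > 0 and (past - best_history[-1]) / past < cfg.improvement_threshold:
                break
            if past == 0:
                break
        genes = np.stack(
            [np.concatenate([ind.occupancy, ind.puu]) for ind in population]
        )
        if float(genes.std(axis=0).mean()) < cfg.variability_floor:
            break
    return population, best_history


@dataclass
class GAResult:
    best: Individual
    history: pd.DataFrame  # phase, generation, best fitness
    n_evaluations: int


def run_ga(
    fitness_fn: GAFitness | Callable[[Individual], float],
    n_barriers: int,
    cfg: GAConfig,
) -> GAResult:
    """Mainland/island evolution of per-barrier parameters.

    Mainland (mu, lambda) ES runs to convergence; islands are then seeded by
    sampling with replacement from the fittest individuals, each masking a
    random stretch of ``k ~ round(N(mask_mean, mask_sd))`` consecutive
    barriers (inactive and non-mutable), except one island that instead
    switches every weak allele (occupancy < 0.5) to (0, 1) with all loci
    mutable. After the islands converge, half the mainland is replaced by
    fitness-proportionate draws from the island populations, and the
    alternation repeats up to ``max_cycles`` times.
    """
    if n_barriers < 1:
        raise ValueError("need at least one barrier")
    rng = np.random.default_rng(cfg.seed)
    population = [_random_individual(n_barriers, rng) for _ in range(cfg.mu)]
    hof: list[Individual] = []
    records: list[dict] = []

    def record(phase: str, history: list[float]) -> None:
        records.extend(
            {"phase": phase, "generation": g, "best_fitness": f}
            for g, f in enumerate(history)
        )

    population, history = _evolve(
        population, fitness_fn, cfg, cfg.mu, cfg.lambda_, cfg.max_generations, rng,
        hall_of_fame=hof,
    )
    record("mainland-0", history)

    for cycle in range(cfg.max_cycles):
        if cfg.n_islands < 1:
            break
        mainland_best = min(ind.fitness for ind in population)
        seeds = hof[: max(cfg.mu // 2, 1)] or population
        island_pool: list[Individual] = []
        for isl in range(cfg.n_islands):
            island = [
                seeds[rng.integers(0, len(seeds))].copy()
                for _ in range(cfg.island_mu)
            ]
            if isl == cfg.n_islands - 1:
                # weak-barrier island: switch weak alleles off, all loci mutable
                for ind in island:
                    weak = ind.occupancy < cfg.weak_occupancy_threshold
                    ind.occupancy[weak] = 0.0
                    ind.puu[weak] = 1.0
                    ind.fitness = None
                mask = None
            else:
                k = int(round(rng.normal(cfg.mask_length_mean, cfg.mask_length_sd)))
                k = max(1, min(k, n_barriers))
                start = int(rng.integers(0, n_barriers - k + 1))
                mask = np.zeros(n_barriers, dtype=bool)
                mask[start : start + k] = True
                for ind in island:
                    ind.occupancy[mask] = 0.0  # masked barriers inactive
                    ind.puu[mask] = 1.0
                    ind.fitness = None
            island, ihist = _evolve(
                island, fitness_fn, cfg, cfg.island_mu, cfg.island_lambda,
                cfg.island_max_generations, rng, mask=mask,
            )
            record(f"island-{cycle}-{isl}", ihist)
            island_pool.extend(island)

        # fitness-proportionate migration back to the mainland
        fit = np.array([ind.fitness for ind in island_pool])
        weights = 1.0 / np.maximum(fit, 1e-9)  # lower fitness = better
        weights /= weights.sum()
        n_replace = cfg.mu // 2
        migrants_idx = rng.choice(len(island_pool), size=n_replace, p=weights)
        population.sort(key=lambda ind: ind.fitness)
        population = population[: cfg.mu - n_replace] + [
            island_pool[i].copy() for i in migrants_idx
        ]
        population, history = _evolve(
            population, fitness_fn, cfg, cfg.mu, cfg.lambda_, cfg.max_generations,
            rng, hall_of_fame=hof,
        )
        record(f"mainland-{cycle + 1}", history)
        new_best = min(ind.fitness for ind in population)
        if mainland_best > 0 and (mainland_best - new_best) / mainland_best < cfg.improvement_threshold:
            break

    best = min(hof + population, key=lambda ind: ind.fitness)
    n_evals = getattr(fitness_fn, "n_evaluations", len(records))
    return GAResult(
        best=best.copy(),
        history=pd.DataFrame.from_records(records),
        n_evaluations=n_evals,
    )
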