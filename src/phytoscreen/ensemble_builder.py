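"""Model pools and GA-optimized ensembles with mean-probability aggregation.

A qualifying pool of base classifiers is assembled by repeatedly drawing a
random algorithm family (RF / DTREE / KNN) and a random 4–25-bit variable
subset, training it, and admitting it only if its test-partition BCR exceeds
a floor (0.65). Ensembles of 2–20 pool members are then evolved by the same
genetic-algorithm machinery used for variable selection, with fitness equal
to the BCR of the arithmetic-mean member probability on the test partition.
External-partition metrics are attached to the output for reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset_builder import LabeledDataset
from .ga_models import (
    ALGORITHMS,
    MAX_VARS,
    MIN_VARS,
    ClassMetrics,
    ModelSpec,
    TrainedModel,
    compute_metrics,
    train_model,
    _tournament,
)

logger = logging.getLogger(__name__)

MIN_ENSEMBLE, MAX_ENSEMBLE = 2, 20
POOL_TARGET_SIZE = 200
POOL_BCR_FLOOR = 0.65


class PoolShortfallError(RuntimeError):
    """Raised when the attempt budget runs out before the pool fills.

    Signals either an unlearnable dataset or a qualification floor set too
    high for it.
    """


@dataclass
class ModelPool:
    """Qualified base models plus their cached partition probabilities."""

    models: list[TrainedModel]
    test_probs: np.ndarray  # (n_models, n_test_in_domain)
    test_labels: np.ndarray
    external_probs: np.ndarray  # reporting only, never used as fitness
    external_labels: np.ndarray
    target_size: int
    bcr_floor: float
    n_attempts: int

    @property
    def test_bcrs(self) -> list[float]:
        return [m.test_metrics.bcr for m in self.models]

    @property
    def admission_rate(self) -> float:
        return len(self.models) / self.n_attempts if self.n_attempts else 0.0

    def __len__(self) -> int:
        return len(self.models)


def build_model_pool(
    dataset: LabeledDataset,
    target_size: int = POOL_TARGET_SIZE,
    bcr_floor: float = POOL_BCR_FLOOR,
    max_attempts: int | None = None,
    seed: int = 0,
    algorithms: tuple[str, ...] = ALGORITHMS,
    min_vars: int = MIN_VARS,
    max_vars: int = MAX_VARS,
) -> ModelPool:
    """Fill a pool with randomly generated models passing the BCR floor.

    Each candidate draws a uniform algorithm family and a uniform-size random
    variable subset; it is admitted iff its test BCR is strictly above
    ``bcr_floor``. Exhausting ``max_attempts`` (default 50x the target)
    raises :class:`PoolShortfallError` naming the shortfall.
    """
    if max_attempts is None:
        max_attempts = 50 * target_size
    if max_attempts < target_size:
        raise ValueError("max_attempts must be at least target_size")
    rng = np.random.default_rng(seed)
    n_features = int(dataset.kept_columns.size)
    hi = min(max_vars, n_features)

    X_test, y_test = dataset.eval_arrays("test")
    X_ext, y_ext = dataset.eval_arrays("external")

    models: list[TrainedModel] = []
    test_rows, ext_rows = [], []
    attempts = 0
    while len(models) < target_size and attempts < max_attempts:
        attempts += 1
        algo = algorithms[int(rng.integers(len(algorithms)))]
        size = int(rng.integers(min_vars, hi + 1))
        variables = tuple(int(v) for v in sorted(rng.choice(n_features, size, replace=False)))
        spec = ModelSpec(algo, variables, seed=int(rng.integers(2**31)))
        model = train_model(spec, dataset, min_vars=min_vars, max_vars=max_vars)
        if model.test_metrics.bcr > bcr_floor:
            models.append(model)
            test_rows.append(model.predict_proba(X_test))
            ext_rows.append(model.predict_proba(X_ext))
    if len(models) < target_size:
        raise PoolShortfallError(
            f"admitted {len(models)}/{target_size} models in {attempts} attempts "
            f"(floor {bcr_floor}); shortfall {target_size - len(models)}"
        )
    logger.info("pool admission rate %.3f (%d attempts)", len(models) / attempts, attempts)
    return ModelPool(
        models=models,
        test_probs=np.vstack(test_rows),
        test_labels=y_test,
        external_probs=np.vstack(ext_rows),
        external_labels=y_ext,
        target_size=target_size,
        bcr_floor=bcr_floor,
        n_attempts=attempts,
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """A set of pool-member indices aggregated by mean probability."""

    member_ids: tuple[int, ...]
    fitness: float  # test-partition BCR of the aggregated prediction

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("ensemble members must be unique")

    def as_manifest(self) -> dict:
        return {"member_ids": [int(i) for i in self.member_ids], "fitness": self.fitness}


def predict_ensemble(
    spec: EnsembleSpec | tuple[int, ...], pool: ModelPool, X: np.ndarray
) -> np.ndarray:
    """Arithmetic mean of member probabilities (order-invariant)."""
    ids = spec.member_ids if isinstance(spec, EnsembleSpec) else tuple(spec)
    if len(ids) == 0:
        raise ValueError("ensemble must have at least one member")
    probs = np.vstack([pool.models[i].predict_proba(X) for i in ids])
    return probs.mean(axis=0)


@dataclass
class EnsembleGAConfig:
    """GA settings for the ensemble search (full budget: 1,000 x 5,000)."""

    init_population: int = 1000
    generations: int = 5000
    min_size: int = MIN_ENSEMBLE
    max_size: int = MAX_ENSEMBLE
    tournament_size: int = 3
    crossover_rate: float = 0.9
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")


@dataclass
class RankedEnsemble:
    spec: EnsembleSpec
    test_metrics: ClassMetrics
    external_metrics: ClassMetrics  # reporting only


@dataclass
class EnsembleGAResult:
    """Deduplicated final population ranked by fitness, best first."""

    ranked: list[RankedEnsemble]
    best_trace: list[float]  # non-decreasing under elitism
    initial_best: float
    config: EnsembleGAConfig

    @property
    def best(self) -> RankedEnsemble:
        return self.ranked[0]


def ensemble_fitness(member_ids: tuple[int, ...], pool: ModelPool) -> float:
    """Test-partition BCR of the mean member probability (pure in the set)."""
    probs = pool.test_probs[list(member_ids)].mean(axis=0)
    return compute_metrics(pool.test_labels, probs).bcr


def optimize_ensembles(
    pool: ModelPool, config: EnsembleGAConfig | None = None
) -> EnsembleGAResult:
    """Evolve member subsets (2–20 models) maximizing aggregated test BCR.

    Same operator suite as variable selection: tournament selection, uniform
    set crossover, per-gene swap mutation, repair to the size window, one
    elite per generation (so the best fitness never decreases). Duplicate
    member sets may coexist during evolution; the returned ranking is
    deduplicated. Fitness uses cached test-partition member probabilities
    only; external metrics are computed afterwards for reporting.
    """
    cfg = config or EnsembleGAConfig()
    n_pool = len(pool)
    if n_pool < cfg.min_size:
        raise ValueError(f"pool of {n_pool} models is smaller than min_size {cfg.min_size}")
    rng = np.random.default_rng(cfg.seed)
    hi = min(cfg.max_size, n_pool)

    cache: dict[frozenset, float] = {}

    def fitness_of(chrom: frozenset) -> float:
        if chrom not in cache:
            cache[chrom] = ensemble_fitness(tuple(sorted(chrom)), pool)
        return cache[chrom]

    def random_chrom() -> frozenset:
        size = int(rng.integers(cfg.min_size, hi + 1))
        return frozenset(int(i) for i in rng.choice(n_pool, size, replace=False))

    def repair(chrom: set) -> frozenset:
        chrom = set(chrom)
        while len(chrom) < cfg.min_size:
            chrom.add(int(rng.integers(n_pool)))
        while len(chrom) > hi:
            chrom.remove(int(rng.choice(sorted(chrom))))
        return frozenset(chrom)

    population = [random_chrom() for _ in range(cfg.init_population)]
    fitness = [fitness_of(c) for c in population]
    best_trace = [max(fitness)]

    for _ in range(cfg.generations - 1):
        order = np.argsort(fitness)[::-1]
        next_pop = [population[i] for i in order[: cfg.elitism]]
        while len(next_pop) < cfg.init_population:
            pa = population[_tournament(fitness, cfg.tournament_size, rng)]
            pb = population[_tournament(fitness, cfg.tournament_size, rng)]
            if rng.random() < cfg.crossover_rate:
                child = set(pa & pb)
                for g in pa ^ pb:
                    if rng.random() < 0.5:
                        child.add(g)
            else:
                child = set(pa)
            # per-gene swap mutation at rate 1/|chromosome|
            rate = 1.0 / max(len(child), 1)
            for g in sorted(child):
                if rng.random() < rate:
                    child.discard(g)
                    child.add(int(rng.integers(n_pool)))
            next_pop.append(repair(child))
        population = next_pop
        fitness = [fitness_of(c) for c in population]
        best_trace.append(max(best_trace[-1], max(fitness)))

    seen: set[frozenset] = set()
    ranked: list[RankedEnsemble] = []
    for i in np.argsort(fitness)[::-1]:
        chrom = population[i]
        if chrom in seen:
            continue
        seen.add(chrom)
        ids = tuple(int(g) for g in sorted(chrom))
        ext_prob = pool.external_probs[list(ids)].mean(axis=0)
        test_prob = pool.test_probs[list(ids)].mean(axis=0)
        ranked.append(
            RankedEnsemble(
                spec=EnsembleSpec(ids, fitness[i]),
                test_metrics=compute_metrics(pool.test_labels, test_prob),
                external_metrics=compute_metrics(pool.external_labels, ext_prob),
            )
        )
    return EnsembleGAResult(
        ranked=ranked,
        best_trace=best_trace,
        initial_best=best_trace[0],
        config=cfg,
    )
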