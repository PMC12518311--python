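"""Base classifiers with genetic-algorithm variable selection.

Three algorithm families are supported — random forest (RF, Gini splits,
max depth 100), decision tree (DTREE, Gini, grown until leaves are pure or
hold a single sample), and k-nearest neighbors (KNN, k = 5, Euclidean on the
selected bits). Variable subsets of 4–25 fingerprint bits are evolved by a
genetic algorithm whose fitness is the balanced classification rate

    BCR = ((Se + Sp) / 2) * (1 - |Se - Sp|)

computed on the test partition; the external partition is never consulted by
any fitness evaluation and serves only for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .dataset_builder import LabeledDataset

logger = logging.getLogger(__name__)

ALGORITHMS = ("RF", "DTREE", "KNN")
MIN_VARS, MAX_VARS = 4, 25
PROB_THRESHOLD = 0.5


def bcr(se: float, sp: float) -> float:
    """Balanced classification rate with an imbalance penalty.

    The plain balanced accuracy (Se+Sp)/2 is multiplied by 1 - |Se - Sp|, so
    a classifier that buys sensitivity at the cost of specificity (or vice
    versa) is penalized; bcr(1, 0) = 0 and bcr(x, x) = x.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError(f"se and sp must lie in [0, 1], got ({se}, {sp})")
    return ((se + sp) / 2.0) * (1.0 - abs(se - sp))


@dataclass(frozen=True)
class ClassMetrics:
    se: float
    sp: float
    bcr: float
    f1: float
    acc: float


def compute_metrics(
    y_true: np.ndarray, prob: np.ndarray, threshold: float = PROB_THRESHOLD
) -> ClassMetrics:
    """Confusion-matrix metrics at a probability cutoff (active iff p > t)."""
    y_true = np.asarray(y_true, dtype=int)
    pred = (np.asarray(prob) > threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    acc = (tp + tn) / len(y_true) if len(y_true) else 0.0
    return ClassMetrics(se=se, sp=sp, bcr=bcr(se, sp), f1=f1, acc=acc)


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm family plus a variable subset (indices into kept columns)."""

    algorithm: str
    variables: tuple[int, ...]
    seed: int = 0
    hyperparams: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable indices must be unique")

    def as_manifest(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "variables": [int(v) for v in self.variables],
            "seed": self.seed,
            "hyperparams": dict(self.hyperparams),
        }


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparams)
    if spec.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            criterion="gini",
            max_depth=hp.get("max_depth", 100),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm == "DTREE":
        # expand until every leaf holds fewer than 2 samples (or is pure)
        return DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=1, random_state=spec.seed
        )
    return KNeighborsClassifier(
        n_neighbors=hp.get("n_neighbors", 5), metric="euclidean"
    )


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    test_metrics: ClassMetrics | None = None
    external_metrics: ClassMetrics | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the active class on variance-filtered features."""
        Xv = np.asarray(X, dtype=float)[:, list(self.spec.variables)]
        proba = self.estimator.predict_proba(Xv)
        classes = list(self.estimator.classes_)
        if 1 not in classes:
            return np.zeros(len(Xv))
        return proba[:, classes.index(1)]


def train_model(
    spec: ModelSpec,
    dataset: LabeledDataset,
    min_vars: int = MIN_VARS,
    max_vars: int = MAX_VARS,
) -> TrainedModel:
    """Fit one base classifier and score it on the in-domain test/external rows."""
    if not (min_vars <= len(spec.variables) <= max_vars):
        raise ValueError(
            f"variable count {len(spec.variables)} outside [{min_vars}, {max_vars}]"
        )
    n_features = dataset.kept_columns.size
    if max(spec.variables) >= n_features:
        raise ValueError("variable index outside the filtered feature space")
    X_train = dataset.features("train")[:, list(spec.variables)]
    y_train = dataset.partition_labels("train")
    est = _make_estimator(spec)
    est.fit(X_train, y_train)
    model = TrainedModel(spec, est)
    for part, attr in (("test", "test_metrics"), ("external", "external_metrics")):
        X, y = dataset.eval_arrays(part)
        setattr(model, attr, compute_metrics(y, model.predict_proba(X)))
    return model


@dataclass
class GAConfig:
    """Genetic-algorithm settings for variable selection.

    The defaults mirror the full-budget run (population 1,000 over 5,000
    generations); scaled configurations (e.g. 50 x 50) are used for tests and
    must be reported as such.
    """

    pop_size: int = 1000
    generations: int = 5000
    min_vars: int = MIN_VARS
    max_vars: int = MAX_VARS
    tournament_size: int = 3
    crossover_rate: float = 0.9
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_vars < self.min_vars:
            raise ValueError("max_vars must be >= min_vars")
        if self.pop_size < 2 or self.generations < 2:
            raise ValueError("pop_size and generations must be >= 2")


@dataclass
class GAResult:
    """Final GA population ranked by test-partition BCR fitness."""

    models: list[TrainedModel]  # sorted by fitness, best first
    fitness: list[float]
    best_trace: list[float]  # best fitness per generation (non-decreasing)
    config: GAConfig
    algorithm: str

    @property
    def best(self) -> TrainedModel:
        return self.models[0]

    def mean_population_metrics(self) -> dict[str, float]:
        """Arithmetic means over the final population (MeanACC/MeanBCR style)."""
        return {
            "mean_bcr": float(np.mean([m.test_metrics.bcr for m in self.models])),
            "mean_acc": float(np.mean([m.test_metrics.acc for m in self.models])),
        }


def _repair(chrom: set[int], n_features: int, cfg: GAConfig, rng) -> frozenset[int]:
    """Force a chromosome back into the [min_vars, max_vars] size window."""
    chrom = set(chrom)
    while len(chrom) < cfg.min_vars:
        chrom.add(int(rng.integers(n_features)))
    while len(chrom) > cfg.max_vars:
        chrom.remove(rng.choice(sorted(chrom)))
    return frozenset(chrom)


def _random_chromosome(n_features: int, cfg: GAConfig, rng) -> frozenset[int]:
    size = int(rng.integers(cfg.min_vars, cfg.max_vars + 1))
    size = min(size, n_features)
    return frozenset(rng.choice(n_features, size=size, replace=False).tolist())


def _crossover(a: frozenset, b: frozenset, rng) -> set[int]:
    """Uniform set crossover: shared genes kept, disputed genes tossed."""
    child = set(a & b)
    for g in a ^ b:
        if rng.random() < 0.5:
            child.add(g)
    return child


def _mutate(chrom: set[int], n_features: int, rng) -> set[int]:
    """Per-gene swap mutation at rate 1/|chromosome|."""
    rate = 1.0 / max(len(chrom), 1)
    out = set(chrom)
    for g in sorted(chrom):
        if rng.random() < rate:
            out.discard(g)
            out.add(int(rng.integers(n_features)))
    return out


def _tournament(fitness: list[float], k: int, rng) -> int:
    contenders = rng.integers(len(fitness), size=k)
    return int(max(contenders, key=lambda i: fitness[i]))


def ga_select_variables(
    dataset: LabeledDataset, algorithm: str, config: GAConfig | None = None
) -> GAResult:
    """Evolve variable subsets maximizing test-partition BCR.

    Chromosomes are variable subsets; selection is tournament (size 3),
    crossover is uniform on sets with size repair, mutation swaps individual
    genes, and one elite survives unchanged per generation, making the best
    fitness non-decreasing. Fitness evaluations are cached by chromosome, so
    converged populations cost little. The returned models carry external
    metrics for reporting only — the external partition plays no role in
    selection.
    """
    cfg = config or GAConfig()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    rng = np.random.default_rng(cfg.seed)
    n_features = int(dataset.kept_columns.size)

    X_train = dataset.features("train")
    y_train = dataset.partition_labels("train")
    X_test, y_test = dataset.eval_arrays("test")

    cache: dict[frozenset, float] = {}

    def fitness_of(chrom: frozenset) -> float:
        if chrom not in cache:
            spec = ModelSpec(algorithm, tuple(int(g) for g in sorted(chrom)), seed=cfg.seed)
            est = _make_estimator(spec)
            est.fit(X_train[:, list(spec.variables)], y_train)
            model = TrainedModel(spec, est)
            cache[chrom] = compute_metrics(y_test, model.predict_proba(X_test)).bcr
        return cache[chrom]

    population = [_random_chromosome(n_features, cfg, rng) for _ in range(cfg.pop_size)]
    fitness = [fitness_of(c) for c in population]
    best_trace = [max(fitness)]

    for _ in range(cfg.generations - 1):
        order = np.argsort(fitness)[::-1]
        next_pop = [population[i] for i in order[: cfg.elitism]]
        while len(next_pop) < cfg.pop_size:
            pa = population[_tournament(fitness, cfg.tournament_size, rng)]
            pb = population[_tournament(fitness, cfg.tournament_size, rng)]
            child = _crossover(pa, pb, rng) if rng.random() < cfg.crossover_rate else set(pa)
            child = _mutate(child, n_features, rng)
            next_pop.append(_repair(child, n_features, cfg, rng))
        population = next_pop
        fitness = [fitness_of(c) for c in population]
        best_trace.append(max(best_trace[-1], max(fitness)))

    order = np.argsort(fitness)[::-1]
    models = [
        train_model(
            ModelSpec(algorithm, tuple(int(g) for g in sorted(population[i])), seed=cfg.seed),
            dataset,
            min_vars=cfg.min_vars,
            max_vars=cfg.max_vars,
        )
        for i in order
    ]
    return GAResult(
        models=models,
        fitness=[fitness[i] for i in order],
        best_trace=best_trace,
        config=cfg,
        algorithm=algorithm,
    )
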