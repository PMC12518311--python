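"""Fingerprint datasets: balancing, partitioning, and applicability domain.

Compounds are described by 1,024-bit circular fingerprints (radius 2). Class
imbalance is reduced by k-means undersampling of the majority class at the
silhouette-optimal cluster count, with a largest-remainder proportional draw
from each cluster. Balanced data are split 60/20/20 into train/test/external
partitions; near-constant bits (population variance < 0.05 on the training
partition) are dropped; and a PCA-based applicability domain is fitted on the
training partition — a query is in-domain iff its Euclidean distance to the
training centroid, in the component space explaining >90% of variance, does
not exceed the maximum training distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import MolFromSmiles, rdFingerprintGenerator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .chem_curation import StandardizedMolecule

logger = logging.getLogger(__name__)

N_BITS = 1024
FP_RADIUS = 2
VARIANCE_THRESHOLD = 0.05
AD_CUM_VARIANCE = 0.90
SPLIT_RATIOS = (0.6, 0.2, 0.2)
PARTITION_NAMES = ("train", "test", "external")


@dataclass
class FingerprintMatrix:
    """Binary fingerprint rows aligned with their InChIKeys."""

    keys: list[str]
    bits: np.ndarray  # (n, N_BITS) uint8

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.keys):
            raise ValueError("bits must be 2-D with one row per key")


def compute_fingerprints(
    molecules: list[StandardizedMolecule],
    n_bits: int = N_BITS,
    radius: int = FP_RADIUS,
) -> FingerprintMatrix:
    """Hashed circular fingerprints (ECFP-style, radius 2, 1,024 bits).

    Invalid or unfingerprintable molecules are dropped with a log entry;
    identical canonical SMILES always yield identical rows.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    keys, rows = [], []
    for m in molecules:
        if not m.valid or m.canonical_smiles is None:
            logger.warning("fingerprint skipped: invalid molecule (%s)", m.reason)
            continue
        mol = MolFromSmiles(m.canonical_smiles)
        if mol is None:
            logger.warning("fingerprint skipped: %s", m.canonical_smiles)
            continue
        rows.append(gen.GetFingerprintAsNumPy(mol))
        keys.append(m.inchikey)
    bits = np.vstack(rows).astype(np.uint8) if rows else np.empty((0, n_bits), np.uint8)
    return FingerprintMatrix(keys, bits)


def largest_remainder_allocation(sizes: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` draws across groups proportionally to ``sizes``.

    Floor quotas are topped up in order of decreasing fractional remainder
    (ties toward the larger group, then the lower index), so the allocation
    sums exactly to ``total`` and never exceeds any group's size.
    """
    sizes = np.asarray(sizes, dtype=float)
    quotas = sizes * total / sizes.sum()
    alloc = np.floor(quotas).astype(int)
    remainder = total - alloc.sum()
    if remainder > 0:
        frac = quotas - alloc
        order = sorted(
            range(len(sizes)), key=lambda i: (-frac[i], -sizes[i], i)
        )
        for i in order[:remainder]:
            alloc[i] += 1
    return alloc


def silhouette_scan(
    X: np.ndarray, k_hi: int, seed: int, n_init: int = 10
) -> tuple[int | None, np.ndarray | None, dict[int, float]]:
    """Scan k-means over k = 2..k_hi and pick the silhouette-optimal k.

    Ties break toward the smaller k (strict improvement required). Returns
    (best_k, best_labels, per-k scores); best_k is None when no k yields two
    or more populated clusters.
    """
    best_k, best_score, best_labels = None, -np.inf, None
    scores: dict[int, float] = {}
    for k in range(2, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(X, labels))
        if scores[k] > best_score:
            best_k, best_score, best_labels = k, scores[k], labels
    return best_k, best_labels, scores


def balance_by_clustering(
    majority: FingerprintMatrix | np.ndarray,
    minority_size: int,
    seed: int,
    k_max: int | None = None,
    n_init: int = 10,
) -> np.ndarray:
    """Undersample the majority class to ``minority_size`` via k-means.

    k is scanned from 2 up to the minority size (optionally capped at
    ``k_max``); the silhouette-optimal k wins, ties broken toward smaller k.
    From each cluster a largest-remainder-proportional number of compounds is
    drawn uniformly at random. Degenerate inputs (all rows identical) fall
    back to a plain random draw.

    Returns sorted row indices into the majority matrix, without replacement.
    """
    X = majority.bits if isinstance(majority, FingerprintMatrix) else np.asarray(majority)
    X = X.astype(float)
    n = X.shape[0]
    if minority_size < 2:
        raise ValueError("minority_size must be at least 2")
    if n <= minority_size:
        raise ValueError("majority class must exceed the minority size")
    rng = np.random.default_rng(seed)

    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < 2:
        logger.warning("degenerate majority (identical rows): random sampling")
        return np.sort(rng.choice(n, size=minority_size, replace=False))

    k_hi = min(minority_size, n - 1, n_distinct)
    if k_max is not None:
        k_hi = min(k_hi, k_max)
    best_k, best_labels, _ = silhouette_scan(X, k_hi, seed=seed, n_init=n_init)
    if best_labels is None:
        logger.warning("silhouette scan failed; random sampling fallback")
        return np.sort(rng.choice(n, size=minority_size, replace=False))

    clusters = [np.flatnonzero(best_labels == c) for c in range(best_k)]
    alloc = largest_remainder_allocation(
        np.array([len(c) for c in clusters]), minority_size
    )
    chosen = [
        rng.choice(members, size=take, replace=False)
        for members, take in zip(clusters, alloc)
        if take > 0
    ]
    return np.sort(np.concatenate(chosen))


def split_dataset(
    n: int, ratios: tuple[float, float, float] = SPLIT_RATIOS, seed: int = 0
) -> np.ndarray:
    """Random label-agnostic train/test/external assignment (60/20/20).

    Counts honor the ratios within the +-1 slack that integer rounding
    forces; the assignment is a seeded permutation, reproducible exactly.
    """
    if n < 10:
        raise ValueError("need at least 10 compounds to form three partitions")
    counts = largest_remainder_allocation(np.asarray(ratios), n)
    parts = np.repeat(np.array(PARTITION_NAMES, dtype=object), counts)
    rng = np.random.default_rng(seed)
    return parts[rng.permutation(n)]


def variance_filter(
    train_bits: np.ndarray, threshold: float = VARIANCE_THRESHOLD
) -> np.ndarray:
    """Indices of columns whose population variance is >= threshold.

    For a binary column with set-bit frequency p the population variance is
    p(1-p); columns strictly below the threshold are removed.
    """
    var = np.var(np.asarray(train_bits, dtype=float), axis=0)  # ddof=0
    kept = np.flatnonzero(~(var < threshold))
    if kept.size == 0:
        raise ValueError(
            f"variance filter removed every column (max variance {var.max():.4f} "
            f"< {threshold})"
        )
    return kept


@dataclass
class ApplicabilityDomain:
    """PCA-Euclidean applicability domain fitted on the training partition."""

    kept_columns: np.ndarray
    mean: np.ndarray  # feature-space center used by the projection
    components: np.ndarray  # (n_components, n_features) loadings
    centroid: np.ndarray  # centroid of training projections
    max_distance: float
    n_components: int

    def distances(self, bits: np.ndarray) -> np.ndarray:
        X = np.asarray(bits, dtype=float)
        if X.shape[1] == self.components.shape[1]:
            pass  # already restricted to kept columns
        elif X.shape[1] > max(self.kept_columns):
            X = X[:, self.kept_columns]
        else:
            raise ValueError(
                f"query has {X.shape[1]} columns; expected "
                f"{self.components.shape[1]} (filtered) or a full-width matrix"
            )
        proj = (X - self.mean) @ self.components.T
        return np.linalg.norm(proj - self.centroid, axis=1)

    def contains(self, bits: np.ndarray) -> np.ndarray:
        """In-domain flags: distance to centroid <= training maximum."""
        d = self.distances(bits)
        return d <= self.max_distance * (1 + 1e-9)


def fit_applicability_domain(
    train_bits: np.ndarray,
    kept_columns: np.ndarray | None = None,
    cum_variance: float = AD_CUM_VARIANCE,
) -> ApplicabilityDomain:
    """Fit the PCA domain on (variance-filtered) training fingerprints.

    The component count is the smallest explaining more than ``cum_variance``
    of cumulative variance; PCA is run on mean-centered raw bits (no
    rescaling — all bits share a scale). The domain radius is the maximum
    training distance to the centroid of training projections, so every
    training compound is in-domain by construction.
    """
    X = np.asarray(train_bits, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a domain")
    if kept_columns is None:
        kept_columns = np.arange(X.shape[1])
    pca = PCA()
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, cum_variance, side="right")) + 1
    n_comp = min(n_comp, pca.components_.shape[0])
    components = pca.components_[:n_comp]
    proj = (X - pca.mean_) @ components.T
    centroid = proj.mean(axis=0)
    max_dist = float(np.linalg.norm(proj - centroid, axis=1).max())
    return ApplicabilityDomain(
        kept_columns=np.asarray(kept_columns),
        mean=pca.mean_,
        components=components,
        centroid=centroid,
        max_distance=max_dist,
        n_components=n_comp,
    )


@dataclass
class LabeledDataset:
    """Balanced, partitioned fingerprint dataset for one cell line."""

    keys: list[str]
    bits: np.ndarray  # full-width (n, N_BITS)
    labels: np.ndarray  # 1 = active
    partition: np.ndarray  # over PARTITION_NAMES
    kept_columns: np.ndarray
    ad: ApplicabilityDomain
    cell_line: str = ""
    manifest: dict = field(default_factory=dict)

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.partition == part)

    def features(self, part: str | None = None) -> np.ndarray:
        X = np.asarray(self.bits, dtype=float)[:, self.kept_columns]
        if part is None:
            return X
        return X[self.indices(part)]

    def partition_labels(self, part: str) -> np.ndarray:
        return self.labels[self.indices(part)]

    def in_domain(self, part: str) -> np.ndarray:
        return self.ad.contains(self.features(part))

    def eval_arrays(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        """Features and labels of a partition restricted to in-domain rows."""
        X, y = self.features(part), self.partition_labels(part)
        mask = self.ad.contains(X)
        return X[mask], y[mask]


def build_dataset(
    fps: FingerprintMatrix,
    labels: np.ndarray,
    seed: int,
    cell_line: str = "",
    ratios: tuple[float, float, float] = SPLIT_RATIOS,
    variance_threshold: float = VARIANCE_THRESHOLD,
    k_max: int | None = None,
    balance: bool = True,
) -> LabeledDataset:
    """Balance, split, variance-filter, and fit the applicability domain.

    Balancing precedes splitting; the variance filter and the domain are
    fitted on the training partition only and applied unchanged elsewhere.
    """
    labels = np.asarray(labels, dtype=int)
    bits = fps.bits
    keys = list(fps.keys)

    if balance:
        n_active, n_inactive = int(labels.sum()), int((labels == 0).sum())
        if n_active != n_inactive:
            maj_label = 1 if n_active > n_inactive else 0
            minority_size = min(n_active, n_inactive)
            maj_idx = np.flatnonzero(labels == maj_label)
            min_idx = np.flatnonzero(labels != maj_label)
            sel = balance_by_clustering(
                bits[maj_idx], minority_size, seed=seed, k_max=k_max
            )
            keep = np.sort(np.concatenate([min_idx, maj_idx[sel]]))
            bits, labels = bits[keep], labels[keep]
            keys = [keys[i] for i in keep]

    partition = split_dataset(len(keys), ratios=ratios, seed=seed)
    train = np.flatnonzero(partition == "train")
    kept = variance_filter(bits[train], threshold=variance_threshold)
    ad = fit_applicability_domain(bits[train][:, kept].astype(float), kept_columns=kept)
    manifest = {
        "seed": seed,
        "variance_threshold": variance_threshold,
        "n_components": ad.n_components,
        "n_kept_columns": int(kept.size),
        "ratios": list(ratios),
    }
    return LabeledDataset(
        keys=keys,
        bits=bits,
        labels=labels,
        partition=partition,
        kept_columns=kept,
        ad=ad,
        cell_line=cell_line,
        manifest=manifest,
    )
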