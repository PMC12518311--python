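"""Early-recognition metrics and the cross-cell-line combination search.

For a ranked list of N compounds containing n actives (Ra = n/N), the robust
initial enhancement is the exponentially rank-weighted sum over active
positions r_i, normalized by its expectation under a uniform random ranking:

    RIE = sum_i exp(-a * r_i / N) / [ (n/N) * (1 - e^{-a}) / (e^{a/N} - 1) ]

Its attainable extremes have closed forms

    RIE_min = (1 - e^{+a*Ra}) / (Ra * (1 - e^{+a}))
    RIE_max = (1 - e^{-a*Ra}) / (Ra * (1 - e^{-a}))

and BEDROC = (RIE - RIE_min) / (RIE_max - RIE_min) lies in [0, 1], equal to 1
when the actives fill the top n ranks and 0 when they fill the bottom n. The
weighting parameter a maps to a top fraction chi carrying a weight mass m via
a = -ln(1 - m) / chi (a = 160.9 puts ~80% of the weight in the top 1%). The
enrichment factor at fraction chi counts actives in the top floor(chi*N)
ranks, scaled by chi*n.

The combination search enumerates one model family per cell line (f^c
choices), scores each compound by the mean of its in-domain per-cell-line
probabilities, and profiles each combination by BEDROC over an alpha grid
and EF over a chi grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_curation import standardize_molecule

MODEL_FAMILIES = ("RF", "DTREE", "KNN", "E")
DEFAULT_ALPHA = 160.9
DEFAULT_ALPHA_GRID = (5.0, 10.0, 20.0, 40.0, 80.0, 160.9, 320.0)
DEFAULT_CHI_GRID = (0.005, 0.01, 0.02, 0.05, 0.1)
DEFAULT_HIT_THRESHOLDS = (0.5, 0.55, 0.6)


@dataclass
class RankedScreen:
    """Scored compound list with known labels (1 = active)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be matching 1-D vectors")
        if not 0 < self.n < self.N:
            raise ValueError("need at least one active and one inactive")

    @property
    def N(self) -> int:
        return len(self.scores)

    @property
    def n(self) -> int:
        return int(self.labels.sum())

    @property
    def ra(self) -> float:
        return self.n / self.N


def active_ranks(screen: RankedScreen, seed: int = 0) -> np.ndarray:
    """1-based ranks of the actives, best score first.

    Ties are broken by a seeded random permutation applied before the stable
    sort, so tied blocks are ordered randomly but reproducibly.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(screen.N)
    order = np.lexsort((perm, -screen.scores))
    ranks = np.empty(screen.N, dtype=int)
    ranks[order] = np.arange(1, screen.N + 1)
    return np.sort(ranks[screen.labels == 1])


def rie(screen: RankedScreen, alpha: float, seed: int = 0) -> float:
    """Robust initial enhancement at exponential weight ``alpha``."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    r = active_ranks(screen, seed=seed)
    N, n = screen.N, screen.n
    numerator = np.exp(-alpha * r / N).sum()
    expectation = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    return float(numerator / expectation)


def rie_bounds(ra: float, alpha: float) -> tuple[float, float]:
    """(RIE_min, RIE_max) closed forms for active fraction ``ra``."""
    rie_min = (1 - math.exp(alpha * ra)) / (ra * (1 - math.exp(alpha)))
    rie_max = (1 - math.exp(-alpha * ra)) / (ra * (1 - math.exp(-alpha)))
    return rie_min, rie_max


def bedroc(screen: RankedScreen, alpha: float, seed: int = 0) -> float:
    """BEDROC in [0, 1]: RIE rescaled by its attainable extremes."""
    rie_min, rie_max = rie_bounds(screen.ra, alpha)
    return (rie(screen, alpha, seed=seed) - rie_min) / (rie_max - rie_min)


def alpha_for_mass_fraction(chi: float, mass: float) -> float:
    """Alpha putting weight ``mass`` of the exponential in the top ``chi``.

    Solves 1 - exp(-alpha*chi) = mass; e.g. chi=0.01, mass=0.8 gives 160.94,
    the conventional top-1% anchor.
    """
    if not 0 < chi < 1:
        raise ValueError("chi must lie strictly in (0, 1)")
    if not 0 < mass < 1:
        raise ValueError("mass must lie strictly in (0, 1)")
    return -math.log1p(-mass) / chi


def weight_mass_fraction(alpha: float, chi: float) -> float:
    """Fraction of exponential weight carried by the top ``chi`` (inverse map)."""
    if alpha <= 0 or not 0 < chi <= 1:
        raise ValueError("alpha must be positive and chi in (0, 1]")
    return 1 - math.exp(-alpha * chi)


def enrichment_factor(screen: RankedScreen, chi: float, seed: int = 0) -> float:
    """EF at top fraction ``chi``: actives in the top floor(chi*N), over chi*n.

    The window holds floor(chi*N) compounds (at least 1); ranks are 1-based.
    """
    if not 0 < chi <= 1:
        raise ValueError("chi must lie in (0, 1]")
    window = max(1, math.floor(chi * screen.N))
    r = active_ranks(screen, seed=seed)
    hits = int((r <= window).sum())
    return hits / (chi * screen.n)


def merge_screening_ledger(
    eval_table: pd.DataFrame, decoy_table: pd.DataFrame
) -> pd.DataFrame:
    """Merge an evaluation table with a decoy table into one unique ledger.

    Both tables need a ``smiles`` column; an ``inchikey`` column is used as
    the deduplication key when present, otherwise keys are computed by
    standardization. Evaluation labels are kept; decoys default to label 0.
    An evaluation entry wins any key collision with a decoy.
    """
    frames = []
    for df, default_label, origin in ((eval_table, None, "eval"), (decoy_table, 0, "decoy")):
        df = df.copy()
        if "inchikey" not in df.columns:
            df["inchikey"] = [
                standardize_molecule(s).inchikey for s in df["smiles"]
            ]
        if "label" not in df.columns:
            df["label"] = default_label if default_label is not None else 0
        df["origin"] = origin
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    merged = merged.dropna(subset=["inchikey"])
    merged = merged.drop_duplicates(subset="inchikey", keep="first")
    return merged.reset_index(drop=True)


@dataclass
class CombinationResult:
    """One per-cell-line family choice and its consensus-score profile."""

    choice: dict[str, str]  # cell line -> family
    consensus_scores: np.ndarray  # NaN for compounds outside any member domain
    n_in_domain: int
    bedroc_profile: dict[float, float] = field(default_factory=dict)
    ef_profile: dict[float, float] = field(default_factory=dict)
    anchor_bedroc: float = float("nan")

    @property
    def label(self) -> str:
        return ", ".join(self.choice[c] for c in sorted(self.choice))


def combination_search(
    probabilities: dict[str, dict[str, np.ndarray]],
    domains: dict[str, dict[str, np.ndarray]],
    labels: np.ndarray | None = None,
    families: tuple[str, ...] = MODEL_FAMILIES,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    chi_grid: tuple[float, ...] = DEFAULT_CHI_GRID,
    anchor_alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> list[CombinationResult]:
    """Enumerate every per-cell-line family choice and rank by early recognition.

    ``probabilities[cell_line][family]`` holds each model's probability for
    every screened compound, ``domains[cell_line][family]`` its in-domain
    flags. A compound receives a consensus score — the arithmetic mean of its
    per-cell-line probabilities — only when it is in-domain for every model
    in the combination; otherwise it is excluded from that combination's
    ranking. With labels supplied, combinations are ranked by BEDROC at the
    anchor alpha; each result also carries a full BEDROC/EF profile.
    """
    cell_lines = sorted(probabilities)
    results: list[CombinationResult] = []
    for combo in itertools.product(families, repeat=len(cell_lines)):
        choice = dict(zip(cell_lines, combo))
        mask = np.ones_like(next(iter(domains[cell_lines[0]].values())), dtype=bool)
        for cl, fam in choice.items():
            mask &= np.asarray(domains[cl][fam], dtype=bool)
        if not mask.any():
            raise ValueError(f"no compound is in-domain for combination {choice}")
        stacked = np.vstack([probabilities[cl][fam] for cl, fam in choice.items()])
        consensus = np.full(mask.shape, np.nan)
        consensus[mask] = stacked[:, mask].mean(axis=0)
        result = CombinationResult(choice, consensus, int(mask.sum()))
        if labels is not None:
            sub = RankedScreen(consensus[mask], np.asarray(labels)[mask])
            result.bedroc_profile = {a: bedroc(sub, a, seed=seed) for a in alpha_grid}
            result.ef_profile = {c: enrichment_factor(sub, c, seed=seed) for c in chi_grid}
            result.anchor_bedroc = bedroc(sub, anchor_alpha, seed=seed)
        results.append(result)
    if labels is not None:
        results.sort(key=lambda r: -r.anchor_bedroc)
    return results


@dataclass
class ConsensusHitReport:
    """Thresholded intersection of two consensus score maps."""

    hits: dict[float, set]  # threshold -> keys above it in BOTH models
    exceedance_a: dict[float, int]
    exceedance_b: dict[float, int]
    max_a: float
    max_b: float


def select_consensus_hits(
    consensus_a: dict | pd.Series,
    consensus_b: dict | pd.Series,
    thresholds: tuple[float, ...] = DEFAULT_HIT_THRESHOLDS,
) -> ConsensusHitReport:
    """Compounds scoring above each threshold in both consensus models.

    Both maps must cover the same compound universe (same keys).
    """
    a = pd.Series(consensus_a, dtype=float)
    b = pd.Series(consensus_b, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("consensus maps must cover the same compound universe")
    b = b.reindex(a.index)
    hits, exc_a, exc_b = {}, {}, {}
    for t in thresholds:
        in_a = set(a.index[a > t])
        in_b = set(b.index[b > t])
        hits[t] = in_a & in_b
        exc_a[t], exc_b[t] = len(in_a), len(in_b)
    return ConsensusHitReport(
        hits=hits,
        exceedance_a=exc_a,
        exceedance_b=exc_b,
        max_a=float(a.max()),
        max_b=float(b.max()),
    )
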