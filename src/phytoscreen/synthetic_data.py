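"""Synthetic inputs for every pipeline stage.

Real runs of this pipeline consume ChEMBL-style activity extracts, a
screening ledger with decoys, and natural-product association tables; none
of those can ship with the package. The generators here emit the same
delimited-text shapes with controllable statistical structure and a ground
truth sufficient to verify every downstream property:

* fingerprint datasets with planted informative bits (class signal), planted
  majority-class cluster structure (for undersampling tests), and bit-flip
  noise;
* score-separated active/decoy screening sets at the scale of the real
  evaluation ledger (86 actives among 4,535 compounds);
* compound–plant association tables with planted high-activity species,
  enantiomer duplicates, and a matching NCBI-style lineage dump that mixes
  in non-plant organisms.

All generators are pure functions of their configuration (seed included).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_curation import standardize_molecule
from .screening_eval import RankedScreen

BACKGROUND_BIT_DENSITY = 0.05
SIGNATURE_BLOCK_START = 512
SIGNATURE_BLOCK_WIDTH = 30
SIGNATURE_BIT_PROB = 0.95

PLANT_GENERA = ("Planta", "Herba", "Arbor", "Folium", "Radix")
NONPLANT_GENERA = ("Mycus", "Animalis")
PLANT_LINEAGE = (
    "cellular organisms; Eukaryota; Viridiplantae; Streptophyta; "
    "Magnoliopsida; Syntheticales"
)
NONPLANT_LINEAGE = (
    "cellular organisms; Eukaryota; Opisthokonta; Fungi; Dikarya; Syntheticomycetes"
)


def _content_hash(*parts: str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
    return h.hexdigest()[:16]


def generate_smiles(n: int, start: int = 0) -> list[str]:
    """Deterministic list of ``n`` distinct valid linear-chain SMILES.

    Each molecule is a fluorine-capped chain of C/N atoms encoding an integer
    in binary; the unique terminal F rules out reversal collisions, so
    distinct indices give distinct constitutions (hence distinct InChIKeys).
    """
    out = []
    for i in range(start, start + n):
        digits = bin(i + 2)[3:]  # strip the leading guard bit
        chain = "".join("C" if d == "0" else "N" for d in digits)
        out.append("FC" + chain)
    return out


def enantiomer_pair(tail: str) -> tuple[str, str]:
    """Two mirror-image SMILES sharing one achiral standardized form."""
    return (f"C[C@H](O){tail}", f"C[C@@H](O){tail}")


# ---------------------------------------------------------------------------
# fingerprint datasets


@dataclass(frozen=True)
class FingerprintSimConfig:
    """Shape and signal of a simulated fingerprint dataset.

    ``effect`` shifts the informative-bit frequency between classes: active
    rows carry each informative bit with probability p0 + effect*(1-p0) and
    inactive rows with p0*(1-effect), so effect=0 erases the signal and
    effect=1 makes the classes perfectly separable (before noise). Majority
    rows additionally draw one of ``n_majority_clusters`` signature-bit
    templates, giving the undersampler real cluster structure to find.
    """

    n_active: int = 200
    n_inactive: int = 400
    n_bits: int = 1024
    informative_bits: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect: float = 0.9
    n_majority_clusters: int = 3
    noise_flip_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 <= b < self.n_bits for b in self.informative_bits):
            raise ValueError("informative_bits must lie inside [0, n_bits)")
        if not 0 <= self.effect <= 1:
            raise ValueError("effect must lie in [0, 1]")
        if not 0 <= self.noise_flip_rate <= 0.5:
            raise ValueError("noise_flip_rate must lie in [0, 0.5]")
        if self.n_majority_clusters < 1:
            raise ValueError("need at least one majority cluster")


@dataclass
class SimulatedFingerprintData:
    """Bits, labels, and the ground truth that produced them."""

    bits: np.ndarray  # (n, n_bits) uint8
    labels: np.ndarray  # 1 = active
    cluster_assignments: np.ndarray  # majority rows 0..k-1, minority rows -1
    informative_bits: tuple[int, ...]
    config: FingerprintSimConfig
    manifest: dict = field(default_factory=dict)


def simulate_fingerprint_dataset(config: FingerprintSimConfig) -> SimulatedFingerprintData:
    """Draw Bernoulli fingerprint rows with planted class and cluster signal."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_active + cfg.n_inactive
    labels = np.concatenate(
        [np.ones(cfg.n_active, dtype=int), np.zeros(cfg.n_inactive, dtype=int)]
    )

    p = np.full((n, cfg.n_bits), BACKGROUND_BIT_DENSITY)
    info = list(cfg.informative_bits)
    p_act = BACKGROUND_BIT_DENSITY + cfg.effect * (1 - BACKGROUND_BIT_DENSITY)
    p_inact = BACKGROUND_BIT_DENSITY * (1 - cfg.effect)
    p[np.ix_(labels == 1, info)] = p_act
    p[np.ix_(labels == 0, info)] = p_inact

    # majority-class cluster structure: disjoint signature-bit blocks.
    # Planted only when a majority exists — on balanced data one-sided
    # signatures would masquerade as class signal.
    clusters = np.full(n, -1, dtype=int)
    if cfg.n_active != cfg.n_inactive:
        maj_label = 1 if cfg.n_active > cfg.n_inactive else 0
        maj_idx = np.flatnonzero(labels == maj_label)
        clusters[maj_idx] = rng.integers(cfg.n_majority_clusters, size=maj_idx.size)
        for c in range(cfg.n_majority_clusters):
            lo = SIGNATURE_BLOCK_START + c * SIGNATURE_BLOCK_WIDTH
            hi = min(lo + SIGNATURE_BLOCK_WIDTH, cfg.n_bits)
            members = maj_idx[clusters[maj_idx] == c]
            p[np.ix_(members, np.arange(lo, hi))] = SIGNATURE_BIT_PROB

    bits = (rng.random((n, cfg.n_bits)) < p).astype(np.uint8)
    if cfg.noise_flip_rate > 0:
        flips = rng.random((n, cfg.n_bits)) < cfg.noise_flip_rate
        bits ^= flips.astype(np.uint8)

    manifest = {
        "config": cfg.__dict__ | {"informative_bits": list(cfg.informative_bits)},
        "seed": cfg.seed,
        "content_hash": _content_hash(bits.tobytes().hex(), labels.tobytes().hex()),
    }
    return SimulatedFingerprintData(
        bits=bits,
        labels=labels,
        cluster_assignments=clusters,
        informative_bits=cfg.informative_bits,
        config=cfg,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# screening sets


@dataclass(frozen=True)
class ScreenSimConfig:
    """Active/decoy score simulation (location-shift normal model).

    Defaults mirror the real evaluation ledger's scale: 86 actives against
    4,449 presumed-inactives for N = 4,535; ``separation`` is the mean score
    gap between classes in units of their common unit spread. The default of
    1.4 SD places the top-1% enrichment of the simulated screen in the
    12-16x regime that well-performing consensus models reach on such a
    ledger; larger separations saturate BEDROC toward 1.
    """

    n_active: int = 86
    n_decoys: int = 4449
    separation: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys < self.n_active:
            raise ValueError("decoy-style imbalance requires n_decoys >= n_active")


def simulate_screen(config: ScreenSimConfig) -> RankedScreen:
    """Scores ~ N(separation, 1) for actives, N(0, 1) for decoys."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scores = np.concatenate(
        [rng.normal(cfg.separation, 1.0, cfg.n_active), rng.normal(0.0, 1.0, cfg.n_decoys)]
    )
    labels = np.concatenate(
        [np.ones(cfg.n_active, dtype=int), np.zeros(cfg.n_decoys, dtype=int)]
    )
    return RankedScreen(scores=scores, labels=labels)


def simulate_screening_ledger(
    n_eval: int = 178, n_eval_active: int = 86, n_decoys: int = 4357, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluation and decoy tables at the real ledger's scale.

    Emits an evaluation table (``smiles``, ``inchikey``, ``label``; 86 of 178
    rows active by default) and a disjoint decoy table, so the merged ledger
    holds n_eval + n_decoys unique entries (4,535 by default).
    """
    if n_eval_active > n_eval:
        raise ValueError("n_eval_active cannot exceed n_eval")
    rng = np.random.default_rng(seed)
    smiles = generate_smiles(n_eval + n_decoys)
    keys = [standardize_molecule(s).inchikey for s in smiles]
    labels = np.zeros(n_eval, dtype=int)
    labels[rng.choice(n_eval, n_eval_active, replace=False)] = 1
    eval_df = pd.DataFrame(
        {"smiles": smiles[:n_eval], "inchikey": keys[:n_eval], "label": labels}
    )
    decoy_df = pd.DataFrame(
        {"smiles": smiles[n_eval:], "inchikey": keys[n_eval:], "label": 0}
    )
    return eval_df, decoy_df


# ---------------------------------------------------------------------------
# plant association tables


@dataclass(frozen=True)
class PlantSimConfig:
    """Compound–plant association simulation with planted hot species.

    ``hot_species`` maps planted species names to the number of consensus-hit
    compounds they carry; hits occur nowhere else, so the planted counts are
    the exact ground truth. A ``nonplant_fraction`` of species receive
    non-plant lineages in the dump and must be excluded downstream;
    ``n_enantiomer_pairs`` compounds are emitted twice as mirror images under
    one species to exercise deduplication.
    """

    n_species: int = 40
    n_compounds: int = 120
    association_density: float = 0.05
    hot_species: tuple[tuple[str, int], ...] | None = None
    nonplant_fraction: float = 0.1
    n_enantiomer_pairs: int = 5
    n_sources: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.association_density <= 1:
            raise ValueError("association_density must lie in (0, 1]")
        total_hot = sum(k for _, k in self.resolved_hot_species())
        if total_hot > self.n_compounds:
            raise ValueError("planted hit counts exceed the compound universe")

    def resolved_hot_species(self) -> tuple[tuple[str, int], ...]:
        if self.hot_species is not None:
            return self.hot_species
        return (("Planta species0", 5), ("Herba species1", 2))


@dataclass
class SimulatedPlantData:
    """Association tables, lineage dump, and the planted ground truth."""

    tables: list[pd.DataFrame]  # columns: species, smiles, source
    lineage_lines: list[str]
    hit_keys: set  # InChIKeys of planted consensus hits
    score_maps: dict[str, dict]  # consensus model -> {inchikey: probability}
    species_hit_counts: dict[str, int]  # planted per-species unique hit counts
    genus_hit_counts: dict[str, int]  # planted per-genus unique hit compounds
    nonplant_species: set
    enantiomer_species: str
    n_plant_species: int
    manifest: dict = field(default_factory=dict)


def simulate_plant_tables(config: PlantSimConfig) -> SimulatedPlantData:
    """Emit association tables, a lineage dump, and the planted hit list."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_nonplant = int(round(cfg.nonplant_fraction * cfg.n_species))
    n_plant = cfg.n_species - n_nonplant
    plant_species = [
        f"{PLANT_GENERA[i % len(PLANT_GENERA)]} species{i}" for i in range(n_plant)
    ]
    nonplant_species = [
        f"{NONPLANT_GENERA[i % len(NONPLANT_GENERA)]} impostor{i}"
        for i in range(n_nonplant)
    ]
    hot = dict(cfg.resolved_hot_species())
    for name in hot:
        if name not in plant_species:
            plant_species.insert(0, name)

    lineage_lines = []
    for taxid, name in enumerate(plant_species, start=1000):
        lineage_lines.append(f"{taxid}\t|\t{name}\t|\t{PLANT_LINEAGE}; {name.split()[0]}\t|")
    for taxid, name in enumerate(nonplant_species, start=9000):
        lineage_lines.append(f"{taxid}\t|\t{name}\t|\t{NONPLANT_LINEAGE}\t|")

    smiles = generate_smiles(cfg.n_compounds)
    keys = [standardize_molecule(s).inchikey for s in smiles]

    # hit compounds are assigned exclusively to the planted hot species
    n_hits_total = sum(hot.values())
    hit_pool = list(rng.choice(cfg.n_compounds, n_hits_total, replace=False))
    hit_keys: set = set()
    species_hit_counts: dict[str, int] = {}
    associations: list[tuple[str, str]] = []  # (species, smiles)
    cursor = 0
    for name, count in hot.items():
        assigned = hit_pool[cursor : cursor + count]
        cursor += count
        species_hit_counts[name] = count
        for ci in assigned:
            associations.append((name, smiles[ci]))
            hit_keys.add(keys[ci])

    nonhit_indices = [i for i in range(cfg.n_compounds) if i not in set(hit_pool)]
    for name in plant_species + nonplant_species:
        n_draw = rng.binomial(len(nonhit_indices), cfg.association_density)
        n_draw = max(n_draw, 1)
        for ci in rng.choice(nonhit_indices, n_draw, replace=False):
            associations.append((name, smiles[ci]))

    # enantiomer duplicates under the first hot species
    enantiomer_species = next(iter(hot))
    for j in range(cfg.n_enantiomer_pairs):
        tail = "C" * (j + 2)
        left, right = enantiomer_pair(tail)
        associations.append((enantiomer_species, left))
        associations.append((enantiomer_species, right))

    # per-genus unique hit compounds (ground truth for grouping summaries)
    genus_hits: dict[str, set] = {}
    for name, count in hot.items():
        genus_hits.setdefault(name.split()[0], set())
    for (name, smi) in associations:
        key = standardize_molecule(smi).inchikey
        if key in hit_keys:
            genus_hits.setdefault(name.split()[0], set()).add(key)
    genus_hit_counts = {g: len(s) for g, s in genus_hits.items()}

    # consensus scores: hits comfortably above 0.55 in both models
    score_maps: dict[str, dict] = {"C1": {}, "C2": {}}
    for k in sorted(set(keys) | hit_keys):
        if k in hit_keys:
            score_maps["C1"][k] = float(rng.uniform(0.56, 0.9))
            score_maps["C2"][k] = float(rng.uniform(0.56, 0.9))
        else:
            score_maps["C1"][k] = float(rng.uniform(0.0, 0.5))
            score_maps["C2"][k] = float(rng.uniform(0.0, 0.5))

    # scatter associations across pseudo-source tables, duplicating a few
    # records between sources (cross-database overlap)
    frames: list[list[dict]] = [[] for _ in range(cfg.n_sources)]
    for (name, smi) in associations:
        t = int(rng.integers(cfg.n_sources))
        frames[t].append({"species": name, "smiles": smi, "source": f"srcdb{t}"})
        if rng.random() < 0.1:
            t2 = int(rng.integers(cfg.n_sources))
            frames[t2].append({"species": name, "smiles": smi, "source": f"srcdb{t2}"})
    tables = [
        pd.DataFrame(rows, columns=["species", "smiles", "source"]) for rows in frames
    ]

    manifest = {
        "config": {
            **{k: v for k, v in cfg.__dict__.items() if k != "hot_species"},
            "hot_species": dict(cfg.resolved_hot_species()),
        },
        "seed": cfg.seed,
        "content_hash": _content_hash(
            "\n".join(lineage_lines), *(t.to_csv(index=False) for t in tables)
        ),
    }
    return SimulatedPlantData(
        tables=tables,
        lineage_lines=lineage_lines,
        hit_keys=hit_keys,
        score_maps=score_maps,
        species_hit_counts=species_hit_counts,
        genus_hit_counts=genus_hit_counts,
        nonplant_species=set(nonplant_species),
        enantiomer_species=enantiomer_species,
        n_plant_species=len(plant_species),
        manifest=manifest,
    )
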