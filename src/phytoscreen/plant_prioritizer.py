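"""Compound–plant associations, taxonomy filtering, and species ranking.

Plant names are resolved against an NCBI-style lineage dump (the
``fullnamelineage.dmp`` dialect: ``taxid | name | lineage |`` with
tab-pipe-tab separators); only names whose lineage contains the green-plant
clade (Viridiplantae) are retained, so processed-food entries and non-plant
organisms drop out. Compound links are keyed by the achiral standardized
InChIKey, collapsing enantiomers reported under the same species to one
association. Species are then ranked by how many of their compounds appear
in the consensus hit set, both absolutely and as a fraction of the species'
reported compounds.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .chem_curation import StandardizedMolecule, standardize_molecule

logger = logging.getLogger(__name__)

PLANT_CLADE = "Viridiplantae"
DEFAULT_MIN_ACTIVE_FILTERS = (1, 2, 5)


def _norm_name(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass
class TaxonomyIndex:
    """Case-normalized plant-name lookup built from a lineage dump."""

    entries: dict[str, tuple[int, str]]  # normalized name -> (taxid, lineage)
    n_skipped: int = 0
    n_nonplant: int = 0

    def resolve(self, name: str) -> tuple[int, str] | None:
        return self.entries.get(_norm_name(name))

    def __len__(self) -> int:
        return len(self.entries)


def build_taxonomy_index(lineage_source) -> TaxonomyIndex:
    """Parse a ``fullnamelineage.dmp``-dialect file into a plant-name index.

    ``lineage_source`` may be a path or an iterable of lines. Records whose
    lineage lacks the Viridiplantae marker are dropped (counted); malformed
    lines are skipped (counted).
    """
    if isinstance(lineage_source, str):
        with open(lineage_source) as fh:
            lines = fh.readlines()
    else:
        lines = list(lineage_source)
    entries: dict[str, tuple[int, str]] = {}
    skipped = nonplant = 0
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("|")]
        # trailing separator leaves an empty final field
        if parts and parts[-1] == "":
            parts = parts[:-1]
        if len(parts) != 3:
            skipped += 1
            continue
        taxid_s, name, lineage = parts
        try:
            taxid = int(taxid_s)
        except ValueError:
            skipped += 1
            continue
        if PLANT_CLADE not in lineage:
            nonplant += 1
            continue
        entries[_norm_name(name)] = (taxid, lineage)
    if skipped:
        logger.warning("taxonomy dump: %d malformed lines skipped", skipped)
    return TaxonomyIndex(entries, n_skipped=skipped, n_nonplant=nonplant)


@dataclass
class AssociationSet:
    """Unique (species, compound) links plus merge accounting."""

    table: pd.DataFrame  # columns: species, inchikey, canonical_smiles
    n_species: int
    n_compounds: int
    n_associations: int
    n_unresolved: int = 0
    n_invalid: int = 0
    n_duplicates: int = 0


def merge_compound_plant_tables(
    tables: list[pd.DataFrame], index: TaxonomyIndex
) -> AssociationSet:
    """Standardize, taxonomy-filter, and deduplicate association tables.

    Each table needs ``species`` and ``smiles`` columns. Records whose name
    does not resolve in the plant index are excluded; enantiomers of one
    compound under one species collapse to a single association.
    """
    std_cache: dict[str, StandardizedMolecule] = {}
    seen: set[tuple[str, str]] = set()
    rows = []
    n_unresolved = n_invalid = n_dup = 0
    for table in tables:
        for _, rec in table.iterrows():
            name = str(rec["species"])
            if index.resolve(name) is None:
                n_unresolved += 1
                continue
            smi = str(rec["smiles"])
            if smi not in std_cache:
                std_cache[smi] = standardize_molecule(smi)
            mol = std_cache[smi]
            if not mol.valid:
                n_invalid += 1
                continue
            key = (_norm_name(name), mol.inchikey)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            rows.append(
                {
                    "species": name.strip(),
                    "species_norm": key[0],
                    "inchikey": mol.inchikey,
                    "canonical_smiles": mol.canonical_smiles,
                }
            )
    if not rows:
        raise ValueError(
            f"no associations survived merging ({n_unresolved} unresolved names, "
            f"{n_invalid} invalid molecules)"
        )
    df = pd.DataFrame(rows)
    return AssociationSet(
        table=df,
        n_species=df["species_norm"].nunique(),
        n_compounds=df["inchikey"].nunique(),
        n_associations=len(df),
        n_unresolved=n_unresolved,
        n_invalid=n_invalid,
        n_duplicates=n_dup,
    )


@dataclass
class SpeciesRanking:
    """Per-species predicted-active content, in two sort orders."""

    by_count: pd.DataFrame  # sorted by n_active desc (absolute view)
    by_fraction: pd.DataFrame  # sorted by fraction desc (relative view)
    filter_tallies: dict[int, int] = field(default_factory=dict)


def rank_species(
    associations: AssociationSet | pd.DataFrame,
    hit_set: set | dict,
    min_active_filters: tuple[int, ...] = DEFAULT_MIN_ACTIVE_FILTERS,
    score_maps: dict[str, dict] | None = None,
) -> SpeciesRanking:
    """Rank species by predicted-active compound content.

    ``hit_set`` holds the InChIKeys of consensus hits (a dict is treated as
    key -> score). A compound's hit status is global, not species-specific.
    ``score_maps`` optionally maps a consensus-model name to a per-compound
    probability map; per-species means over linked hit compounds are then
    reported. Tallies count species with n_active >= each filter value.
    """
    df = associations.table if isinstance(associations, AssociationSet) else associations
    hits = set(hit_set)
    rows = []
    for species, group in df.groupby("species_norm", sort=True):
        compounds = set(group["inchikey"])
        active = compounds & hits
        row = {
            "species": group["species"].iloc[0],
            "n_total": len(compounds),
            "n_active": len(active),
            "fraction": len(active) / len(compounds),
        }
        for model_name, scores in (score_maps or {}).items():
            vals = [scores[k] for k in active if k in scores]
            row[f"mean_prob_{model_name}"] = (
                sum(vals) / len(vals) if vals else float("nan")
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    by_count = table.sort_values(
        ["n_active", "fraction", "species"], ascending=[False, False, True]
    ).reset_index(drop=True)
    by_fraction = table.sort_values(
        ["fraction", "n_active", "species"], ascending=[False, False, True]
    ).reset_index(drop=True)
    tallies = {
        f: int((table["n_active"] >= f).sum()) for f in min_active_filters
    }
    return SpeciesRanking(by_count=by_count, by_fraction=by_fraction, filter_tallies=tallies)


def default_grouping(species: str) -> str:
    """Genus = first token of the binomial name."""
    return str(species).strip().split()[0]


def summarize_by_group(
    associations: AssociationSet | pd.DataFrame,
    hit_set: set | dict,
    grouping: dict[str, str] | None = None,
    class_annotations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Unique hit compounds per group (genus by default).

    ``grouping`` maps species name to a group label; unmapped species fall
    back to the first binomial token. With ``class_annotations`` (compound
    key -> chemical class, supplied externally), the per-group class
    composition of the hits is reported as fractions.
    """
    df = associations.table if isinstance(associations, AssociationSet) else associations
    hits = set(hit_set)
    group_hits: dict[str, set] = defaultdict(set)
    for _, rec in df.iterrows():
        if rec["inchikey"] not in hits:
            continue
        species = rec["species"]
        group = (grouping or {}).get(species, default_grouping(species))
        group_hits[group].add(rec["inchikey"])
    rows = []
    for group in sorted(group_hits):
        compounds = group_hits[group]
        row = {"group": group, "n_hit_compounds": len(compounds)}
        if class_annotations:
            counts: dict[str, int] = defaultdict(int)
            for k in compounds:
                counts[class_annotations.get(k, "unclassified")] += 1
            total = sum(counts.values())
            row["class_composition"] = {
                cls: cnt / total for cls, cnt in sorted(counts.items())
            }
        rows.append(row)
    return pd.DataFrame(rows)
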