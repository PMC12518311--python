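"""Curation of compound–cell-line activity records.

Raw records (SMILES, cell line, IC50 in µM) are standardized, labeled
active/inactive against a 10 µM cutoff, checked for replicate consistency,
and partitioned into per-cell-line training pools versus a reserved
virtual-screening set (molecules measured in three or more cell lines).

Molecule standardization strips stereochemistry (enantiomers collapse to one
entry), keeps the largest covalent fragment, sanitizes, and keys every
molecule by the InChIKey of the resulting achiral canonical form.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import inchi

RDLogger.DisableLog("rdApp.*")

DEFAULT_CELL_LINES = ("AGS", "NCI-N87", "BGC-823", "SNU-16")
ACTIVITY_THRESHOLD_UM = 10.0

#: rejection reason codes emitted by :func:`standardize_molecule`
REASON_EMPTY = "empty_input"
REASON_PARSE = "parse_failure"
REASON_SANITIZE = "sanitize_failure"
REASON_INCHI = "inchi_failure"


@dataclass(frozen=True)
class ActivityRecord:
    """One raw compound–cell-line–IC50 measurement (IC50 in µM, > 0)."""

    smiles: str
    cell_line: str
    ic50: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50!r}")


@dataclass(frozen=True)
class StandardizedMolecule:
    """Achiral canonical SMILES plus InChIKey; ``valid`` is False on rejection."""

    canonical_smiles: str | None
    inchikey: str | None
    valid: bool
    reason: str | None = None


@dataclass(frozen=True)
class LabeledCompound:
    molecule: StandardizedMolecule
    cell_line: str
    label: str  # "active" | "inactive"
    n_reports: int


def standardize_molecule(smiles: str) -> StandardizedMolecule:
    """Sanitize, keep the largest fragment, strip chirality, canonicalize.

    Enantiomeric inputs map to identical canonical SMILES and InChIKey.
    Unparsable input yields ``valid=False`` with a reason code; callers log
    and drop such records, never keep them silently.
    """
    if not smiles or not smiles.strip():
        return StandardizedMolecule(None, None, False, REASON_EMPTY)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizedMolecule(None, None, False, REASON_PARSE)
    try:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        # largest covalent fragment by heavy-atom count (salt/solvent stripping)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        Chem.RemoveStereochemistry(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return StandardizedMolecule(None, None, False, REASON_SANITIZE)
    canonical = Chem.MolToSmiles(mol)
    key = inchi.MolToInchiKey(mol)
    if not key:
        return StandardizedMolecule(None, None, False, REASON_INCHI)
    return StandardizedMolecule(canonical, key, True, None)


def classify_activity(ic50: float, threshold: float = ACTIVITY_THRESHOLD_UM) -> str:
    """Label an IC50 (µM): active iff strictly below the threshold.

    Values exactly at the threshold fall to "inactive" (the active class is
    defined strictly as IC50 < threshold).
    """
    if not ic50 > 0:
        raise ValueError(f"ic50 must be positive, got {ic50!r}")
    return "active" if ic50 < threshold else "inactive"


def resolve_replicates(
    records: list[ActivityRecord],
    threshold: float = ACTIVITY_THRESHOLD_UM,
    molecule: StandardizedMolecule | None = None,
) -> LabeledCompound | None:
    """Collapse replicate measurements of one molecule in one cell line.

    The pair is kept only when every replicate falls in the same activity
    class; class disagreement excludes the pair (returns None). Values are
    never averaged — consistency is judged on classes alone.
    """
    if not records:
        raise ValueError("resolve_replicates requires at least one record")
    cell_lines = {r.cell_line for r in records}
    if len(cell_lines) != 1:
        raise ValueError(f"records span multiple cell lines: {sorted(cell_lines)}")
    if molecule is None:
        molecule = standardize_molecule(records[0].smiles)
        if not molecule.valid:
            raise ValueError(f"unstandardizable molecule: {molecule.reason}")
    labels = {classify_activity(r.ic50, threshold) for r in records}
    if len(labels) > 1:
        return None
    return LabeledCompound(molecule, records[0].cell_line, labels.pop(), len(records))


def partition_training_vs_screening(
    compounds: list[LabeledCompound],
) -> tuple[dict[str, list[LabeledCompound]], list[LabeledCompound]]:
    """Split labeled compounds into per-cell-line pools and a reserved set.

    Molecules with retained labels in >= 3 distinct cell lines go only to the
    reserved virtual-screening set; everything else feeds its cell lines'
    training pools. The two sides are disjoint by InChIKey.
    """
    by_key: dict[str, set[str]] = defaultdict(set)
    for c in compounds:
        by_key[c.molecule.inchikey].add(c.cell_line)
    pools: dict[str, list[LabeledCompound]] = defaultdict(list)
    reserved: list[LabeledCompound] = []
    for c in compounds:
        if len(by_key[c.molecule.inchikey]) >= 3:
            reserved.append(c)
        else:
            pools[c.cell_line].append(c)
    return dict(pools), reserved


@dataclass
class CurationResult:
    """Full accounting of a curation run over a raw activity table."""

    pools: dict[str, list[LabeledCompound]]
    reserved: list[LabeledCompound]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)
    n_input: int = 0

    @property
    def n_kept(self) -> int:
        return sum(c.n_reports for pool in self.pools.values() for c in pool)

    @property
    def n_reserved(self) -> int:
        return sum(c.n_reports for c in self.reserved)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_kept - self.n_reserved

    def pool_table(self, cell_line: str) -> pd.DataFrame:
        rows = [
            {
                "inchikey": c.molecule.inchikey,
                "canonical_smiles": c.molecule.canonical_smiles,
                "cell_line": c.cell_line,
                "label": c.label,
                "n_reports": c.n_reports,
            }
            for c in self.pools.get(cell_line, [])
        ]
        return pd.DataFrame(
            rows,
            columns=["inchikey", "canonical_smiles", "cell_line", "label", "n_reports"],
        )


def read_activity_table(path_or_buffer) -> pd.DataFrame:
    """Read a delimited activity table (comma or tab auto-detected).

    Requires header columns smiles, cell_line, ic50_um; source is optional.
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python")
    missing = {"smiles", "cell_line", "ic50_um"} - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    return df


def curate_activity_table(
    table: pd.DataFrame | str | io.IOBase,
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES,
    threshold: float = ACTIVITY_THRESHOLD_UM,
) -> CurationResult:
    """Run the full curation pipeline on a raw activity table.

    Every input row is accounted for exactly once: kept in a training pool,
    reserved for screening, or excluded with a reason in ``exclusion_log``
    (invalid molecule, unknown cell line, non-positive IC50, or replicate
    class disagreement).
    """
    if not isinstance(table, pd.DataFrame):
        table = read_activity_table(table)
    log: list[tuple[str, str]] = []
    std_cache: dict[str, StandardizedMolecule] = {}
    groups: dict[tuple[str, str], list[ActivityRecord]] = defaultdict(list)
    group_mol: dict[tuple[str, str], StandardizedMolecule] = {}

    for _, row in table.iterrows():
        smi = str(row["smiles"]) if pd.notna(row["smiles"]) else ""
        cell = str(row["cell_line"])
        if cell not in cell_lines:
            log.append((smi, f"unknown_cell_line:{cell}"))
            continue
        try:
            ic50 = float(row["ic50_um"])
        except (TypeError, ValueError):
            ic50 = float("nan")
        if not ic50 > 0:
            log.append((smi, "nonpositive_ic50"))
            continue
        if smi not in std_cache:
            std_cache[smi] = standardize_molecule(smi)
        mol = std_cache[smi]
        if not mol.valid:
            log.append((smi, mol.reason or "invalid"))
            continue
        key = (mol.inchikey, cell)
        groups[key].append(ActivityRecord(smi, cell, ic50, str(row.get("source", ""))))
        group_mol[key] = mol

    labeled: list[LabeledCompound] = []
    for key in sorted(groups):
        recs = groups[key]
        compound = resolve_replicates(recs, threshold, molecule=group_mol[key])
        if compound is None:
            for r in recs:
                log.append((r.smiles, "inconsistent_replicates"))
        else:
            labeled.append(compound)

    pools, reserved = partition_training_vs_screening(labeled)
    return CurationResult(pools, reserved, log, n_input=len(table))


def write_exclusion_log(result: CurationResult, path: str) -> None:
    with open(path, "w") as fh:
        for smi, reason in result.exclusion_log:
            fh.write(f"{reason}\t{smi}\n")
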