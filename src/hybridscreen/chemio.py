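"""Molecule I/O: SMILES tables, SDF files, standardization and deduplication.

Every molecule entering the pipeline passes through this module, so a single
canonicalization dialect (RDKit canonical SMILES, stereo retained) is used
everywhere — in particular as the deduplication key.  Multi-component inputs
(salts, mixtures) are reduced to their largest organic component before
canonicalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import SDWriter

logger = logging.getLogger("hybridscreen")


class ConfigurationError(ValueError):
    """A required column, key or parameter is missing or invalid."""


class InputError(ValueError):
    """The input data itself is unusable (empty, single-class, no conformer...)."""


@dataclass
class MoleculeRecord:
    """A molecule with its canonical SMILES and optional 3D conformer / label.

    ``mol`` always carries implicit hydrogens in the graph; if the source SDF
    contained explicit hydrogens their coordinates are kept on the conformer.
    """

    id: str
    smiles: str
    mol: Chem.Mol
    label: Optional[int] = None
    provenance: str = ""

    @property
    def conformer(self) -> Optional[np.ndarray]:
        """(n_atoms, 3) coordinates in Å, or None for a 2D record."""
        if self.mol.GetNumConformers() == 0:
            return None
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


def canonical_smiles(mol: Chem.Mol) -> str:
    """Stereo-aware RDKit canonical SMILES — the one dialect used package-wide."""
    return Chem.MolToSmiles(mol, canonical=True, isomericSmiles=True)


def strip_to_largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Keep the largest organic component of a multi-fragment molecule.

    Returns (molecule, stripped?) where stripped is True when counterions or
    co-fragments were removed.  Largest = most heavy atoms; ties broken by
    canonical SMILES for determinism.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol, False
    best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return best, True


def _parse_smiles(smiles: str) -> Optional[Chem.Mol]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol, stripped = strip_to_largest_fragment(mol)
    if stripped:
        logger.debug("stripped counterion/co-fragment from %s", smiles)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return None
    return mol


def read_smiles_table(
    path,
    smiles_col: str = "smiles",
    id_col: str = "id",
    label_col: Optional[str] = "label",
) -> tuple[list[MoleculeRecord], int]:
    """Read a labelled (or unlabelled) SMILES CSV into records.

    Unparseable SMILES are skipped, never silently: the skip count is the
    second return value and ``records + skipped == rows``.

    Raises
    ------
    ConfigurationError
        if ``smiles_col`` is absent from the header.
    InputError
        if no row parses.
    """
    df = pd.read_csv(path, dtype={smiles_col: str} if smiles_col else None)
    if smiles_col not in df.columns:
        raise ConfigurationError(
            f"column {smiles_col!r} not found in {path} (columns: {list(df.columns)})"
        )
    has_id = id_col in df.columns
    has_label = label_col is not None and label_col in df.columns

    records: list[MoleculeRecord] = []
    skipped = 0
    for i, row in df.iterrows():
        mol = _parse_smiles(str(row[smiles_col]))
        if mol is None:
            skipped += 1
            logger.warning("skipping unparseable SMILES at row %d: %r", i, row[smiles_col])
            continue
        label = None
        if has_label and not pd.isna(row[label_col]):
            label = int(row[label_col])
            if label not in (0, 1):
                raise InputError(f"label must be 0 or 1, got {label!r} at row {i}")
        rec_id = str(row[id_col]) if has_id else f"row{i}"
        records.append(
            MoleculeRecord(
                id=rec_id,
                smiles=canonical_smiles(mol),
                mol=mol,
                label=label,
                provenance=str(path),
            )
        )
    if not records:
        raise InputError(f"no parseable SMILES in {path}")
    return records, skipped


def read_sdf(path) -> list[MoleculeRecord]:
    """Read a V2000 SDF; 3D coordinates are kept exactly as written.

    No re-embedding, no alignment, no hydrogen addition.  Corrupt molblocks
    are skipped with a warning; an SDF yielding zero molecules is an error.
    """
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    except OSError as exc:
        raise InputError(f"cannot read SDF {path}: {exc}") from exc
    records: list[MoleculeRecord] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"skipping corrupt molblock #{i} in {path}")
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        records.append(
            MoleculeRecord(
                id=name,
                smiles=canonical_smiles(mol),
                mol=mol,
                label=int(mol.GetProp("label")) if mol.HasProp("label") else None,
                provenance=str(path),
            )
        )
    if not records:
        raise InputError(f"no molecules read from {path}")
    return records


def write_sdf(records: Sequence[MoleculeRecord], path) -> None:
    """Write records (with conformers where present) to a V2000 SDF."""
    if not records:
        raise InputError("refusing to write an empty SDF")
    writer = SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            if rec.label is not None:
                mol.SetProp("label", str(rec.label))
            writer.write(mol)
    finally:
        writer.close()


#: stable column order for screening output tables
SCREENING_COLUMNS = [
    "id",
    "smiles",
    "probability",
    "max_tanimoto",
    "qed",
    "sa",
    "pass_activity",
    "pass_ad",
    "pass_qed",
    "pass_sa",
    "final_pass",
]


def write_table(records: Sequence, path) -> None:
    """Write MoleculeRecords or ScreeningRecords to CSV with a stable header.

    MoleculeRecords produce (id, smiles[, label]); ScreeningRecords produce the
    documented funnel column order.
    """
    if not records:
        raise InputError("refusing to write an empty table")
    first = records[0]
    if hasattr(first, "final_pass"):  # triage.ScreeningRecord, avoids circular import
        rows = [{c: getattr(r, c) for c in SCREENING_COLUMNS} for r in records]
        df = pd.DataFrame(rows, columns=SCREENING_COLUMNS)
    else:
        rows = [{"id": r.id, "smiles": r.smiles, "label": r.label} for r in records]
        df = pd.DataFrame(rows, columns=["id", "smiles", "label"])
        if df["label"].isna().all():
            df = df.drop(columns=["label"])
    df.to_csv(path, index=False)


def deduplicate(records: Iterable[MoleculeRecord]) -> tuple[list[MoleculeRecord], int]:
    """One record per canonical SMILES; first occurrence wins.

    Idempotent.  Returns (unique records, number removed).
    """
    seen: set[str] = set()
    kept: list[MoleculeRecord] = []
    removed = 0
    for rec in records:
        if rec.smiles in seen:
            removed += 1
            continue
        seen.add(rec.smiles)
        kept.append(rec)
    return kept, removed
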