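"""BREED-style fragment hybridization of binding-site-aligned 3D ligands.

Given two or more ligands sharing one coordinate frame (e.g. co-crystallized
or docked into the same pocket), every acyclic single bond between heavy atoms
is a potential cut site.  When a cut bond of ligand A superimposes onto a cut
bond of ligand B — both endpoints within ``d_max`` Å and the bond vectors
within ``theta_max`` degrees — the fragments on either side can be swapped,
producing hybrid molecules that inherit the parents' binding geometry.

The module is fully deterministic: no randomness anywhere, output sorted by
canonical SMILES.  Ligands are ASSUMED pre-aligned; a convenience rigid
MCS-based aligner (`align_to_reference`) exists but is never invoked
implicitly, because vector matching across unrelated frames is meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS

from .chemio import InputError, MoleculeRecord, canonical_smiles


class DegenerateGeometryError(ValueError):
    """A bond vector has (near-)zero length; the angle test is undefined."""


@dataclass
class HybridizationParams:
    """Geometric and chemical tolerances governing fragment recombination.

    d_max
        Maximum displacement (Å) allowed between the paired endpoints of two
        cut bonds; applied to BOTH endpoints, boundary inclusive.
    theta_max
        Maximum angle (degrees) between the two bond vectors, inclusive.
    min_fragment_heavy_atoms
        A bond is cuttable only if both resulting fragments keep at least this
        many heavy atoms; guards against swapping trivial caps.
    generations
        Number of hybridization cycles; hybrids of cycle g join the pool of
        cycle g+1.
    untangle
        If true, hybrids get a short constrained force-field relaxation to
        resolve junction clashes (topology is never altered).
    displacement_mode
        "endpoint" (default, stricter): both endpoint distances ≤ d_max.
        "midpoint": the distance between bond midpoints ≤ d_max.
    """

    d_max: float = 1.0
    theta_max: float = 15.0
    min_fragment_heavy_atoms: int = 3
    generations: int = 1
    untangle: bool = False
    displacement_mode: str = "endpoint"

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 <= self.theta_max <= 180:
            raise ValueError("theta_max must be in [0, 180]")
        if self.min_fragment_heavy_atoms < 1:
            raise ValueError("min_fragment_heavy_atoms must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.displacement_mode not in ("endpoint", "midpoint"):
            raise ValueError("displacement_mode must be 'endpoint' or 'midpoint'")


@dataclass
class CuttableBond:
    """A directed acyclic single bond a→b with its 3D endpoints.

    Each physical bond appears twice (a→b and b→a), so that every fragment
    orientation is considered exactly once during cross-ligand pairing.
    """

    parent_id: str
    atom_a: int
    atom_b: int
    pos_a: np.ndarray
    pos_b: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return self.pos_b - self.pos_a


@dataclass
class HybridMolecule(MoleculeRecord):
    parent_head_id: str = ""
    parent_tail_id: str = ""
    junction: tuple[int, int] = (0, 0)
    displacement: float = 0.0
    angle: float = 0.0
    untangle_failed: bool = False


@dataclass
class GenerationReport:
    pairs_tested: int = 0
    matches: int = 0
    valence_drops: int = 0
    duplicates_removed: int = 0
    novel_kept: int = 0
    generations_run: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# 1. fragmentation: enumerate cut sites
# ---------------------------------------------------------------------------

def _fragment_sizes(mol: Chem.Mol, bond_idx: int) -> tuple[int, int]:
    """Heavy-atom counts of the two sides of an acyclic bond (begin-side, end-side)."""
    bond = mol.GetBondWithIdx(bond_idx)
    begin = bond.GetBeginAtomIdx()
    # BFS from `begin` without crossing the bond
    seen = {begin}
    stack = [begin]
    blocked = {bond.GetEndAtomIdx()}
    while stack:
        a = stack.pop()
        for nb in mol.GetAtomWithIdx(a).GetNeighbors():
            j = nb.GetIdx()
            if j in seen or (a == begin and j in blocked):
                continue
            if j in blocked:
                continue
            seen.add(j)
            stack.append(j)
    n_heavy = mol.GetNumHeavyAtoms()
    side_a = sum(1 for i in seen if mol.GetAtomWithIdx(i).GetAtomicNum() > 1)
    return side_a, n_heavy - side_a


def enumerate_cuttable_bonds(
    ligand: MoleculeRecord, params: HybridizationParams
) -> list[CuttableBond]:
    """All directed cut sites of a ligand.

    A bond qualifies when it is a single-order, non-ring bond between two
    heavy atoms and its cleavage leaves both fragments with at least
    ``min_fragment_heavy_atoms`` heavy atoms.  Each qualifying bond yields two
    directed entries (a→b and b→a).
    """
    coords = ligand.conformer
    if coords is None:
        raise InputError(f"ligand {ligand.id} has no conformer")
    mol = ligand.mol
    out: list[CuttableBond] = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        na, nb = _fragment_sizes(mol, bond.GetIdx())
        if min(na, nb) < params.min_fragment_heavy_atoms:
            continue
        ai, bi = a.GetIdx(), b.GetIdx()
        out.append(CuttableBond(ligand.id, ai, bi, coords[ai].copy(), coords[bi].copy()))
        out.append(CuttableBond(ligand.id, bi, ai, coords[bi].copy(), coords[ai].copy()))
    return out


# ---------------------------------------------------------------------------
# 2. geometric matching of cut-bond vectors
# ---------------------------------------------------------------------------

def match_bond_vectors(
    bond_i: CuttableBond, bond_j: CuttableBond, params: HybridizationParams
) -> tuple[bool, float, float]:
    """Test whether two directed cut bonds superimpose within tolerance.

    Pairing is directed — a(i)↔a(j) and b(i)↔b(j); the reversed pairing is
    covered because both bond directions are enumerated upstream.  Both
    boundary tests are inclusive (≤).

    Returns (accept, displacement, angle) where displacement is the larger of
    the two endpoint distances (or the midpoint distance in midpoint mode) and
    angle is in degrees.
    """
    vi, vj = bond_i.vector, bond_j.vector
    ni, nj = float(np.linalg.norm(vi)), float(np.linalg.norm(vj))
    if ni < 1e-9 or nj < 1e-9:
        raise DegenerateGeometryError("zero-length bond vector")
    cosang = float(np.dot(vi, vj) / (ni * nj))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    if params.displacement_mode == "midpoint":
        disp = float(np.linalg.norm((bond_i.pos_a + bond_i.pos_b) / 2
                                    - (bond_j.pos_a + bond_j.pos_b) / 2))
    else:
        da = float(np.linalg.norm(bond_i.pos_a - bond_j.pos_a))
        db = float(np.linalg.norm(bond_i.pos_b - bond_j.pos_b))
        disp = max(da, db)
    accept = disp <= params.d_max and angle <= params.theta_max
    return accept, disp, angle


# ---------------------------------------------------------------------------
# 3. recombination
# ---------------------------------------------------------------------------

def _join_fragments(
    mol_head: Chem.Mol,
    keep_head: int,
    drop_head: int,
    mol_tail: Chem.Mol,
    drop_tail: int,
    keep_tail: int,
) -> Optional[Chem.Mol]:
    """Cut head and tail molecules at the given bonds and join the head-side
    fragment of the first to the tail-side fragment of the second with a new
    single bond.  Coordinates are carried over unchanged.  Returns None when
    the assembly fails sanitization (e.g. valence violation at the junction).
    """
    combo = Chem.RWMol(Chem.CombineMols(mol_head, mol_tail))
    off = mol_head.GetNumAtoms()
    combo.RemoveBond(keep_head, drop_head)
    combo.RemoveBond(drop_tail + off, keep_tail + off)
    frags = Chem.GetMolFrags(combo)
    keep_atoms: set[int] = set()
    for frag in frags:
        if keep_head in frag or (keep_tail + off) in frag:
            keep_atoms.update(frag)
    if drop_head in keep_atoms or (drop_tail + off) in keep_atoms:
        # the two cut atoms ended up connected through another path; should be
        # impossible for acyclic bonds, but guard anyway
        return None
    to_remove = sorted((i for i in range(combo.GetNumAtoms()) if i not in keep_atoms),
                       reverse=True)
    for idx in to_remove:
        combo.RemoveAtom(idx)
    # index shift after removals
    removed = np.array(to_remove)
    new_head = keep_head - int(np.sum(removed < keep_head))
    new_tail = (keep_tail + off) - int(np.sum(removed < keep_tail + off))
    combo.AddBond(new_head, new_tail, Chem.BondType.SINGLE)
    # junction configuration is ambiguous after the swap: clear stereo there
    for idx in (new_head, new_tail):
        combo.GetAtomWithIdx(idx).SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def recombine(
    bond_i: CuttableBond,
    bond_j: CuttableBond,
    ligand_a: MoleculeRecord,
    ligand_b: MoleculeRecord,
    displacement: float = 0.0,
    angle: float = 0.0,
) -> tuple[list[HybridMolecule], int]:
    """Swap fragments across a matched bond pair.

    Produces up to two hybrids: (head of A + tail of B) and the complementary
    (head of B + tail of A).  Assemblies that fail valence sanitization are
    dropped and counted.  Returns (hybrids, n_dropped).
    """
    hybrids: list[HybridMolecule] = []
    dropped = 0
    combos = [
        (ligand_a, bond_i, ligand_b, bond_j),
        (ligand_b, bond_j, ligand_a, bond_i),
    ]
    for head_rec, hb, tail_rec, tb in combos:
        mol = _join_fragments(head_rec.mol, hb.atom_a, hb.atom_b,
                              tail_rec.mol, tb.atom_a, tb.atom_b)
        if mol is None:
            dropped += 1
            continue
        smi = canonical_smiles(mol)
        hybrids.append(
            HybridMolecule(
                id=f"{head_rec.id}|{tail_rec.id}",
                smiles=smi,
                mol=mol,
                provenance="hybridize",
                parent_head_id=head_rec.id,
                parent_tail_id=tail_rec.id,
                junction=(hb.atom_a, tb.atom_b),
                displacement=displacement,
                angle=angle,
            )
        )
    return hybrids, dropped


# ---------------------------------------------------------------------------
# 4. library generation
# ---------------------------------------------------------------------------

def generate_library(
    ligands: Sequence[MoleculeRecord], params: HybridizationParams
) -> tuple[list[HybridMolecule], GenerationReport]:
    """Hybridize every ordered cross-ligand bond pairing; dedup; sort.

    Hybrids are deduplicated by canonical SMILES against both each other and
    the parent structures.  With ``generations > 1`` the output of each cycle
    joins the input pool of the next.  Output order is sorted by canonical
    SMILES, making the whole procedure deterministic.
    """
    if len(ligands) < 2:
        raise InputError("hybridization needs at least 2 aligned ligands")
    report = GenerationReport()
    parent_smiles = {rec.smiles for rec in ligands}
    pool: list[MoleculeRecord] = list(ligands)
    kept: dict[str, HybridMolecule] = {}

    for gen in range(params.generations):
        report.generations_run = gen + 1
        bonds = {id(rec): enumerate_cuttable_bonds(rec, params) for rec in pool}
        new_this_gen: dict[str, HybridMolecule] = {}
        for a_idx, rec_a in enumerate(pool):
            for b_idx, rec_b in enumerate(pool):
                if a_idx == b_idx:
                    continue
                for bi in bonds[id(rec_a)]:
                    for bj in bonds[id(rec_b)]:
                        report.pairs_tested += 1
                        accept, disp, ang = match_bond_vectors(bi, bj, params)
                        if not accept:
                            continue
                        report.matches += 1
                        # head from A, tail from B; the complementary hybrid is
                        # produced when the ordered pair (B, A) comes up
                        mol = _join_fragments(rec_a.mol, bi.atom_a, bi.atom_b,
                                              rec_b.mol, bj.atom_a, bj.atom_b)
                        if mol is None:
                            report.valence_drops += 1
                            continue
                        smi = canonical_smiles(mol)
                        if smi in parent_smiles or smi in kept or smi in new_this_gen:
                            report.duplicates_removed += 1
                            continue
                        new_this_gen[smi] = HybridMolecule(
                            id=f"hyb_{rec_a.id}_{rec_b.id}_{bi.atom_a}_{bj.atom_b}",
                            smiles=smi,
                            mol=mol,
                            provenance=f"hybridize:gen{gen + 1}",
                            parent_head_id=rec_a.id,
                            parent_tail_id=rec_b.id,
                            junction=(bi.atom_a, bj.atom_b),
                            displacement=disp,
                            angle=ang,
                        )
        kept.update(new_this_gen)
        if not new_this_gen:
            break
        pool = pool + list(new_this_gen.values())

    out = [kept[s] for s in sorted(kept)]
    if params.untangle:
        out = [untangle(h, params) for h in out]
    for i, h in enumerate(out):
        h.id = f"hyb{i:05d}"
    report.novel_kept = len(out)
    return out, report


# ---------------------------------------------------------------------------
# 5. optional junction relaxation
# ---------------------------------------------------------------------------

def untangle(hybrid: HybridMolecule, params: HybridizationParams) -> HybridMolecule:
    """Short constrained force-field relaxation around the junction.

    Atoms more than two bonds away from the junction are held fixed, so the
    parents' binding geometry is preserved while the artificial junction bond
    relaxes to a physical length.  The topology (canonical SMILES) never
    changes; on force-field setup failure the hybrid is passed through
    unrelaxed with ``untangle_failed`` set.
    """
    mol = Chem.Mol(hybrid.mol)
    if mol.GetNumConformers() == 0:
        hybrid.untangle_failed = True
        return hybrid
    # junction indices refer to the assembled molecule: the new bond is between
    # the two atoms recorded at assembly time only in parent numbering, so
    # locate the junction bond as the one flagged via distance: relax the whole
    # molecule with far atoms fixed instead of tracking indices through dedup.
    try:
        mh = Chem.AddHs(mol, addCoords=True)
        ff = AllChem.UFFGetMoleculeForceField(mh)
        if ff is None:
            raise ValueError("no force field")
        # fix every heavy atom whose local geometry is already physical:
        # atoms not involved in any stretched/compressed bond (>20% off UFF
        # equilibrium ~1.5 Å for single bonds)
        conf = mh.GetConformer()
        loose: set[int] = set()
        for bond in mh.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            d = conf.GetAtomPosition(i).Distance(conf.GetAtomPosition(j))
            if d > 1.9 or d < 0.7:
                loose.update((i, j))
                for nb in mh.GetAtomWithIdx(i).GetNeighbors():
                    loose.add(nb.GetIdx())
                for nb in mh.GetAtomWithIdx(j).GetNeighbors():
                    loose.add(nb.GetIdx())
        # strong harmonic restraints (not hard fixed points, which destabilize
        # the BFGS line search) anchor every atom with sound local geometry
        for idx in range(mh.GetNumAtoms()):
            if idx not in loose:
                ff.UFFAddPositionConstraint(idx, 0.0, 1.0e4)
        ff.Initialize()
        ff.Minimize(maxIts=500)
        mh = Chem.RemoveHs(mh)
        if canonical_smiles(mh) == hybrid.smiles:
            hybrid.mol = mh
        else:  # relaxation must never change topology
            hybrid.untangle_failed = True
    except Exception:
        hybrid.untangle_failed = True
    return hybrid


# ---------------------------------------------------------------------------
# convenience: rigid MCS alignment (never called implicitly)
# ---------------------------------------------------------------------------

def align_to_reference(probe: MoleculeRecord, reference: MoleculeRecord) -> float:
    """Rigidly align ``probe`` onto ``reference`` via their maximum common
    substructure; returns the alignment RMSD (Å).  Mutates the probe conformer.
    """
    if probe.conformer is None or reference.conformer is None:
        raise InputError("both molecules need conformers for alignment")
    mcs = rdFMCS.FindMCS([probe.mol, reference.mol], timeout=10)
    if mcs.numAtoms < 3:
        raise InputError("no common substructure of >= 3 atoms; cannot align")
    patt = Chem.MolFromSmarts(mcs.smartsString)
    pm = probe.mol.GetSubstructMatch(patt)
    rm = reference.mol.GetSubstructMatch(patt)
    amap = list(zip(pm, rm))
    return AllChem.AlignMol(probe.mol, reference.mol, atomMap=amap)
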