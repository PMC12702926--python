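"""Independent brute-force oracles used to cross-check the implementation.

Deliberately built on a DIFFERENT construction route than the package:
fragmentation uses FragmentOnBonds with labelled dummy atoms and reassembly
uses Chem.molzip, versus the package's RWMol surgery; geometry is plain
Python math on conformer positions.
"""

import math

from rdkit import Chem


def oracle_cut_bonds(mol, min_frag):
    """Directed acyclic single heavy-heavy bonds leaving both sides >= min_frag."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        cut = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=False)
        sides = Chem.GetMolFrags(cut)
        heavies = [
            sum(1 for i in side if mol.GetAtomWithIdx(i).GetAtomicNum() > 1)
            for side in sides
        ]
        if min(heavies) < min_frag:
            continue
        out.append((a.GetIdx(), b.GetIdx()))
        out.append((b.GetIdx(), a.GetIdx()))
    return out


def oracle_geometry_ok(molA, bondA, molB, bondB, d_max, theta_max):
    """The three geometric tests, in plain math: both endpoints and the angle."""
    pa = molA.GetConformer().GetPositions()
    pb = molB.GetConformer().GetPositions()
    ai, bi = bondA
    aj, bj = bondB

    def dist(p, q):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(p, q)))

    if dist(pa[ai], pb[aj]) > d_max or dist(pa[bi], pb[bj]) > d_max:
        return False
    vi = [pa[bi][k] - pa[ai][k] for k in range(3)]
    vj = [pb[bj][k] - pb[aj][k] for k in range(3)]
    ni = math.sqrt(sum(x * x for x in vi))
    nj = math.sqrt(sum(x * x for x in vj))
    cosang = sum(x * y for x, y in zip(vi, vj)) / (ni * nj)
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return angle <= theta_max


def _fragment_with_dummy(mol, a, b):
    """Fragment at bond a-b; return the piece containing atom ``a`` with a
    single isotope-1 dummy marking the cut."""
    bond = mol.GetBondBetweenAtoms(a, b)
    cut = Chem.FragmentOnBonds(mol, [bond.GetIdx()], dummyLabels=[(1, 1)])
    mapping = []
    frags = Chem.GetMolFrags(cut, asMols=True, fragsMolAtomMapping=mapping)
    for frag, atom_ids in zip(frags, mapping):
        if a in atom_ids:
            return frag
    raise AssertionError("atom not found in any fragment")


def oracle_hybrid_smiles(molA, bondA, molB, bondB):
    """Canonical SMILES of (head of A at bondA) + (tail of B at bondB) via molzip."""
    head = _fragment_with_dummy(molA, bondA[0], bondA[1])
    tail = _fragment_with_dummy(molB, bondB[1], bondB[0])
    params = Chem.MolzipParams()
    params.label = Chem.MolzipLabel.Isotope
    zipped = Chem.molzip(Chem.CombineMols(head, tail), params)
    Chem.SanitizeMol(zipped)
    for atom in zipped.GetAtoms():
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    return Chem.MolToSmiles(zipped)


def oracle_library_smiles(mols, d_max, theta_max, min_frag):
    """Every hybrid a correct implementation must produce, as a SMILES set."""
    parents = {Chem.MolToSmiles(m) for m in mols}
    bonds = [oracle_cut_bonds(m, min_frag) for m in mols]
    out = set()
    for i, molA in enumerate(mols):
        for j, molB in enumerate(mols):
            if i == j:
                continue
            for ba in bonds[i]:
                for bb in bonds[j]:
                    if not oracle_geometry_ok(molA, ba, molB, bb, d_max, theta_max):
                        continue
                    smi = oracle_hybrid_smiles(molA, ba, molB, bb)
                    if smi not in parents:
                        out.add(smi)
    return out
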