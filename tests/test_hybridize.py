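import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from hybridscreen import (
    CuttableBond,
    DegenerateGeometryError,
    HybridizationParams,
    InputError,
    MoleculeRecord,
    canonical_smiles,
    enumerate_cuttable_bonds,
    generate_library,
    match_bond_vectors,
    recombine,
    untangle,
)
from hybridscreen.fixtures import make_aligned_set

from oracle import oracle_library_smiles


def _embed(smiles: str, seed: int = 17) -> MoleculeRecord:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    mol = Chem.RemoveHs(mol)
    return MoleculeRecord(id=smiles, smiles=canonical_smiles(mol), mol=mol)


PARAMS2 = HybridizationParams(min_fragment_heavy_atoms=2)


class TestEnumerateCuttableBonds:
    def test_ethane_two_directed_entries(self):
        rec = _embed("CC")
        bonds = enumerate_cuttable_bonds(rec, HybridizationParams(min_fragment_heavy_atoms=1))
        assert len(bonds) == 2
        assert {(b.atom_a, b.atom_b) for b in bonds} == {(0, 1), (1, 0)}

    def test_benzene_has_no_cut_sites(self):
        rec = _embed("c1ccccc1")
        assert enumerate_cuttable_bonds(rec, HybridizationParams(min_fragment_heavy_atoms=1)) == []

    @pytest.mark.parametrize("min_frag,expected", [(1, 2), (3, 0)])
    def test_toluene_exocyclic_bond(self, min_frag, expected):
        rec = _embed("Cc1ccccc1")
        bonds = enumerate_cuttable_bonds(
            rec, HybridizationParams(min_fragment_heavy_atoms=min_frag)
        )
        assert len(bonds) == expected

    def test_no_conformer_is_input_error(self):
        mol = Chem.MolFromSmiles("CCO")
        rec = MoleculeRecord(id="x", smiles="CCO", mol=mol)
        with pytest.raises(InputError):
            enumerate_cuttable_bonds(rec, PARAMS2)

    def test_matches_oracle_on_drug_like_molecules(self):
        from oracle import oracle_cut_bonds

        for smi in ["CC(C)Cc1ccc(cc1)C(C)C(=O)O", "CCOC(=O)c1ccc(N)cc1", "CN1CCC(CC1)Oc1ccccc1"]:
            rec = _embed(smi)
            for min_frag in (1, 2, 3):
                params = HybridizationParams(min_fragment_heavy_atoms=min_frag)
                got = {(b.atom_a, b.atom_b) for b in enumerate_cuttable_bonds(rec, params)}
                assert got == set(oracle_cut_bonds(rec.mol, min_frag))


def _bond(pa, pb, parent="x", a=0, b=1):
    return CuttableBond(parent, a, b, np.array(pa, float), np.array(pb, float))


class TestMatchBondVectors:
    def test_identical_bonds_accept_at_zero(self):
        bi = _bond((0, 0, 0), (1.5, 0, 0), "A")
        bj = _bond((0, 0, 0), (1.5, 0, 0), "B")
        ok, disp, ang = match_bond_vectors(bi, bj, PARAMS2)
        assert ok and disp == 0.0 and ang == 0.0

    def test_boundary_angle_15_degrees_inclusive(self):
        th = np.radians(15.0)
        bi = _bond((0, 0, 0), (1, 0, 0), "A")
        bj = _bond((0, 0, 0), (np.cos(th), np.sin(th), 0), "B")
        ok, _, ang = match_bond_vectors(bi, bj, PARAMS2)
        assert ok and ang == pytest.approx(15.0, abs=1e-9)

    def test_boundary_displacement_1_0_inclusive_1_01_rejected(self):
        # displace endpoint b along the bond axis so the angle stays 0
        bi = _bond((0, 0, 0), (1.5, 0, 0), "A")
        ok, disp, _ = match_bond_vectors(bi, _bond((0, 0, 0), (2.5, 0, 0), "B"), PARAMS2)
        assert ok and disp == pytest.approx(1.0)
        ok, disp, _ = match_bond_vectors(bi, _bond((0, 0, 0), (2.51, 0, 0), "B"), PARAMS2)
        assert not ok and disp == pytest.approx(1.01)

    def test_symmetry_of_accept_decision(self, rng):
        for _ in range(200):
            bi = _bond(rng.normal(size=3), rng.normal(size=3), "A")
            bj = _bond(rng.normal(size=3), rng.normal(size=3), "B")
            ri = match_bond_vectors(bi, bj, PARAMS2)
            rj = match_bond_vectors(bj, bi, PARAMS2)
            assert ri[0] == rj[0]
            assert ri[1] == pytest.approx(rj[1]) and ri[2] == pytest.approx(rj[2])

    def test_zero_length_vector_is_degenerate(self):
        bi = _bond((0, 0, 0), (0, 0, 0), "A")
        with pytest.raises(DegenerateGeometryError):
            match_bond_vectors(bi, _bond((0, 0, 0), (1, 0, 0), "B"), PARAMS2)

    def test_midpoint_mode_is_looser_on_translated_bonds(self):
        params_mid = HybridizationParams(displacement_mode="midpoint")
        # bond j shifted +0.9 along its own axis: endpoints each off by 0.9,
        # midpoints also 0.9 apart -> both accept; shift one endpoint only and
        # the midpoint test averages the error
        bi = _bond((0, 0, 0), (1.5, 0, 0), "A")
        bj = _bond((0, 0, 0), (1.5, 0, 1.8), "B")
        assert not match_bond_vectors(bi, bj, HybridizationParams(theta_max=60))[0]
        assert match_bond_vectors(bi, bj, HybridizationParams(theta_max=60, displacement_mode="midpoint"))[0]


class TestRecombine:
    def test_self_hybridization_reproduces_parent(self):
        recs, _ = make_aligned_set(k=2, tails=("O", "N"))
        lig = recs[0]
        bonds = enumerate_cuttable_bonds(lig, PARAMS2)
        hybrids, dropped = recombine(bonds[0], bonds[0], lig, lig)
        assert dropped == 0
        assert all(h.smiles == lig.smiles for h in hybrids)

    def test_tail_swap_pair_gives_two_hybrids(self):
        recs, manifest = make_aligned_set(k=2, tails=("O", "N"))
        a, b = recs
        ba = enumerate_cuttable_bonds(a, PARAMS2)
        bb = enumerate_cuttable_bonds(b, PARAMS2)
        # pick the matching direction (ring-side head atom for both)
        bi = next(x for x in ba if x.atom_a == 0)
        bj = next(x for x in bb if x.atom_a == 0)
        ok, disp, ang = match_bond_vectors(bi, bj, PARAMS2)
        assert ok
        hybrids, dropped = recombine(bi, bj, a, b, disp, ang)
        assert dropped == 0
        assert sorted(h.smiles for h in hybrids) == manifest

    def test_inconsistent_ring_bond_is_counted_drop(self):
        # enumeration never emits ring bonds; feeding one in exercises the
        # counted-drop path (cutting a ring bond leaves the graph connected)
        recs, _ = make_aligned_set(k=2, tails=("O", "N"))
        a, b = recs
        good = next(x for x in enumerate_cuttable_bonds(b, PARAMS2) if x.atom_a == 0)
        coords = a.conformer
        ring_bond = CuttableBond(a.id, 0, 1, coords[0], coords[1])  # aromatic ring edge
        hybrids, dropped = recombine(ring_bond, good, a, b)
        assert dropped == 2 and hybrids == []

    def test_enumerated_pairs_never_drop(self, aligned4):
        # valence conservation: a single-bond cut-and-rejoin preserves every
        # atom's explicit valence, so sanitization cannot fail
        recs, _ = aligned4
        _, report = generate_library(recs, PARAMS2)
        assert report.valence_drops == 0


class TestGenerateLibrary:
    def test_two_identical_superimposed_ligands_yield_nothing(self):
        recs, _ = make_aligned_set(k=2, tails=("O", "N"))
        twin = MoleculeRecord(id="twin", smiles=recs[0].smiles, mol=Chem.Mol(recs[0].mol))
        hybrids, report = generate_library([recs[0], twin], PARAMS2)
        assert hybrids == []
        assert report.duplicates_removed == report.matches - report.valence_drops

    def test_four_ligand_manifest_reproduced(self, aligned4):
        recs, manifest = aligned4
        hybrids, report = generate_library(recs, PARAMS2)
        assert sorted(h.smiles for h in hybrids) == manifest
        assert report.novel_kept == len(manifest) == 12

    def test_matches_brute_force_oracle(self):
        for k, tails in [(2, ("O", "N")), (3, ("O", "N", "S")), (4, None)]:
            recs, _ = make_aligned_set(k=k, tails=tails)
            hybrids, _ = generate_library(recs, PARAMS2)
            expected = oracle_library_smiles([r.mol for r in recs], 1.0, 15.0, 2)
            assert {h.smiles for h in hybrids} == expected

    def test_perturbed_ligand_contributes_no_matches(self):
        recs, manifest = make_aligned_set(k=4, perturb_ligand=2, perturb_delta=1.5)
        hybrids, _ = generate_library(recs, PARAMS2)
        assert sorted(h.smiles for h in hybrids) == manifest  # 3*(3-1)=6 hybrids
        assert len(manifest) == 6

    def test_monotone_in_tolerances(self):
        recs, _ = make_aligned_set(k=4, perturb_ligand=1, perturb_delta=0.9)
        sizes_d = []
        for d_max in (0.5, 0.95, 1.5, 3.0):
            h, _ = generate_library(
                recs, HybridizationParams(d_max=d_max, min_fragment_heavy_atoms=2)
            )
            sizes_d.append(len(h))
        assert sizes_d == sorted(sizes_d)
        sizes_t = []
        for theta in (1.0, 15.0, 60.0, 180.0):
            h, _ = generate_library(
                recs, HybridizationParams(theta_max=theta, min_fragment_heavy_atoms=2)
            )
            sizes_t.append(len(h))
        assert sizes_t == sorted(sizes_t)
        sizes_f = []
        for min_frag in (1, 2, 8):
            h, _ = generate_library(
                recs, HybridizationParams(min_fragment_heavy_atoms=min_frag)
            )
            sizes_f.append(len(h))
        assert sizes_f == sorted(sizes_f, reverse=True)

    def test_heavy_atom_conservation(self, aligned4):
        recs, _ = aligned4
        hybrids, _ = generate_library(recs, PARAMS2)
        # every ligand is scaffold(7 heavy) + tail(2 heavy); any head+tail
        # hybrid must conserve the total
        assert all(h.heavy_atoms == 9 for h in hybrids)
        assert all(h.parent_head_id != h.parent_tail_id for h in hybrids)

    def test_no_hybrid_equals_a_parent(self, aligned4):
        recs, _ = aligned4
        hybrids, _ = generate_library(recs, PARAMS2)
        assert {h.smiles for h in hybrids}.isdisjoint({r.smiles for r in recs})

    def test_deterministic_sorted_output(self, aligned4):
        recs, _ = aligned4
        h1, _ = generate_library(recs, PARAMS2)
        h2, _ = generate_library(list(reversed(recs)), PARAMS2)
        assert [h.smiles for h in h1] == [h.smiles for h in h2]
        assert [h.smiles for h in h1] == sorted(h.smiles for h in h1)

    def test_fewer_than_two_ligands_is_input_error(self, aligned4):
        recs, _ = aligned4
        with pytest.raises(InputError):
            generate_library(recs[:1], PARAMS2)

    def test_second_generation_extends_pool(self):
        # with distinct halide+tail crosses a second cycle cannot add molecules
        # beyond the k*(k-1) crosses (same cut site), so the library is stable
        recs, manifest = make_aligned_set(k=3, tails=("O", "N", "S"))
        h1, _ = generate_library(recs, HybridizationParams(min_fragment_heavy_atoms=2))
        h2, _ = generate_library(
            recs, HybridizationParams(min_fragment_heavy_atoms=2, generations=2)
        )
        assert {h.smiles for h in h1} == {h.smiles for h in h2} == set(manifest)


class TestUntangle:
    def _stretched_hybrid(self):
        recs, _ = make_aligned_set(k=2, tails=("O", "N"))
        a, b = recs
        # shift b's whole tail +0.8 Å so the junction bond comes out long but
        # still within the 1.0 Å matching tolerance
        conf = b.mol.GetConformer()
        from rdkit.Geometry import Point3D

        for idx in (7, 8):
            p = conf.GetAtomPosition(idx)
            conf.SetAtomPosition(idx, Point3D(p.x + 0.8, p.y, p.z))
        hybrids, _ = generate_library([a, b], HybridizationParams(
            min_fragment_heavy_atoms=2, theta_max=60.0))
        return hybrids

    def test_junction_bond_relaxes_toward_equilibrium(self):
        hybrids = self._stretched_hybrid()
        assert hybrids
        for h in [x for x in hybrids]:
            before = h.smiles
            d0 = _junction_length(h)
            relaxed = untangle(h, HybridizationParams(untangle=True))
            assert not relaxed.untangle_failed
            assert relaxed.smiles == before  # topology invariant
            d1 = _junction_length(relaxed)
            assert abs(d1 - 1.5) < abs(d0 - 1.5)
            assert 1.2 <= d1 <= 1.8

    def test_clean_hybrid_barely_moves(self, aligned4):
        recs, _ = aligned4
        hybrids, _ = generate_library(recs, PARAMS2)
        h = hybrids[0]
        before = np.array(h.conformer)
        relaxed = untangle(h, HybridizationParams(untangle=True))
        rmsd = np.sqrt(((np.array(relaxed.conformer) - before) ** 2).sum(axis=1).mean())
        assert rmsd < 0.5


def _junction_length(h):
    mol = h.mol
    conf = mol.GetConformer()
    best = None
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        d = conf.GetAtomPosition(bond.GetBeginAtomIdx()).Distance(
            conf.GetAtomPosition(bond.GetEndAtomIdx())
        )
        if best is None or d > best:
            best = d
    return best
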