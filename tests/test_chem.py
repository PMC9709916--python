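"""Molecule perception, symmetry classes and torsion-quartet grouping."""

import numpy as np
import pytest
from rdkit import Chem

from torsionforge.chem import (
    Molecule,
    TorsionQuartet,
    enumerate_quartets,
    find_rotatable_bonds,
    perceive,
    symmetry_classes,
    torsion_type_groups,
)
from torsionforge.errors import InputError, UsageError

from conftest import PANEL_SMILES


class TestPerceive:
    def test_ethane_counts(self):
        mol = perceive("CC")
        assert mol.n_atoms == 8  # 2 C + 6 H
        assert mol.n_bonds == 7

    def test_biphenyl_aromatic_with_nonring_central_bond(self, biphenyl):
        aromatic_c = [
            a for a in biphenyl.rdmol.GetAtoms()
            if a.GetIsAromatic() and a.GetAtomicNum() == 6
        ]
        assert len(aromatic_c) == 12
        (bond,) = find_rotatable_bonds(biphenyl)
        assert not biphenyl.rdmol.GetBondBetweenAtoms(*bond).IsInRing()

    def test_malformed_smiles_raises_input_error(self):
        with pytest.raises(InputError, match="C\\("):
            perceive("C(")

    def test_sdf_round_trip(self, tmp_path, butane):
        butane = butane.copy()
        butane.embed(seed=1)
        path = str(tmp_path / "butane.sdf")
        butane.to_sdf(path)
        back = perceive(path)
        assert back.n_atoms == butane.n_atoms
        assert back.to_smiles() == butane.to_smiles()

    def test_canonical_smiles_round_trip(self, molecule_panel):
        for mol in molecule_panel:
            assert perceive(mol.to_smiles()).to_smiles() == mol.to_smiles()


class TestSymmetryClasses:
    def test_methane_hydrogens_share_one_class(self):
        mol = perceive("C")
        labels = symmetry_classes(mol)
        h_classes = {
            labels[a.GetIdx()]
            for a in mol.rdmol.GetAtoms()
            if a.GetAtomicNum() == 1
        }
        assert len(h_classes) == 1

    def test_biphenyl_heavy_atom_classes(self, biphenyl):
        # both rings equivalent: ipso/ortho/meta/para -> 4 heavy-atom classes
        labels = symmetry_classes(biphenyl)
        heavy = [
            labels[a.GetIdx()]
            for a in biphenyl.rdmol.GetAtoms()
            if a.GetAtomicNum() == 6
        ]
        assert len(set(heavy)) == 4
        for cls in set(heavy):
            assert heavy.count(cls) in (2, 4)  # pairs across the two rings

    @pytest.mark.parametrize("smiles", PANEL_SMILES)
    def test_permutation_invariance(self, smiles):
        """Relabeling atoms and recomputing yields the same partition."""
        mol = perceive(smiles)
        labels = symmetry_classes(mol)
        rng = np.random.default_rng(hash(smiles) % 2**31)
        perm = rng.permutation(mol.n_atoms).tolist()
        permuted = Molecule(Chem.RenumberAtoms(mol.rdmol, perm))
        plabels = symmetry_classes(permuted)
        # perm[new] = old: atom old i moved to position perm.index(i)
        inv = {old: new for new, old in enumerate(perm)}
        original = {
            frozenset(group) for group in _partition(labels.labels)
        }
        mapped_back = {
            frozenset(inv[a] for a in group) for group in _partition(labels.labels)
        }
        permuted_partition = {frozenset(g) for g in _partition(plabels.labels)}
        assert mapped_back == permuted_partition or original == permuted_partition

    @pytest.mark.parametrize("smiles", PANEL_SMILES)
    def test_agrees_with_rdkit_canonical_ranking(self, smiles):
        """Independent oracle: RDKit's symmetry classes give the same partition."""
        mol = perceive(smiles)
        ours = {frozenset(g) for g in _partition(symmetry_classes(mol).labels)}
        ranks = list(
            Chem.CanonicalRankAtoms(mol.rdmol, breakTies=False)
        )
        theirs = {frozenset(g) for g in _partition(ranks)}
        assert ours == theirs

    def test_idempotent(self, aspirin):
        assert symmetry_classes(aspirin) == symmetry_classes(aspirin)


def _partition(labels):
    groups = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    return groups.values()


class TestRotatableBonds:
    def test_benzene_has_none(self):
        assert find_rotatable_bonds(perceive("c1ccccc1")) == []

    def test_biphenyl_central_bond_only(self, biphenyl):
        bonds = find_rotatable_bonds(biphenyl)
        assert len(bonds) == 1
        a, b = bonds[0]
        assert biphenyl.rdmol.GetAtomWithIdx(a).GetIsAromatic()
        assert biphenyl.rdmol.GetAtomWithIdx(b).GetIsAromatic()

    def test_butyne_excluded(self):
        # sp-carbon bonds have geometrically degenerate dihedrals
        assert find_rotatable_bonds(perceive("CC#CC")) == []

    def test_terminal_bonds_excluded(self):
        # methanol C-O: oxygen has the hydroxyl H, so it is nonterminal
        assert find_rotatable_bonds(perceive("CO")) == [(0, 1)]
        # hydrogen fluoride-like terminal: no rotatable bonds in methane
        assert find_rotatable_bonds(perceive("C")) == []

    def test_deterministic_sorted_order(self, aspirin):
        bonds = find_rotatable_bonds(aspirin)
        assert bonds == sorted(bonds)


class TestTorsionQuartet:
    def test_reverse_equality(self):
        assert TorsionQuartet(0, 1, 2, 3) == TorsionQuartet(3, 2, 1, 0)
        assert hash(TorsionQuartet(0, 1, 2, 3)) == hash(TorsionQuartet(3, 2, 1, 0))

    def test_degenerate_rejected(self):
        with pytest.raises(UsageError):
            TorsionQuartet(0, 1, 2, 0)


class TestTorsionTypeGroups:
    def test_biphenyl_one_group(self, biphenyl):
        (bond,) = find_rotatable_bonds(biphenyl)
        groups = torsion_type_groups(biphenyl, bond)
        assert len(groups) == 1
        assert len(groups[0].quartets) == 4

    def test_aspirin_ester_oxygen_aryl_two_groups(self, aspirin):
        bond = _aspirin_o_aryl_bond(aspirin)
        groups = torsion_type_groups(aspirin, bond)
        assert len(groups) == 2

    def test_ethane_single_group_of_nine(self):
        mol = perceive("CC")
        groups = torsion_type_groups(mol, (0, 1))
        assert len(groups) == 1
        assert len(groups[0].quartets) == 9

    def test_partition_property(self, molecule_panel):
        """Groups partition the quartets of every rotatable bond exactly."""
        for mol in molecule_panel:
            for bond in find_rotatable_bonds(mol):
                groups = torsion_type_groups(mol, bond)
                grouped = [q for g in groups for q in g.quartets]
                assert sorted(q.atoms for q in grouped) == sorted(
                    q.atoms for q in enumerate_quartets(mol, bond)
                )

    def test_non_rotatable_bond_rejected(self, biphenyl):
        with pytest.raises(UsageError, match="not rotatable"):
            torsion_type_groups(biphenyl, (0, 1))


def _aspirin_o_aryl_bond(aspirin):
    for bond in find_rotatable_bonds(aspirin):
        a1 = aspirin.rdmol.GetAtomWithIdx(bond[0])
        a2 = aspirin.rdmol.GetAtomWithIdx(bond[1])
        if {a1.GetAtomicNum(), a2.GetAtomicNum()} == {8, 6} and (
            a1.GetIsAromatic() or a2.GetIsAromatic()
        ):
            return bond
    raise AssertionError("ester-oxygen-aryl bond not found")
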