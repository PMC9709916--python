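"""Molecule representation, rotatable-bond perception, and symmetry typing.

Molecules are thin wrappers around RDKit ``Mol`` objects with explicit
hydrogens, so that hydrogens participate in torsion quartets and symmetry
classes on equal footing with heavy atoms.

Symmetry classes are computed by an iterative Morgan-style refinement over
the bonding topology: atoms are seeded with an invariant built from element,
formal charge, degree, ring membership and hydrogen count, then repeatedly
re-partitioned by the sorted multiset of their neighbours' classes until the
partition is stable.  Two atoms share a class exactly when their topological
environments are indistinguishable, which is what lets torsion quartets
through one rotatable bond be grouped into a small number of torsion types
(biphenyl's central bond gives one type; the ester-oxygen-aryl bond of
aspirin gives two).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from .errors import InputError, UsageError

__all__ = [
    "Molecule",
    "SymmetryLabeling",
    "TorsionQuartet",
    "TorsionTypeGroup",
    "perceive",
    "symmetry_classes",
    "find_rotatable_bonds",
    "torsion_type_groups",
]


# ---------------------------------------------------------------------------
# Molecule


class Molecule:
    """A perceived molecule: explicit hydrogens, aromaticity and rings done.

    Wraps an RDKit ``Mol``; conformer coordinates are in Angstrom and atom
    indices are 0-based everywhere in the library (1-based only inside
    SMIRKS atom-map tokens).
    """

    def __init__(self, rdmol: Chem.Mol, name: str = ""):
        self.rdmol = rdmol
        self.name = name or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "Molecule":
        mol = Chem.MolFromSmiles(smiles, sanitize=True)
        if mol is None:
            raise InputError(f"could not parse SMILES {smiles!r}")
        mol = Chem.AddHs(mol)
        Chem.SanitizeMol(mol)
        return cls(mol, name=name)

    @classmethod
    def from_sdf(cls, source: str) -> "Molecule":
        """Read the first record of an SDF (V2000) file or text block."""
        if os.path.exists(source):
            supplier = Chem.SDMolSupplier(source, removeHs=False, sanitize=True)
        else:
            supplier = Chem.SDMolSupplier()
            supplier.SetData(source, removeHs=False, sanitize=True)
        mol = next(iter(supplier), None)
        if mol is None:
            raise InputError(f"could not parse SDF record from {source[:80]!r}")
        mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
        Chem.SanitizeMol(mol)
        return cls(mol)

    def copy(self) -> "Molecule":
        return Molecule(Chem.Mol(self.rdmol), name=self.name)

    # -- basic views ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def n_bonds(self) -> int:
        return self.rdmol.GetNumBonds()

    def coords(self, conf_id: int = 0):
        import numpy as np

        if self.rdmol.GetNumConformers() == 0:
            raise UsageError("molecule has no conformer")
        return np.asarray(self.rdmol.GetConformer(conf_id).GetPositions(), dtype=float)

    def set_coords(self, xyz, conf_id: int = 0) -> None:
        from rdkit.Geometry import Point3D

        if self.rdmol.GetNumConformers() == 0:
            conf = Chem.Conformer(self.n_atoms)
            self.rdmol.AddConformer(conf, assignId=True)
        conf = self.rdmol.GetConformer(conf_id)
        for i, (x, y, z) in enumerate(xyz):
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))

    def embed(self, seed: int = 2024) -> None:
        """Generate a single 3D conformer (ETKDG), deterministic per seed."""
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        if AllChem.EmbedMolecule(self.rdmol, params) != 0:
            # fall back to unconstrained coordinates for tiny/odd species
            params.useRandomCoords = True
            if AllChem.EmbedMolecule(self.rdmol, params) != 0:
                raise InputError(f"3D embedding failed for {self.to_smiles()}")

    def dihedral(self, quartet, conf_id: int = 0) -> float:
        """Signed dihedral in degrees, IUPAC convention, range (-180, 180]."""
        i, j, k, l = quartet
        val = rdMolTransforms.GetDihedralDeg(self.rdmol.GetConformer(conf_id), i, j, k, l)
        if val <= -180.0:
            val += 360.0
        return val

    def to_smiles(self, mapped_atoms: dict[int, int] | None = None) -> str:
        """Canonical SMILES; ``mapped_atoms`` maps atom index -> map number."""
        mol = Chem.Mol(self.rdmol)
        if mapped_atoms:
            for idx, num in mapped_atoms.items():
                mol.GetAtomWithIdx(idx).SetAtomMapNum(int(num))
        return Chem.MolToSmiles(Chem.RemoveHs(mol) if not mapped_atoms else mol)

    def to_sdf(self, path: str, props: dict[str, str] | None = None) -> None:
        mol = Chem.Mol(self.rdmol)
        if props:
            for key, val in props.items():
                mol.SetProp(key, str(val))
        with Chem.SDWriter(path) as writer:
            writer.write(mol)

    def neighbors(self, idx: int) -> list[int]:
        return sorted(n.GetIdx() for n in self.rdmol.GetAtomWithIdx(idx).GetNeighbors())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Molecule({self.to_smiles()!r}, n_atoms={self.n_atoms})"


def perceive(smiles_or_sdf: str) -> Molecule:
    """Parse a SMILES string, an SDF file path, or an SDF text block."""
    text = smiles_or_sdf.strip()
    looks_like_sdf = (
        (os.path.exists(smiles_or_sdf) and smiles_or_sdf.lower().endswith((".sdf", ".mol")))
        or "V2000" in text
        or "$$$$" in text
    )
    if looks_like_sdf:
        return Molecule.from_sdf(smiles_or_sdf)
    if "\n" in text or not text:
        raise InputError(f"input is neither SMILES nor SDF: {smiles_or_sdf[:80]!r}")
    return Molecule.from_smiles(text)


# ---------------------------------------------------------------------------
# Symmetry classes (Morgan-style iterative refinement)


@dataclass(frozen=True)
class SymmetryLabeling:
    """Partition of atoms into topological symmetry classes.

    ``labels[i]`` is the class of atom ``i``; class ids are dense ranks of the
    refined invariants and therefore permutation-invariant: relabelling the
    atoms of a molecule and recomputing yields the same partition.
    """

    labels: tuple[int, ...]

    def __getitem__(self, idx: int) -> int:
        return self.labels[idx]

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))

    def partition(self) -> list[frozenset[int]]:
        groups: dict[int, set[int]] = {}
        for idx, lab in enumerate(self.labels):
            groups.setdefault(lab, set()).add(idx)
        return sorted((frozenset(v) for v in groups.values()), key=min)


def symmetry_classes(mol: Molecule) -> SymmetryLabeling:
    rd = mol.rdmol
    # seed invariant: element, charge, degree, ring flag, explicit-H count
    seeds = []
    for atom in rd.GetAtoms():
        n_h = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() == 1)
        seeds.append(
            (
                atom.GetAtomicNum(),
                atom.GetFormalCharge(),
                atom.GetDegree(),
                atom.IsInRing(),
                n_h,
            )
        )
    ranks = _dense_ranks(seeds)
    adjacency = [mol.neighbors(i) for i in range(mol.n_atoms)]

    prev_count = -1
    stable_rounds = 0
    for _ in range(max(mol.n_atoms, 1)):
        refined = [
            (ranks[i], tuple(sorted(ranks[j] for j in adjacency[i])))
            for i in range(mol.n_atoms)
        ]
        new_ranks = _dense_ranks(refined)
        n_classes = len(set(new_ranks))
        stable_rounds = stable_rounds + 1 if n_classes == prev_count else 0
        ranks, prev_count = new_ranks, n_classes
        if stable_rounds >= 2:
            break
    return SymmetryLabeling(tuple(ranks))


def _dense_ranks(keys: list) -> list[int]:
    order = {key: rank for rank, key in enumerate(sorted(set(keys)))}
    return [order[key] for key in keys]


# ---------------------------------------------------------------------------
# Rotatable bonds and torsion quartets


def find_rotatable_bonds(mol: Molecule) -> list[tuple[int, int]]:
    """Nonterminal, non-ring, non-triple bonds, sorted by atom indices.

    Bonds whose central atoms sit in a triple bond (sp linear centres) are
    excluded: every dihedral through them is geometrically degenerate.
    """
    rd = mol.rdmol
    out = []
    for bond in rd.GetBonds():
        if bond.IsInRing() or bond.GetBondType() == Chem.BondType.TRIPLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:
            continue
        if _in_triple_bond(a) or _in_triple_bond(b):
            continue
        pair = tuple(sorted((a.GetIdx(), b.GetIdx())))
        out.append(pair)
    return sorted(out)


def _in_triple_bond(atom: Chem.Atom) -> bool:
    return any(b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds())


@dataclass(frozen=True)
class TorsionQuartet:
    """Four consecutively bonded atoms (i, j, k, l); (j, k) is the central bond.

    Stored in the canonical orientation (the lexicographically smaller of the
    index tuple and its reverse) so that a quartet equals its reverse.
    """

    atoms: tuple[int, int, int, int]

    def __init__(self, i: int, j: int, k: int, l: int):
        if i == l:
            raise UsageError(f"degenerate quartet with i == l == {i}")
        tup = (i, j, k, l)
        rev = (l, k, j, i)
        object.__setattr__(self, "atoms", min(tup, rev))

    @property
    def i(self):
        return self.atoms[0]

    @property
    def j(self):
        return self.atoms[1]

    @property
    def k(self):
        return self.atoms[2]

    @property
    def l(self):
        return self.atoms[3]

    @property
    def central_bond(self) -> tuple[int, int]:
        return tuple(sorted(self.atoms[1:3]))

    def __iter__(self):
        return iter(self.atoms)


@dataclass
class TorsionTypeGroup:
    """Symmetry-equivalent quartets through one rotatable bond.

    ``type_key`` is the canonicalized 4-tuple of symmetry classes (a quartet
    and its reverse share the key); all quartets in a group carry one torsion
    parameter set.
    """

    central_bond: tuple[int, int]
    type_key: tuple[int, int, int, int]
    quartets: list[TorsionQuartet] = field(default_factory=list)


def enumerate_quartets(mol: Molecule, bond: tuple[int, int]) -> list[TorsionQuartet]:
    """All bonded quartets i-j-k-l running through ``bond`` = (j, k)."""
    j, k = bond
    quartets = []
    for i in mol.neighbors(j):
        if i == k:
            continue
        for l in mol.neighbors(k):
            if l == j or l == i:
                continue
            quartets.append(TorsionQuartet(i, j, k, l))
    return sorted(set(quartets), key=lambda q: q.atoms)


def torsion_type_groups(mol: Molecule, bond: tuple[int, int]) -> list[TorsionTypeGroup]:
    """Partition the quartets through a rotatable bond by symmetry type."""
    bond = tuple(sorted(bond))
    if bond not in find_rotatable_bonds(mol):
        raise UsageError(f"bond {bond} is not rotatable")
    labels = symmetry_classes(mol)
    groups: dict[tuple, TorsionTypeGroup] = {}
    for quartet in enumerate_quartets(mol, bond):
        i, j, k, l = quartet
        key_fwd = (labels[i], labels[j], labels[k], labels[l])
        key = min(key_fwd, key_fwd[::-1])
        if key not in groups:
            groups[key] = TorsionTypeGroup(central_bond=bond, type_key=key)
        groups[key].quartets.append(quartet)
    return sorted(groups.values(), key=lambda g: g.type_key)
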