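"""Torsion-preserving fragmentation gated by Wiberg-bond-order conservation.

A fragment around a rotatable bond keeps the bond's atoms plus everything
within one bond of them, with whole rings and aromatic systems retained and
no non-single bond ever cut; open valences are hydrogen-capped.  A proposed
fragment is accepted only when the central-bond bond order computed on the
fragment agrees with the parent value within a threshold (0.03 e by
default).  Rejected fragments are grown one substituent at a time, greedily
choosing the addition that most reduces the bond-order disruption, until
acceptance (the parent itself is always accepted).

Quantum Wiberg bond orders are deliberately out of scope here: any callable
``(Molecule, bond) -> float`` can serve as the provider.  The default is a
topological conjugation-aware surrogate that adds small delocalization
increments from pi systems and heteroatoms near the central bond to the
nominal bond order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from rdkit import Chem

from .chem import Molecule, TorsionQuartet, find_rotatable_bonds
from .errors import BackendError, UsageError

DEFAULT_WBO_THRESHOLD = 0.03  # e

BondOrderProvider = Callable[[Molecule, tuple[int, int]], float]

__all__ = [
    "Fragment",
    "WboReport",
    "BondOrderProvider",
    "surrogate_bond_order",
    "initial_fragment",
    "accept",
    "fragment_molecule",
]


@dataclass
class Fragment:
    """A hydrogen-capped submolecule around one rotatable bond."""

    molecule: Molecule
    parent_map: dict[int, int]  # fragment atom index -> parent atom index
    target_bond: tuple[int, int]  # fragment indices
    cap_atoms: frozenset[int] = frozenset()
    # cap atom index -> parent atom index of the substituent the cap replaced
    cap_map: dict[int, int] = field(default_factory=dict)

    @property
    def inverse_map(self) -> dict[int, int]:
        return {p: f for f, p in self.parent_map.items()}

    def map_quartet(self, parent_quartet: TorsionQuartet) -> TorsionQuartet:
        inv = self.inverse_map
        try:
            return TorsionQuartet(*(inv[a] for a in parent_quartet))
        except KeyError as exc:
            raise UsageError(f"parent atom {exc} not present in fragment") from exc

    def to_sdf(self, path: str) -> None:
        tag = ",".join(f"{f}:{p}" for f, p in sorted(self.parent_map.items()))
        self.molecule.to_sdf(path, props={
            "parent_map": tag,
            "target_bond": f"{self.target_bond[0]},{self.target_bond[1]}",
        })


@dataclass
class WboReport:
    """Central-bond order comparison between parent and fragment."""

    wbo_parent: float
    wbo_fragment: float
    threshold: float = DEFAULT_WBO_THRESHOLD
    accepted: bool = field(init=False)

    def __post_init__(self):
        self.accepted = accept(self)


def accept(report: WboReport) -> bool:
    """Inclusive-boundary acceptance: |Delta WBO| <= threshold.

    A small epsilon absorbs binary-representation noise so that a deviation
    equal to the threshold at the printed precision is accepted.
    """
    return abs(report.wbo_parent - report.wbo_fragment) <= report.threshold + 1e-9


# ---------------------------------------------------------------------------
# Default bond-order surrogate

_DELOC_WEIGHT = {1: 0.020, 2: 0.010, 3: 0.005}  # by graph distance from bond


def surrogate_bond_order(mol: Molecule, bond: tuple[int, int]) -> float:
    """Conjugation-aware topological stand-in for a Wiberg bond order.

    nominal order (aromatic = 1.5) plus distance-weighted increments from
    nearby pi systems and heteroatoms.  Purely topological, deterministic,
    and swappable for any quantum provider.
    """
    rd = mol.rdmol
    a, b = bond
    rdbond = rd.GetBondBetweenAtoms(a, b)
    if rdbond is None:
        raise BackendError(f"no bond between atoms {a} and {b}")
    order = rdbond.GetBondTypeAsDouble()
    dists = Chem.GetDistanceMatrix(rd)
    total = float(order)
    for atom in rd.GetAtoms():
        idx = atom.GetIdx()
        if idx in (a, b):
            continue
        dist = int(min(dists[idx][a], dists[idx][b]))
        if dist not in _DELOC_WEIGHT:
            continue
        feature = 0.0
        if atom.GetIsAromatic() or any(
            bd.GetBondTypeAsDouble() > 1.0 for bd in atom.GetBonds()
        ):
            feature += 1.0
        if atom.GetAtomicNum() in (7, 8, 9, 16, 17, 35, 53):
            feature += 0.5
        total += _DELOC_WEIGHT[dist] * feature
    return total


# ---------------------------------------------------------------------------
# Fragment construction


def _closure(mol: Molecule, seed: set[int]) -> set[int]:
    """Close an atom set over whole rings and over non-single boundary bonds."""
    rd = mol.rdmol
    ring_info = rd.GetRingInfo()
    atoms = set(seed)
    changed = True
    while changed:
        changed = False
        for ring in ring_info.AtomRings():
            ring_set = set(ring)
            if atoms & ring_set and not ring_set <= atoms:
                atoms |= ring_set
                changed = True
        for bond in rd.GetBonds():
            if bond.GetBondTypeAsDouble() == 1.0:
                continue
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if (i in atoms) != (j in atoms):
                atoms.update((i, j))
                changed = True
    # hydrogens of included atoms belong to the fragment (caps replace heavy atoms only)
    for a in list(atoms):
        for n in rd.GetAtomWithIdx(a).GetNeighbors():
            if n.GetAtomicNum() == 1:
                atoms.add(n.GetIdx())
    return atoms


def _extract(parent: Molecule, atom_set: set[int], bond: tuple[int, int]) -> Fragment:
    """Copy an atom subset into a capped fragment molecule."""
    kek = Chem.Mol(parent.rdmol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    rw = Chem.RWMol()
    frag_idx: dict[int, int] = {}
    for p in sorted(atom_set):
        src = kek.GetAtomWithIdx(p)
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetNoImplicit(True)
        frag_idx[p] = rw.AddAtom(atom)
    caps = set()
    cap_map = {}
    for b in kek.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in atom_set and j in atom_set:
            rw.AddBond(frag_idx[i], frag_idx[j], b.GetBondType())
        elif i in atom_set or j in atom_set:
            inside, outside = (i, j) if i in atom_set else (j, i)
            cap = rw.AddAtom(Chem.Atom(1))
            rw.AddBond(frag_idx[inside], cap, Chem.BondType.SINGLE)
            caps.add(cap)
            cap_map[cap] = outside
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Fragment(
        molecule=Molecule(mol, name=f"{parent.name}-frag-{bond[0]}-{bond[1]}"),
        parent_map={f: p for p, f in frag_idx.items()},
        target_bond=(frag_idx[bond[0]], frag_idx[bond[1]]),
        cap_atoms=frozenset(caps),
        cap_map=cap_map,
    )


def initial_fragment(parent: Molecule, bond: tuple[int, int]) -> Fragment:
    """Smallest capped shell: bond atoms + one-bond neighbourhood + closures."""
    bond = tuple(sorted(bond))
    if bond not in find_rotatable_bonds(parent):
        raise UsageError(f"bond {bond} is not rotatable in the parent")
    seed = {bond[0], bond[1]}
    for a in bond:
        seed.update(parent.neighbors(a))
    return _extract(parent, _closure(parent, seed), bond)


def _substituent_candidates(parent: Molecule, atoms: set[int]) -> list[set[int]]:
    """Growable substituents: closure of each outside atom adjacent to the set."""
    rd = parent.rdmol
    frontier = sorted(
        {n for a in atoms for n in parent.neighbors(a)} - atoms
    )
    candidates = []
    seen = set()
    for v in frontier:
        add = _closure(parent, atoms | {v}) - atoms
        key = frozenset(add)
        if key not in seen:
            seen.add(key)
            candidates.append((len(add), min(add), add))
    # tie-break: smallest added atom count, then lowest parent atom index
    return [c[2] for c in sorted(candidates, key=lambda c: (c[0], c[1]))]


def fragment_molecule(
    parent: Molecule,
    provider: BondOrderProvider = surrogate_bond_order,
    threshold: float = DEFAULT_WBO_THRESHOLD,
) -> list[tuple[Fragment, WboReport]]:
    """One accepted (Fragment, WboReport) per rotatable bond of the parent."""
    results = []
    for bond in find_rotatable_bonds(parent):
        results.append(_fragment_bond(parent, bond, provider, threshold))
    return results


def _fragment_bond(parent, bond, provider, threshold):
    try:
        wbo_parent = provider(parent, bond)
    except Exception as exc:  # provider contract failure
        raise BackendError(f"bond-order provider failed on parent bond {bond}: {exc}") from exc
    frag = initial_fragment(parent, bond)
    atoms = set(frag.parent_map.values())
    parent_atoms = set(range(parent.n_atoms))
    while True:
        if atoms == parent_atoms:
            # the parent is its own fragment: exact by construction
            frag = _extract(parent, atoms, bond)
            return frag, WboReport(wbo_parent, wbo_parent, threshold)
        frag = _extract(parent, atoms, bond)
        try:
            wbo_frag = provider(frag.molecule, frag.target_bond)
        except Exception as exc:
            raise BackendError(f"bond-order provider failed on fragment of bond {bond}: {exc}") from exc
        report = WboReport(wbo_parent, wbo_frag, threshold)
        if report.accepted:
            return frag, report
        best = None
        for add in _substituent_candidates(parent, atoms):
            trial = _extract(parent, atoms | add, bond)
            try:
                wbo_trial = provider(trial.molecule, trial.target_bond)
            except Exception as exc:
                raise BackendError(f"bond-order provider failed during growth at bond {bond}: {exc}") from exc
            delta = abs(wbo_parent - wbo_trial)
            if best is None or delta < best[0] - 1e-12:
                best = (delta, add)
        atoms |= best[1]
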