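"""Highly specific SMIRKS pattern generation for bespoke torsion parameters.

Each pattern embeds the common substructure shared by a fragment and its
parent, tags the four dihedral atoms with map indices :1-:4, and pins every
atom down with a fixed attribute set (atomic number, aromaticity, degree,
total hydrogen count, formal charge, ring membership).  Where the parent and
fragment differ — at hydrogen-capped cut sites — the differing attributes
become OR alternatives, so the one pattern matches both molecules (and any
other molecule sharing the exact substructure) while remaining too specific
to fire on unrelated chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .chem import Molecule, TorsionQuartet, TorsionTypeGroup
from .errors import ConsistencyError, InputError, TorsionForgeError

__all__ = ["AtomSpec", "SmirksPattern", "mcs_map", "generate_smirks", "match"]


@dataclass(frozen=True)
class AtomSpec:
    """OR-lists of atom attributes; single-valued lists render without ORs."""

    elements: tuple[int, ...]
    aromatic: tuple[bool, ...]
    degree: tuple[int, ...]
    h_count: tuple[int, ...]
    charge: tuple[int, ...]
    in_ring: tuple[bool, ...]

    def __post_init__(self):
        for name in ("elements", "aromatic", "degree", "h_count", "charge", "in_ring"):
            if not getattr(self, name):
                raise ConsistencyError(f"empty OR-list for atom attribute {name}")

    @property
    def has_or(self) -> bool:
        return any(
            len(set(getattr(self, f))) > 1
            for f in ("elements", "aromatic", "degree", "h_count", "charge", "in_ring")
        )

    def to_smarts(self, map_index: int = 0) -> str:
        clauses = [",".join(f"#{z}" for z in sorted(set(self.elements)))]
        arom = set(self.aromatic)
        if len(arom) == 1:
            clauses.append("a" if arom.pop() else "A")
        clauses.append(",".join(f"X{d}" for d in sorted(set(self.degree))))
        clauses.append(",".join(f"H{h}" for h in sorted(set(self.h_count))))
        clauses.append(",".join(_charge_token(c) for c in sorted(set(self.charge))))
        ring = set(self.in_ring)
        if len(ring) == 1:
            clauses.append("R" if ring.pop() else "!R")
        body = ";".join(clauses)
        return f"[{body}:{map_index}]" if map_index else f"[{body}]"


def _charge_token(c: int) -> str:
    if c == 0:
        return "+0"
    return f"+{c}" if c > 0 else str(c)


def _atom_attrs(mol: Molecule, idx: int) -> tuple:
    atom = mol.rdmol.GetAtomWithIdx(idx)
    n_h = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() == 1)
    return (
        atom.GetAtomicNum(),
        atom.GetIsAromatic(),
        atom.GetDegree(),
        n_h,
        atom.GetFormalCharge(),
        atom.IsInRing(),
    )


@dataclass(frozen=True)
class SmirksPattern:
    """A SMARTS string with map indices :1..:4 on the dihedral quartet."""

    smarts: str
    source_key: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise InputError(f"invalid SMARTS: {self.smarts!r}")
        maps = sorted(
            a.GetAtomMapNum() for a in query.GetAtoms() if a.GetAtomMapNum()
        )
        if maps != [1, 2, 3, 4]:
            raise InputError(
                f"pattern must carry exactly map indices 1-4, found {maps}"
            )

    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)

    def tagged_positions(self) -> list[int]:
        """Query-atom indices of map numbers 1..4, in map order."""
        query = self.query()
        by_map = {a.GetAtomMapNum(): a.GetIdx() for a in query.GetAtoms() if a.GetAtomMapNum()}
        return [by_map[m] for m in (1, 2, 3, 4)]


# ---------------------------------------------------------------------------
# Parent/fragment common-substructure mapping


def mcs_map(parent: Molecule, fragment) -> tuple[dict[int, int], dict[int, list[str]]]:
    """Validate the fragment->parent atom map and diff atom environments.

    The fragment's own parent map is the seed of the common substructure (the
    fragment was carved out of the parent, so the map is exact); this
    operation checks the map is injective, connected, and bond-consistent,
    then reports which attributes differ per fragment atom (cut-adjacent
    atoms differ in hydrogen count; cap hydrogens differ from the parent
    substituents they replaced).
    """
    fmol = fragment.molecule
    pmap = dict(fragment.parent_map)
    if len(set(pmap.values())) != len(pmap):
        raise ConsistencyError("fragment parent_map is not injective")
    for f_i, p_i in pmap.items():
        zf = fmol.rdmol.GetAtomWithIdx(f_i).GetAtomicNum()
        zp = parent.rdmol.GetAtomWithIdx(p_i).GetAtomicNum()
        if zf != zp:
            raise ConsistencyError(f"mapped atoms {f_i}->{p_i} differ in element")
    # bond consistency + connectivity over the mapped subgraph
    seen = set()
    stack = [fragment.target_bond[0]]
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        for nbr in fmol.neighbors(cur):
            if nbr in pmap:
                if parent.rdmol.GetBondBetweenAtoms(pmap[cur], pmap[nbr]) is None:
                    raise ConsistencyError(
                        f"fragment bond {cur}-{nbr} has no parent counterpart"
                    )
                stack.append(nbr)
    if seen != set(pmap):
        raise ConsistencyError("mapped substructure is disconnected")

    attr_names = ["element", "aromatic", "degree", "h_count", "charge", "in_ring"]
    diffs: dict[int, list[str]] = {}
    for f_i, p_i in pmap.items():
        delta = [
            name
            for name, a, b in zip(
                attr_names, _atom_attrs(fmol, f_i), _atom_attrs(parent, p_i)
            )
            if a != b
        ]
        if delta:
            diffs[f_i] = delta
    for cap, p_i in fragment.cap_map.items():
        diffs[cap] = [
            name
            for name, a, b in zip(
                attr_names, _atom_attrs(fmol, cap), _atom_attrs(parent, p_i)
            )
            if a != b
        ]
    return pmap, diffs


# ---------------------------------------------------------------------------
# Pattern generation


def generate_smirks(parent: Molecule, fragment, group: TorsionTypeGroup) -> SmirksPattern:
    """Build the tagged pattern for one torsion type group of a fragment."""
    fmol = fragment.molecule
    pmap, _ = mcs_map(parent, fragment)

    specs: dict[int, AtomSpec] = {}
    for f_i in range(fmol.n_atoms):
        f_attrs = _atom_attrs(fmol, f_i)
        if f_i in pmap:
            p_attrs = _atom_attrs(parent, pmap[f_i])
        elif f_i in fragment.cap_map:
            p_attrs = _atom_attrs(parent, fragment.cap_map[f_i])
        else:  # pragma: no cover - caps always carry a cap_map entry
            p_attrs = f_attrs
        specs[f_i] = AtomSpec(
            *(tuple({fa, pa}) if fa != pa else (fa,) for fa, pa in zip(f_attrs, p_attrs))
        )

    quartet = group.quartets[0]
    tags = {atom: pos + 1 for pos, atom in enumerate(quartet.atoms)}
    smarts = _render(fmol, parent, fragment, specs, tags)
    pattern = SmirksPattern(smarts, source_key=group.type_key)

    matched = set(match(pattern, fmol))
    expected = set(group.quartets)
    if not expected <= matched:
        raise TorsionForgeError(
            f"generated pattern fails self-match: {smarts} "
            f"(matched {len(matched)}, expected {len(expected)})"
        )
    return pattern


def _bond_smarts(mol: Molecule, i: int, j: int, ring_known: bool = True) -> str:
    bond = mol.rdmol.GetBondBetweenAtoms(i, j)
    sym = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":"}[bond.GetBondTypeAsDouble()]
    if not ring_known:
        return sym
    return sym + (";@" if bond.IsInRing() else ";!@")


def _render(fmol, parent, fragment, specs, tags) -> str:
    """Deterministic DFS SMARTS writer with ring closures, rooted at tag :1.

    Neighbours are visited in ascending fragment-atom-index order, which is
    reproducible because fragment atom numbering is itself deterministic.
    """
    root = next(a for a, t in tags.items() if t == 1)
    visited: set[int] = set()
    closure_bonds: dict[frozenset, int] = {}  # back edge -> ring-closure digit
    counter = [0]

    def scan(i, from_atom):
        visited.add(i)
        for j in fmol.neighbors(i):
            if j == from_atom:
                continue
            key = frozenset((i, j))
            if key in closure_bonds:
                continue
            if j in visited:
                counter[0] += 1
                closure_bonds[key] = counter[0]
            else:
                scan(j, i)

    scan(root, -1)
    visited.clear()

    def ring_flag_known(i, j) -> bool:
        # drop the ring-membership bond token when parent/fragment disagree
        if i in fragment.parent_map and j in fragment.parent_map:
            pb = parent.rdmol.GetBondBetweenAtoms(
                fragment.parent_map[i], fragment.parent_map[j]
            )
            fb = fmol.rdmol.GetBondBetweenAtoms(i, j)
            return pb is not None and pb.IsInRing() == fb.IsInRing()
        return True

    open_digits: set[int] = set()

    def write(i, from_atom) -> str:
        visited.add(i)
        out = specs[i].to_smarts(tags.get(i, 0))
        incident = sorted(
            (key for key in closure_bonds if i in key), key=closure_bonds.get
        )
        for key in incident:
            num = closure_bonds[key]
            j = next(a for a in key if a != i)
            if num not in open_digits:
                open_digits.add(num)
                out += _bond_smarts(fmol, i, j, ring_flag_known(i, j)) + _digit(num)
            else:
                out += _digit(num)
        branches = []
        for j in fmol.neighbors(i):
            if j == from_atom or j in visited or frozenset((i, j)) in closure_bonds:
                continue
            branches.append(_bond_smarts(fmol, i, j, ring_flag_known(i, j)) + write(j, i))
        if not branches:
            return out
        return out + "".join(f"({b})" for b in branches[:-1]) + branches[-1]

    return write(root, -1)


def _digit(n: int) -> str:
    return str(n) if n < 10 else f"%{n:02d}"


# ---------------------------------------------------------------------------
# Matching


def match(pattern: SmirksPattern, mol: Molecule) -> list[TorsionQuartet]:
    """All tagged-atom quartets the pattern embeds in a molecule.

    Embeddings are deduplicated under quartet reversal.
    """
    query = pattern.query()
    if query is None:
        raise InputError(f"invalid SMARTS: {pattern.smarts!r}")
    positions = pattern.tagged_positions()
    quartets = set()
    for emb in mol.rdmol.GetSubstructMatches(query, uniquify=False, maxMatches=100000):
        quartets.add(TorsionQuartet(*(emb[p] for p in positions)))
    return sorted(quartets, key=lambda q: q.atoms)
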