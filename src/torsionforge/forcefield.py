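"""SMIRKS-keyed hierarchical torsion parameter store.

Torsion parameters are keyed by tagged SMARTS patterns and assigned by
direct chemical perception: every record whose pattern embeds a quartet is
a candidate, and the *last* matching record in file order wins.  Bespoke
records are appended at the bottom of the hierarchy, after every base
record, so they take precedence exactly when their highly specific
substructure is present.  Bond/angle/nonbonded blocks of the base force
field are carried as opaque, round-tripped data (the MM engine parametrizes
them from its generic tables).

A fragment-keyed parameter cache lets congeneric series reuse fitted core
parameters: the key is the canonical SMILES of the fragment with map
indices 1-4 on the torsion atoms, which is identical for graph-isomorphic
fragments with equivalent mapped torsions.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace


from .chem import Molecule, TorsionQuartet, enumerate_quartets
from .energy import TorsionTerm
from .errors import CoverageError, InputError
from .smirks import SmirksPattern

GENERIC_TORSION_SMIRKS = "[*:1]~[*:2]~[*:3]~[*:4]"

__all__ = [
    "TorsionParameterRecord",
    "ForceField",
    "ParameterCache",
    "default_base_forcefield",
    "assign_torsions",
    "add_bespoke",
    "combine",
    "read_ff",
    "write_ff",
]


@dataclass(frozen=True)
class TorsionParameterRecord:
    """One SMIRKS-keyed proper-torsion parameter."""

    smirks: str
    terms: tuple[TorsionTerm, ...]
    id: str
    source: str = "base"  # "base" | "bespoke"
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        SmirksPattern(self.smirks)  # validates SMARTS + 4 mapped atoms
        ns = [t.n for t in self.terms]
        if len(ns) != len(set(ns)) or len(ns) > 4:
            raise InputError(
                f"record {self.id!r}: needs <= 4 terms with distinct periodicities, got n={ns}"
            )

    def pattern(self) -> SmirksPattern:
        return SmirksPattern(self.smirks)


@dataclass
class ForceField:
    """Ordered torsion hierarchy (top = most general) plus static base blocks."""

    name: str = "torsionforge-base"
    torsions: list[TorsionParameterRecord] = field(default_factory=list)
    static_blocks: dict = field(default_factory=dict)  # opaque bonds/angles/vdW data
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._check_order()

    def _check_order(self):
        seen_bespoke = False
        for rec in self.torsions:
            if rec.source == "bespoke":
                seen_bespoke = True
            elif seen_bespoke:
                raise InputError(
                    f"base record {rec.id!r} appears after a bespoke record; "
                    "bespoke parameters must sit at the bottom of the hierarchy"
                )

    def copy(self) -> "ForceField":
        return ForceField(
            name=self.name,
            torsions=list(self.torsions),
            static_blocks=dict(self.static_blocks),
            metadata=dict(self.metadata),
        )


def default_base_forcefield() -> ForceField:
    """Minimal generic base: one wildcard proper-torsion record with k = 0.

    Real published force fields are deliberately not bundled; the base serves
    as the hierarchy root every bespoke record refines.
    """
    return ForceField(
        torsions=[
            TorsionParameterRecord(
                smirks=GENERIC_TORSION_SMIRKS,
                terms=(TorsionTerm(k=0.0, n=3, phase=0.0),),
                id="t-generic",
                source="base",
            )
        ]
    )


# ---------------------------------------------------------------------------
# Assignment


def assign_torsions(
    ff: ForceField, mol: Molecule
) -> dict[TorsionQuartet, TorsionParameterRecord]:
    """Map every bonded quartet of the molecule to its governing record.

    Last match in hierarchy order wins; an unmatched quartet is a coverage
    error naming the quartet.
    """
    all_quartets: set[TorsionQuartet] = set()
    for bond in mol.rdmol.GetBonds():
        j, k = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if mol.rdmol.GetAtomWithIdx(j).GetDegree() < 2:
            continue
        if mol.rdmol.GetAtomWithIdx(k).GetDegree() < 2:
            continue
        all_quartets.update(enumerate_quartets(mol, (min(j, k), max(j, k))))

    assignment: dict[TorsionQuartet, TorsionParameterRecord] = {}
    for record in ff.torsions:  # later records overwrite earlier matches
        from .smirks import match as smirks_match

        for quartet in smirks_match(record.pattern(), mol):
            if quartet in all_quartets:
                assignment[quartet] = record
    missing = all_quartets - set(assignment)
    if missing:
        sample = sorted(q.atoms for q in missing)[:5]
        raise CoverageError(f"no torsion record matches quartets {sample}")
    return assignment


# ---------------------------------------------------------------------------
# Hierarchy editing


def add_bespoke(ff: ForceField, records: list[TorsionParameterRecord]) -> ForceField:
    """Append bespoke records at the bottom of the hierarchy (new object)."""
    out = ff.copy()
    for rec in records:
        rec = replace(rec, source="bespoke") if rec.source != "bespoke" else rec
        existing = {r.smirks: r for r in out.torsions}
        if rec.smirks in existing:
            if existing[rec.smirks].terms == rec.terms:
                continue  # identical duplicate
            raise InputError(
                f"conflicting parameters for SMIRKS {rec.smirks!r}: "
                f"{existing[rec.smirks].terms} vs {rec.terms}"
            )
        out.torsions.append(rec)
    out._check_order()
    return out


def combine(ffs: list[ForceField]) -> ForceField:
    """Merge bespoke hierarchies sharing one base into a single force field.

    Identical (SMIRKS, terms) records are deduplicated; identical SMIRKS with
    different terms is a conflict error.  Associative and idempotent.
    """
    if not ffs:
        raise InputError("nothing to combine")
    names = {ff.name for ff in ffs}
    if len(names) > 1:
        raise InputError(f"cannot combine force fields with different bases: {sorted(names)}")
    base_records = [r for r in ffs[0].torsions if r.source == "base"]
    for ff in ffs[1:]:
        other_base = [r for r in ff.torsions if r.source == "base"]
        if [(r.smirks, r.terms) for r in other_base] != [
            (r.smirks, r.terms) for r in base_records
        ]:
            raise InputError("combined force fields disagree on base records")
    out = ForceField(
        name=ffs[0].name,
        torsions=list(base_records),
        static_blocks=dict(ffs[0].static_blocks),
        metadata={"combined_from": len(ffs)},
    )
    for ff in ffs:
        out = add_bespoke(out, [r for r in ff.torsions if r.source == "bespoke"])
    return out


# ---------------------------------------------------------------------------
# Parameter cache


class ParameterCache:
    """Fitted-term cache keyed by canonical mapped fragment SMILES."""

    def __init__(self):
        self._store: dict[str, tuple[TorsionTerm, ...]] = {}

    @staticmethod
    def key(fragment_mol: Molecule, quartet) -> str:
        # orientation-invariant: a quartet and its reverse share the key, and
        # canonical SMILES makes the key identical across graph isomorphs
        atoms = tuple(quartet) if not isinstance(quartet, TorsionQuartet) else quartet.atoms
        forward = fragment_mol.to_smiles(
            mapped_atoms={a: i + 1 for i, a in enumerate(atoms)}
        )
        backward = fragment_mol.to_smiles(
            mapped_atoms={a: i + 1 for i, a in enumerate(atoms[::-1])}
        )
        return min(forward, backward)

    def store(self, fragment_mol: Molecule, quartet, terms) -> str:
        key = self.key(fragment_mol, quartet)
        self._store[key] = tuple(terms)
        return key

    def lookup(self, fragment_mol: Molecule, quartet) -> tuple[TorsionTerm, ...] | None:
        return self._store.get(self.key(fragment_mol, quartet))

    def __len__(self):
        return len(self._store)


# ---------------------------------------------------------------------------
# Serialization (JSON primary, offxml-like XML export)


def write_ff(ff: ForceField, path: str) -> None:
    if path.endswith(".xml") or path.endswith(".offxml"):
        _write_xml(ff, path)
        return
    payload = {
        "name": ff.name,
        "torsions": [
            {
                "id": r.id,
                "smirks": r.smirks,
                "source": r.source,
                "terms": [{"k": t.k, "n": t.n, "phase": t.phase} for t in r.terms],
                "provenance": r.provenance,
            }
            for r in ff.torsions
        ],
        "static_blocks": ff.static_blocks,
        "metadata": ff.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_ff(path: str) -> ForceField:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InputError(f"{path}: not valid force-field JSON: {exc}") from exc
    if not isinstance(payload.get("torsions"), list):
        raise InputError(f"{path}: missing 'torsions' list at document root")
    records = []
    for pos, raw in enumerate(payload["torsions"]):
        try:
            records.append(
                TorsionParameterRecord(
                    smirks=raw["smirks"],
                    terms=tuple(
                        TorsionTerm(k=float(t["k"]), n=int(t["n"]), phase=float(t.get("phase", 0.0)))
                        for t in raw["terms"]
                    ),
                    id=str(raw.get("id", f"t{pos}")),
                    source=raw.get("source", "base"),
                    provenance=raw.get("provenance", {}),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"{path}: torsions[{pos}]: {exc}") from exc
    try:
        return ForceField(
            name=payload.get("name", "torsionforge-base"),
            torsions=records,
            static_blocks=payload.get("static_blocks", {}),
            metadata=payload.get("metadata", {}),
        )
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def _write_xml(ff: ForceField, path: str) -> None:
    root = ET.Element("ForceField", {"name": ff.name})
    block = ET.SubElement(root, "ProperTorsions", {"potential": "k*(1+cos(periodicity*theta-phase))"})
    for rec in ff.torsions:
        attrs = {"smirks": rec.smirks, "id": rec.id, "source": rec.source}
        for pos, term in enumerate(rec.terms, start=1):
            attrs[f"k{pos}"] = f"{term.k} * kilocalorie/mole"
            attrs[f"periodicity{pos}"] = str(term.n)
            attrs[f"phase{pos}"] = f"{term.phase} * degree"
        ET.SubElement(block, "Proper", attrs)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
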