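"""End-to-end bespoke parametrization workflow and dataset factory.

``run_bespoke`` chains the full pipeline for one molecule: fragment every
rotatable bond under the WBO gate, type the torsions of each fragment,
generate their SMIRKS, produce a reference scan per fragment (from the MM
baseline, a seeded synthetic surface, or user-supplied scan files), fit all
bespoke force constants simultaneously, and append the fitted records to
the base force-field hierarchy.  Workflow settings live in a versioned,
JSON-round-trippable schema; identical schema + seed reproduces outputs
byte for byte.  A parameter cache keyed by canonical mapped fragment SMILES
short-circuits the scan + fit for torsions already fitted in a congeneric
series.

The dataset factory mirrors large-scale curation tooling in miniature:
modular components (filters, a state-enumeration placeholder, fragmentation,
conformer generation) applied in order, each logging kept/removed counts,
with final deduplication by (canonical mapped SMILES, driven bond).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .chem import Molecule, perceive, find_rotatable_bonds, torsion_type_groups
from .energy import build_system
from .errors import InputError, TorsionForgeError
from .fitting import FitTarget, ObjectiveConfig, fit as run_fit
from .forcefield import (
    ForceField,
    ParameterCache,
    TorsionParameterRecord,
    add_bespoke,
    assign_torsions,
    default_base_forcefield,
)
from .fragment import fragment_molecule, surrogate_bond_order
from .scan import Grid, MMScanBackend, TorsionScanResult, run_scan, seed_conformers
from .smirks import generate_smirks
from .synthetic import injected_terms

logger = logging.getLogger("torsionforge")

__all__ = [
    "WorkflowSchema",
    "WorkflowStageError",
    "TorsionDataset",
    "DatasetEntry",
    "ElementFilter",
    "StateEnumeration",
    "ConformerGeneration",
    "build_dataset",
    "run_bespoke",
]


class WorkflowStageError(TorsionForgeError):
    """Failure in one named pipeline stage, carrying the offending inputs."""

    def __init__(self, stage: str, inputs: dict, cause: Exception):
        self.stage = stage
        self.inputs = inputs
        self.cause = cause
        super().__init__(f"stage {stage!r} failed on {inputs}: {cause}")


# ---------------------------------------------------------------------------
# Workflow schema


class FragmentationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float = 0.03  # e; WBO acceptance band
    provider: Literal["surrogate"] = "surrogate"


class ReferenceSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backend: Literal["mm", "analytic", "scan-file"] = "analytic"
    grid_spacing: float = 15.0  # degrees
    max_conformers: int = 4
    scan_files: list[str] = Field(default_factory=list)


class ObjectiveSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scale_factor: float = 1.0
    weight_cutoff_low: float = 1.0
    weight_cutoff_high: float = 10.0
    prior_width: float = 6.0
    regularization: Literal["L1", "L2"] = "L1"
    restraint_k: float | None = 1.0
    rmsd_in_objective: bool = False
    rmsd_weight: float = 1.0

    def to_config(self) -> ObjectiveConfig:
        return ObjectiveConfig(**self.model_dump())


class WorkflowSchema(BaseModel):
    """Versioned, lossless-round-trip workflow configuration."""

    model_config = ConfigDict(extra="forbid")
    version: int = 1
    fragmentation: FragmentationSettings = Field(default_factory=FragmentationSettings)
    reference: ReferenceSettings = Field(default_factory=ReferenceSettings)
    objective: ObjectiveSettings = Field(default_factory=ObjectiveSettings)
    seed: int = 2024

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "WorkflowSchema":
        try:
            with open(source) as fh:
                payload = json.load(fh)
        except OSError:
            payload = json.loads(source)
        return cls.model_validate(payload)


# ---------------------------------------------------------------------------
# Bespoke pipeline


def _derived_seed(seed: int, index: int) -> int:
    return (seed * 9973 + 7919 * index + 1) % (2**31 - 1)


def run_bespoke(
    smiles_or_mol,
    workflow: WorkflowSchema | None = None,
    base_ff: ForceField | None = None,
    cache: ParameterCache | None = None,
) -> tuple[dict, ForceField]:
    """Full bespoke parametrization of one molecule.

    Returns (report, force field).  The report records, per stage, every
    fragment, WBO acceptance, scan provenance and fitted parameter, so each
    bespoke record is traceable to the scan and fragment that produced it.
    """
    workflow = workflow or WorkflowSchema()
    base_ff = base_ff or default_base_forcefield()
    grid = Grid(workflow.reference.grid_spacing)
    config = workflow.objective.to_config()

    try:
        mol = smiles_or_mol if isinstance(smiles_or_mol, Molecule) else perceive(smiles_or_mol)
    except Exception as exc:
        raise WorkflowStageError("input", {"input": str(smiles_or_mol)[:120]}, exc)

    report = {
        "molecule": mol.to_smiles(),
        "seed": workflow.seed,
        "workflow": workflow.model_dump(),
        "fragments": [],
        "fit": None,
        "cached": [],
    }
    rot_bonds = find_rotatable_bonds(mol)
    if not rot_bonds:
        report["fit"] = {"n_parameters": 0, "note": "no rotatable bonds"}
        report["bespoke_records"] = []
        return report, base_ff.copy()

    try:
        frag_results = fragment_molecule(
            mol, provider=surrogate_bond_order, threshold=workflow.fragmentation.threshold
        )
    except Exception as exc:
        raise WorkflowStageError("fragmentation", {"molecule": mol.to_smiles()}, exc)

    targets: list[FitTarget] = []
    pending_records: list[dict] = []  # group-level bookkeeping
    cached_records: list[TorsionParameterRecord] = []

    for frag_index, (frag, wbo) in enumerate(frag_results):
        frag_info = {
            "index": frag_index,
            "smiles": frag.molecule.to_smiles(),
            "parent_bond": sorted(frag.parent_map[a] for a in frag.target_bond),
            "wbo_parent": round(wbo.wbo_parent, 6),
            "wbo_fragment": round(wbo.wbo_fragment, 6),
            "wbo_accepted": wbo.accepted,
            "groups": [],
        }
        try:
            groups = torsion_type_groups(frag.molecule, frag.target_bond)
            patterns = [generate_smirks(mol, frag, g) for g in groups]
        except Exception as exc:
            raise WorkflowStageError(
                "smirks", {"fragment": frag.molecule.to_smiles()}, exc
            )

        all_cached = cache is not None and all(
            cache.lookup(frag.molecule, g.quartets[0]) is not None for g in groups
        )
        if all_cached:
            for g, pattern in zip(groups, patterns):
                terms = cache.lookup(frag.molecule, g.quartets[0])
                cached_records.append(
                    TorsionParameterRecord(
                        smirks=pattern.smarts,
                        terms=tuple(terms),
                        id=f"t-bespoke-cached-{frag_index}-{len(cached_records)}",
                        source="bespoke",
                        provenance={"cached": True, "fragment": frag.molecule.to_smiles()},
                    )
                )
                frag_info["groups"].append(
                    {"smirks": pattern.smarts, "cached": True, "n_quartets": len(g.quartets)}
                )
            report["cached"].append(frag_info["smiles"])
            report["fragments"].append(frag_info)
            continue

        try:
            system = build_system(frag.molecule)
            assignment = assign_torsions(base_ff, frag.molecule)
            for quartet, record in assignment.items():
                system.set_torsion_terms(quartet, list(record.terms))
        except Exception as exc:
            raise WorkflowStageError(
                "parametrization", {"fragment": frag.molecule.to_smiles()}, exc
            )

        frag_seed = _derived_seed(workflow.seed, frag_index)
        try:
            reference = _make_reference(
                workflow, frag_index, frag, groups, system, grid, frag_seed
            )
        except Exception as exc:
            raise WorkflowStageError(
                "reference-scan", {"fragment": frag.molecule.to_smiles()}, exc
            )

        initial_terms = {
            p.smarts: list(assignment[g.quartets[0]].terms)
            for g, p in zip(groups, patterns)
        }
        targets.append(
            FitTarget(
                system=system,
                reference=reference,
                groups=groups,
                parameter_keys=[p.smarts for p in patterns],
                initial_terms=initial_terms,
                name=f"fragment-{frag_index}",
            )
        )
        for g, pattern in zip(groups, patterns):
            frag_info["groups"].append(
                {"smirks": pattern.smarts, "cached": False, "n_quartets": len(g.quartets)}
            )
            pending_records.append(
                {"fragment_index": frag_index, "fragment": frag, "group": g, "smirks": pattern.smarts}
            )
        frag_info["scan"] = {
            "backend": reference.provenance.get("backend"),
            "n_points": len(reference.angles),
            "seed": frag_seed,
        }
        report["fragments"].append(frag_info)

    bespoke_records: list[TorsionParameterRecord] = list(cached_records)
    if targets:
        try:
            result = run_fit(targets, config)
        except Exception as exc:
            raise WorkflowStageError("fit", {"n_targets": len(targets)}, exc)
        report["fit"] = {
            "n_parameters": 4 * len(result.terms),
            "converged": result.converged,
            "n_outer": result.n_outer,
            "objective_trace": [round(v, 10) for v in result.objective_trace],
            "rmse_weighted": {k: round(v, 8) for k, v in result.rmse.items()},
            "rmse_full": {k: round(v, 8) for k, v in result.rmse_full.items()},
        }
        emitted = set()
        for pos, pending in enumerate(pending_records):
            smirks = pending["smirks"]
            if smirks in emitted:
                continue
            emitted.add(smirks)
            terms = tuple(result.terms[smirks])
            bespoke_records.append(
                TorsionParameterRecord(
                    smirks=smirks,
                    terms=terms,
                    id=f"t-bespoke-{pos}",
                    source="bespoke",
                    provenance={
                        "fragment": pending["fragment"].molecule.to_smiles(),
                        "target": f"fragment-{pending['fragment_index']}",
                        "rmse_weighted": report["fit"]["rmse_weighted"].get(
                            f"fragment-{pending['fragment_index']}"
                        ),
                    },
                )
            )
            if cache is not None:
                cache.store(
                    pending["fragment"].molecule, pending["group"].quartets[0], terms
                )
    elif report["fit"] is None:
        report["fit"] = {"n_parameters": 0, "note": "all torsions cached"}

    ff_out = add_bespoke(base_ff, bespoke_records)
    report["bespoke_records"] = [
        {"id": r.id, "smirks": r.smirks,
         "terms": [{"k": round(t.k, 8), "n": t.n, "phase": t.phase} for t in r.terms]}
        for r in bespoke_records
    ]
    return report, ff_out


def _make_reference(workflow, frag_index, frag, groups, system, grid, seed):
    backend_kind = workflow.reference.backend
    quartet = groups[0].quartets[0].atoms
    if backend_kind == "scan-file":
        files = workflow.reference.scan_files
        if frag_index >= len(files):
            raise InputError(
                f"no scan file supplied for fragment {frag_index} "
                f"({len(files)} file(s) given)"
            )
        path = files[frag_index]
        scan = (
            TorsionScanResult.from_csv(path)
            if path.endswith(".csv")
            else TorsionScanResult.from_json(path)
        )
        if scan.quartet is None:
            scan.quartet = quartet
        return scan

    scan_system = system
    if backend_kind == "analytic":
        # synthetic reference: base-assigned system + deterministic injected terms
        scan_system = build_system(frag.molecule)
        for q, terms in system.torsions.items():
            scan_system.set_torsion_terms(q, terms)
        for g_index, group in enumerate(groups):
            terms = injected_terms(_derived_seed(seed, g_index), n_terms=2, k_range=(0.5, 2.0))
            for q in group.quartets:
                scan_system.set_torsion_terms(q, terms)
    seeds = seed_conformers(
        frag.molecule, max_n=workflow.reference.max_conformers, seed=seed
    )
    return run_scan(MMScanBackend(scan_system), frag.molecule, quartet, seeds, grid)


# ---------------------------------------------------------------------------
# Dataset factory


@dataclass
class DatasetEntry:
    molecule: Molecule
    driven_bond: tuple[int, int] | None = None
    conformers: list = dc_field(default_factory=list)
    compute_spec: str = "default"

    def key(self) -> tuple[str, tuple[int, int]] | None:
        if self.driven_bond is None:
            return None
        mapped = self.molecule.to_smiles(
            mapped_atoms={self.driven_bond[0]: 1, self.driven_bond[1]: 2}
        )
        return (mapped, tuple(sorted(self.driven_bond)))


@dataclass
class TorsionDataset:
    entries: list[DatasetEntry]
    provenance: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "entries": [
                {
                    "mapped_smiles": (e.key() or (e.molecule.to_smiles(), None))[0],
                    "driven_bond": list(e.driven_bond) if e.driven_bond else None,
                    "n_conformers": len(e.conformers),
                    "compute_spec": e.compute_spec,
                }
                for e in self.entries
            ],
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


class ElementFilter:
    """Keep molecules whose elements all lie in an allowed set."""

    name = "element-filter"

    def __init__(self, allowed: set[str] = frozenset({"C", "H", "N", "O", "S", "F", "Cl"})):
        self.allowed = set(allowed)

    def __call__(self, entries):
        kept, removed = [], 0
        for entry in entries:
            symbols = {a.GetSymbol() for a in entry.molecule.rdmol.GetAtoms()}
            if symbols <= self.allowed:
                kept.append(entry)
            else:
                removed += 1
        return kept, {"component": self.name, "kept": len(kept), "removed": removed}


class StateEnumeration:
    """Placeholder: tautomer/protomer enumeration is deliberately not done."""

    name = "state-enumeration"

    def __call__(self, entries):
        logger.warning("state enumeration requested but not implemented; passing through")
        return list(entries), {
            "component": self.name,
            "kept": len(entries),
            "removed": 0,
            "note": "no-op placeholder",
        }


class FragmentationComponent:
    """Expand each molecule into WBO-accepted fragments, one per rotatable bond."""

    name = "fragmentation"

    def __init__(self, threshold: float = 0.03):
        self.threshold = threshold

    def __call__(self, entries):
        out = []
        failures = 0
        for entry in entries:
            try:
                for frag, _ in fragment_molecule(entry.molecule, threshold=self.threshold):
                    out.append(
                        DatasetEntry(
                            molecule=frag.molecule,
                            driven_bond=frag.target_bond,
                            compute_spec=entry.compute_spec,
                        )
                    )
            except Exception as exc:
                failures += 1
                logger.warning("fragmentation failed for %s: %s", entry.molecule.to_smiles(), exc)
        return out, {"component": self.name, "kept": len(out), "removed": failures}


class ConformerGeneration:
    """Attach up to max_n diverse conformers to every entry."""

    name = "conformer-generation"

    def __init__(self, max_n: int = 4, seed: int = 2024):
        self.max_n = max_n
        self.seed = seed

    def __call__(self, entries):
        kept = []
        failures = 0
        for entry in entries:
            try:
                entry.conformers = seed_conformers(entry.molecule, self.max_n, seed=self.seed)
                kept.append(entry)
            except Exception as exc:
                failures += 1
                logger.warning("conformers failed for %s: %s", entry.molecule.to_smiles(), exc)
        return kept, {"component": self.name, "kept": len(kept), "removed": failures}


def build_dataset(components, molecules) -> TorsionDataset:
    """Apply workflow components in order and deduplicate the result.

    Deduplication key: (canonical mapped SMILES with the driven bond tagged,
    central bond); entries without a driven bond are deduplicated by plain
    canonical SMILES.
    """
    if not molecules:
        raise InputError("dataset factory needs at least one molecule")
    entries = [
        DatasetEntry(molecule=m if isinstance(m, Molecule) else perceive(m))
        for m in molecules
    ]
    logs = []
    for component in components:
        entries, log = component(entries)
        logs.append(log)
    unique: dict = {}
    for entry in entries:
        key = entry.key() or (entry.molecule.to_smiles(), None)
        unique.setdefault(key, entry)
    return TorsionDataset(
        entries=list(unique.values()),
        provenance={"components": logs, "n_input": len(molecules), "n_unique": len(unique)},
    )
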