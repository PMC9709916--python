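"""1D torsion scans on a regular dihedral grid with wavefront propagation.

A scan constrains the driven dihedral to each point of a regular grid over
(-180, 180] and relaxes all other degrees of freedom.  Whenever a grid point
finds a new structure lower than its current best by more than ``e_tol``,
that structure is rotated by one grid spacing in both directions and queued
as a fresh starting point for the two neighbouring grid points.  This
wavefront propagation lets low-energy structures discovered anywhere on the
grid spread outward, avoiding the hysteresis that plagues sequential scans
of molecules with multiple coupled rotors.  The per-point best energy is
non-increasing, so termination is guaranteed.

Backends are pluggable: anything exposing ``dihedral``, ``set_dihedral`` and
``optimize_at`` over an opaque geometry object can drive a scan — the MM
model here, an analytic toy surface, or an external quantum engine.
"""

from __future__ import annotations

import csv
import json
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule, TorsionQuartet
from .energy import ParametrizedSystem, dihedral_angle, minimize, set_dihedral
from .errors import BackendError, UsageError

DEFAULT_GRID_SPACING = 15.0  # degrees
ENERGY_IMPROVEMENT_TOL = 1e-6  # kcal/mol
MAX_FAILED_FRACTION = 0.1

__all__ = [
    "Grid",
    "TorsionScanResult",
    "MMScanBackend",
    "run_scan",
    "seed_conformers",
    "write_xyz",
    "read_xyz",
]


def write_xyz(path: str, symbols: list[str], frames: list, comments: list[str] | None = None):
    """Write conformer frames as a multi-frame XYZ file (Angstrom)."""
    with open(path, "w") as fh:
        for idx, frame in enumerate(frames):
            frame = np.asarray(frame, dtype=float)
            fh.write(f"{len(symbols)}\n")
            fh.write((comments[idx] if comments else f"frame {idx}") + "\n")
            for sym, (x, y, z) in zip(symbols, frame):
                fh.write(f"{sym} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: str):
    """Read a multi-frame XYZ file -> (symbols, list of (n,3) arrays)."""
    frames, symbols = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        count = int(lines[pos])
        block = lines[pos + 2 : pos + 2 + count]
        symbols = [ln.split()[0] for ln in block]
        frames.append(np.array([[float(v) for v in ln.split()[1:4]] for ln in block]))
        pos += 2 + count
    return symbols, frames


@dataclass(frozen=True)
class Grid:
    """Regular dihedral grid covering (-180, 180] (half-open, no duplicate)."""

    spacing: float = DEFAULT_GRID_SPACING

    def __post_init__(self):
        if 360.0 % self.spacing != 0:
            raise UsageError(f"grid spacing {self.spacing} must divide 360")

    @property
    def points(self) -> list[float]:
        n = int(round(360.0 / self.spacing))
        return [-180.0 + self.spacing * (i + 1) for i in range(n)]

    def snap(self, angle_deg: float) -> float:
        k = round((angle_deg + 180.0) / self.spacing)
        snapped = -180.0 + k * self.spacing
        while snapped <= -180.0:
            snapped += 360.0
        while snapped > 180.0:
            snapped -= 360.0
        return snapped

    def neighbors(self, angle_deg: float) -> tuple[float, float]:
        return (self.snap(angle_deg - self.spacing), self.snap(angle_deg + self.spacing))


@dataclass
class TorsionScanResult:
    """Best energy and geometry found at every grid angle of one scan."""

    angles: list[float]  # degrees, sorted
    energies: list[float]  # kcal/mol, raw backend scale
    geometries: list  # backend geometry object per point (may be None)
    quartet: tuple[int, int, int, int] | None = None
    provenance: dict = field(default_factory=dict)
    failed_points: list[float] = field(default_factory=list)

    @property
    def relative_energies(self) -> np.ndarray:
        e = np.asarray(self.energies, dtype=float)
        return e - e.min()

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "angles": list(self.angles),
            "energies": list(self.energies),
            "relative_energies": self.relative_energies.tolist(),
            "quartet": list(self.quartet) if self.quartet else None,
            "provenance": self.provenance,
            "failed_points": self.failed_points,
            "geometries": [
                np.asarray(g).tolist() if g is not None else None
                for g in self.geometries
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "TorsionScanResult":
        try:
            with open(source) as fh:
                payload = json.load(fh)
        except OSError:
            payload = json.loads(source)
        return cls(
            angles=[float(a) for a in payload["angles"]],
            energies=[float(e) for e in payload["energies"]],
            geometries=[
                np.asarray(g, dtype=float) if g is not None else None
                for g in payload.get("geometries", [None] * len(payload["angles"]))
            ],
            quartet=tuple(payload["quartet"]) if payload.get("quartet") else None,
            provenance=payload.get("provenance", {}),
            failed_points=payload.get("failed_points", []),
        )

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["angle_deg", "relative_energy_kcal_mol"])
            for angle, rel in zip(self.angles, self.relative_energies):
                writer.writerow([angle, rel])

    @classmethod
    def from_csv(cls, path: str) -> "TorsionScanResult":
        angles, energies = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                angles.append(float(row["angle_deg"]))
                energies.append(float(row["relative_energy_kcal_mol"]))
        return cls(angles=angles, energies=energies, geometries=[None] * len(angles))


# ---------------------------------------------------------------------------
# Backends


class MMScanBackend:
    """Drives scans on the class-1 MM model via restrained minimization."""

    id = "mm"

    def __init__(self, system: ParametrizedSystem):
        self.system = system

    def dihedral(self, geom, quartet) -> float:
        return dihedral_angle(geom, quartet)

    def set_dihedral(self, geom, quartet, angle_deg):
        return set_dihedral(self.system, geom, quartet, angle_deg)

    def optimize_at(self, geom, quartet, angle_deg):
        res = minimize(self.system, geom, frozen_dihedrals=[(quartet, angle_deg)])
        return res.coords, res.energy


# ---------------------------------------------------------------------------
# Wavefront scan


def run_scan(
    backend,
    mol: Molecule | None,
    quartet,
    seeds: list,
    grid: Grid = Grid(),
    e_tol: float = ENERGY_IMPROVEMENT_TOL,
) -> TorsionScanResult:
    """Wavefront-propagated constrained scan over a dihedral grid.

    ``seeds`` are backend geometry objects.  Each seed is snapped to its
    nearest grid point; every energy improvement larger than ``e_tol``
    propagates the improved structure (rotated by one spacing) to both grid
    neighbours.  The scan fails if more than 10% of the points never yield a
    successful optimization.
    """
    if not seeds:
        raise UsageError("at least one seed geometry is required")
    quartet = tuple(quartet) if not isinstance(quartet, TorsionQuartet) else quartet.atoms
    points = grid.points
    best_e = {p: np.inf for p in points}
    best_g = {p: None for p in points}
    failures: dict[float, str] = {}

    queue: deque = deque()
    for seed in seeds:
        target = grid.snap(backend.dihedral(seed, quartet))
        queue.append((target, seed))

    while queue:
        point, start = queue.popleft()
        try:
            geom, energy = backend.optimize_at(start, quartet, point)
        except Exception as exc:
            failures[point] = str(exc)
            continue
        if energy < best_e[point] - e_tol:
            best_e[point] = energy
            best_g[point] = geom
            for nbr in grid.neighbors(point):
                queue.append((nbr, backend.set_dihedral(geom, quartet, nbr)))

    failed = sorted(p for p in points if best_g[p] is None)
    if len(failed) > MAX_FAILED_FRACTION * len(points):
        raise BackendError(
            f"scan failed at {len(failed)}/{len(points)} grid points: "
            + "; ".join(f"{p}: {failures.get(p, 'unreached')}" for p in failed[:5])
        )
    ok = [p for p in points if best_g[p] is not None]
    return TorsionScanResult(
        angles=ok,
        energies=[best_e[p] for p in ok],
        geometries=[best_g[p] for p in ok],
        quartet=tuple(quartet),
        provenance={
            "backend": getattr(backend, "id", type(backend).__name__),
            "grid_spacing": grid.spacing,
            "n_seeds": len(seeds),
        },
        failed_points=failed,
    )


# ---------------------------------------------------------------------------
# Seed conformers


def seed_conformers(mol: Molecule, max_n: int = 4, seed: int = 2024,
                    rmsd_threshold: float = 0.5) -> list[np.ndarray]:
    """Up to ``max_n`` diverse conformers (pairwise heavy-atom RMSD >= 0.5 A).

    ETKDG embedding with a fixed random seed; candidates are greedily
    accepted in energy-agnostic embedding order if they differ from every
    accepted conformer by at least the RMSD threshold after superposition.
    Falls back to a single conformer (with a warning) if embedding is hard.
    """
    from rdkit.Chem import AllChem, rdMolAlign
    from rdkit import Chem

    if max_n < 1:
        raise UsageError("max_n must be >= 1")
    work = Molecule(Chem.Mol(mol.rdmol), name=mol.name)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = -1.0
    ids = list(AllChem.EmbedMultipleConfs(work.rdmol, numConfs=max(4 * max_n, 8), params=params))
    if not ids:
        warnings.warn("multi-conformer embedding failed; falling back to one conformer")
        work.embed(seed=seed)
        return [work.coords()]

    heavy = [a.GetIdx() for a in work.rdmol.GetAtoms() if a.GetAtomicNum() > 1]
    noh = Chem.RemoveHs(Chem.Mol(work.rdmol))
    accepted: list[int] = []
    for cid in ids:
        diverse = True
        for prev in accepted:
            rms = rdMolAlign.GetBestRMS(Chem.Mol(noh), Chem.Mol(noh), prbId=cid, refId=prev)
            if rms < rmsd_threshold:
                diverse = False
                break
        if diverse:
            accepted.append(cid)
        if len(accepted) >= max_n:
            break
    if not accepted:
        accepted = [ids[0]]
    return [
        np.asarray(work.rdmol.GetConformer(cid).GetPositions(), dtype=float)
        for cid in accepted
    ]
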