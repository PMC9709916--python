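"""Synthetic reference data with known ground truth.

Quantum torsion scans are expensive and non-deterministic across software
stacks, so the test and demonstration fixtures here build reference scans
from the package's own baseline MM model plus an injected Fourier torsion
term with known coefficients.  A fit run against such a scan has a unique
right answer — the injected coefficients — which turns parameter recovery,
L1 sparsity and weight-function behaviour into sharp, checkable statements.
The generated data emulates the shape of a quantum torsion drive (a relaxed
1D profile with coupled spectator rotors) but none of its electronic
structure: conjugation, hyperconjugation and charge transfer are absent,
so agreement here demonstrates correctness of the machinery, not chemical
accuracy of the surrogate.

Also provided is an analytic two-rotor toy surface whose exact per-grid
minimum is computable by enumeration — the oracle for wavefront
propagation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .chem import Molecule, perceive, torsion_type_groups
from .energy import ParametrizedSystem, TorsionTerm, build_system
from .fitting import FitTarget
from .scan import Grid, MMScanBackend, TorsionScanResult, run_scan, seed_conformers

RECOVERY_SMILES = "COOC"  # dimethyl peroxide: 10 atoms, one-quartet driven bond
RECOVERY_BOND = None  # resolved to the O-O bond at runtime

__all__ = [
    "AnalyticTorsionBackend",
    "TwoRotorToyBackend",
    "two_rotor_oracle",
    "injected_terms",
    "make_reference_scan",
    "make_recovery_case",
    "make_sparsity_case",
]


# ---------------------------------------------------------------------------
# Analytic backends


class AnalyticTorsionBackend:
    """Rigid 1D analytic torsion surface; no relaxation degrees of freedom.

    Geometry objects are 1-vectors [phi_deg].
    """

    id = "analytic-rigid"

    def __init__(self, energy_fn):
        self.energy_fn = energy_fn

    def dihedral(self, geom, quartet) -> float:
        return float(np.atleast_1d(geom)[0])

    def set_dihedral(self, geom, quartet, angle_deg):
        return np.array([float(angle_deg)])

    def optimize_at(self, geom, quartet, angle_deg):
        geom = np.array([float(angle_deg)])
        return geom, float(self.energy_fn(angle_deg))


class TwoRotorToyBackend:
    """Driven rotor coupled to a spectator rotor with two basins.

    E(phi, psi) = d*(1 + cos phi) + b*(1 - cos 2 psi) + c*cos psi*cos phi
    (kcal/mol, angles in degrees).  The spectator basin near psi = 0 loses
    local stability where cos phi > 4b/c and the basin near psi = 180 where
    cos phi < -4b/c, so a single-seed sequential scan gets trapped in the
    wrong basin over part of the grid while wavefront propagation carries
    the correct structure across.  Geometry objects are [phi_deg, psi_deg].
    """

    id = "two-rotor-toy"

    def __init__(self, b: float = 0.5, c: float = 3.0, d: float = 1.0):
        self.b, self.c, self.d = b, c, d

    def energy(self, phi_deg: float, psi_deg: float) -> float:
        phi, psi = np.deg2rad(phi_deg), np.deg2rad(psi_deg)
        return float(
            self.d * (1.0 + np.cos(phi))
            + self.b * (1.0 - np.cos(2.0 * psi))
            + self.c * np.cos(psi) * np.cos(phi)
        )

    def dihedral(self, geom, quartet) -> float:
        return float(geom[0])

    def set_dihedral(self, geom, quartet, angle_deg):
        return np.array([float(angle_deg), float(geom[1])])

    def optimize_at(self, geom, quartet, angle_deg):
        res = minimize_scalar(
            lambda psi: self.energy(angle_deg, psi),
            bracket=(float(geom[1]) - 1.0, float(geom[1]) + 1.0),
            method="brent",
            options={"xtol": 1e-12},
        )
        return np.array([float(angle_deg), float(res.x)]), float(res.fun)


def two_rotor_oracle(backend: TwoRotorToyBackend, grid: Grid) -> np.ndarray:
    """Exhaustive per-grid-point global minimum over both spectator basins."""
    energies = []
    for phi in grid.points:
        best = np.inf
        for psi0 in (0.0, 90.0, 180.0, 270.0):
            res = minimize_scalar(
                lambda psi: backend.energy(phi, psi),
                bracket=(psi0 - 1.0, psi0 + 1.0),
                method="brent",
                options={"xtol": 1e-12},
            )
            best = min(best, float(res.fun))
        energies.append(best)
    e = np.asarray(energies)
    return e - e.min()


# ---------------------------------------------------------------------------
# MM-based synthetic reference scans


def injected_terms(seed: int, n_terms: int = 2, k_range=(0.5, 3.0)) -> list[TorsionTerm]:
    """Deterministic random Fourier terms: distinct n in 1..4, |k| in k_range."""
    rng = np.random.default_rng(seed)
    ns = rng.choice([1, 2, 3, 4], size=n_terms, replace=False)
    terms = []
    for n in sorted(int(n) for n in ns):
        k = float(rng.uniform(*k_range)) * (1.0 if rng.random() < 0.5 else -1.0)
        terms.append(TorsionTerm(k=round(k, 3), n=n, phase=0.0))
    return terms


def _driven_setup(smiles: str = RECOVERY_SMILES):
    mol = perceive(smiles)
    # drive the unique heavy-heavy bond whose two sides carry one substituent
    # each (dimethyl peroxide: the O-O bond, a single one-quartet group)
    from .chem import find_rotatable_bonds

    for bond in find_rotatable_bonds(mol):
        groups = torsion_type_groups(mol, bond)
        if len(groups) == 1 and len(groups[0].quartets) == 1:
            return mol, bond, groups
    raise RuntimeError(f"no one-quartet driven bond in {smiles}")


def make_reference_scan(
    system: ParametrizedSystem,
    mol: Molecule,
    quartet,
    grid: Grid = Grid(),
    seed: int = 2024,
    n_seeds: int = 1,
) -> TorsionScanResult:
    """Wavefront MM scan of ``system`` used as synthetic reference data."""
    seeds = seed_conformers(mol, max_n=n_seeds, seed=seed)
    return run_scan(MMScanBackend(system), mol, quartet, seeds, grid)


def make_recovery_case(
    seed: int,
    grid: Grid = Grid(),
    smiles: str = RECOVERY_SMILES,
) -> tuple[FitTarget, dict[int, float]]:
    """One seeded parameter-recovery target with known ground truth.

    Injects 1-2 random Fourier terms (|k| in 0.5-3 kcal/mol, n in 1..4) on
    the driven bond's torsion group of the baseline MM model, scans the
    doctored model to produce the reference, then returns a FitTarget whose
    system starts from the undoctored baseline (all driven k = 0).  Returns
    (target, true force constants by periodicity; absent n are 0).
    """
    mol, bond, groups = _driven_setup(smiles)
    group = groups[0]
    truth_terms = injected_terms(seed)
    truth = {n: 0.0 for n in (1, 2, 3, 4)}
    for t in truth_terms:
        truth[t.n] = t.k

    doctored = build_system(
        mol, torsion_terms={q: truth_terms for q in group.quartets}
    )
    reference = make_reference_scan(doctored, mol, group.quartets[0].atoms, grid, seed=seed)

    baseline = build_system(mol)
    target = FitTarget(
        system=baseline,
        reference=reference,
        groups=[group],
        parameter_keys=[f"recovery-{bond[0]}-{bond[1]}"],
        initial_terms={},
        name=f"recovery-seed{seed}",
    )
    return target, truth


def make_sparsity_case(
    k3: float = 2.0, grid: Grid = Grid(), seed: int = 2024, smiles: str = RECOVERY_SMILES
) -> tuple[FitTarget, float]:
    """A pure n = 3 synthetic surface; every other harmonic is redundant."""
    mol, bond, groups = _driven_setup(smiles)
    group = groups[0]
    terms = [TorsionTerm(k=k3, n=3, phase=0.0)]
    doctored = build_system(mol, torsion_terms={q: terms for q in group.quartets})
    reference = make_reference_scan(doctored, mol, group.quartets[0].atoms, grid, seed=seed)
    target = FitTarget(
        system=build_system(mol),
        reference=reference,
        groups=[group],
        parameter_keys=["sparsity"],
        initial_terms={},
        name="sparsity",
    )
    return target, k3
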