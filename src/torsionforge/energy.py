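"""Minimal class-1 molecular-mechanics model and restrained minimization.

The model is the usual additive form: harmonic bonds and angles, a truncated
Fourier torsion series E = sum_i k_i (1 + cos(n_i phi - phi0_i)), 12-6
Lennard-Jones with Lorentz-Berthelot combination, and point-charge Coulomb
interactions.  1-2 and 1-3 pairs are excluded; 1-4 pairs are scaled by fixed
factors (0.5 LJ, 0.8333 electrostatics).  Energies are in kcal/mol,
coordinates in Angstrom, dihedrals in degrees with the right-handed IUPAC
sign convention in (-180, 180].

Dihedral freezing during minimization is done with a stiff harmonic dihedral
restraint (5000 kcal/mol/rad^2) followed by an exact rigid-rotation snap of
the far-side subtree onto the target angle, so the returned geometry honours
each frozen dihedral to 1e-3 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .chem import Molecule, TorsionQuartet
from .errors import TorsionForgeError

COULOMB_KCAL = 332.0637  # (e^2/Angstrom) -> kcal/mol
DIHEDRAL_RESTRAINT_K = 5000.0  # kcal/mol/rad^2, freezing stiffness
FROZEN_DIHEDRAL_TOL = 1e-3  # degrees, post-minimization contract

__all__ = [
    "TorsionTerm",
    "ParametrizedSystem",
    "RestraintSpec",
    "MinimizationResult",
    "torsion_energy",
    "build_system",
    "minimize",
    "set_dihedral",
]


class NumericalGuardError(TorsionForgeError):
    """Raised when coordinates are numerically pathological (atom overlap)."""


@dataclass(frozen=True)
class TorsionTerm:
    """One Fourier term k*(1 + cos(n*phi - phase)).

    k in kcal/mol, integer periodicity n >= 1, phase in degrees (0 or 180
    for bespoke terms by default).
    """

    k: float
    n: int
    phase: float = 0.0


@dataclass
class RestraintSpec:
    """Harmonic positional restraint E = (k/2)*sum |r - r_ref|^2 over atoms."""

    atoms: list[int]
    reference: np.ndarray  # (n_atoms, 3) Angstrom; only restrained rows read
    force_constant: float = 1.0  # kcal/mol/A^2

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("restraint force constant must be >= 0")


def torsion_energy(terms: list[TorsionTerm], phi_deg: float) -> float:
    """Evaluate the Fourier torsion series at a dihedral angle in degrees."""
    phi = np.deg2rad(phi_deg)
    return float(
        sum(t.k * (1.0 + np.cos(t.n * phi - np.deg2rad(t.phase))) for t in terms)
    )


class ParametrizedSystem:
    """Bonded + nonbonded parameters for one molecule.

    Parameters are plain Python lists until ``compile()`` packs them into
    numpy index arrays; any mutation invalidates the compiled state.  Torsion
    force constants are expected to change frequently during fitting, so the
    torsion block is recompiled cheaply on its own.
    """

    def __init__(self, n_atoms: int):
        self.n_atoms = n_atoms
        self.bonds: list[tuple[int, int, float, float]] = []  # i, j, r0 A, kb kcal/mol/A^2
        self.angles: list[tuple[int, int, int, float, float]] = []  # i,j,k, th0 deg, ka kcal/mol/rad^2
        self.torsions: dict[TorsionQuartet, list[TorsionTerm]] = {}
        self.sigma = np.zeros(n_atoms)  # A
        self.epsilon = np.zeros(n_atoms)  # kcal/mol
        self.charges = np.zeros(n_atoms)  # e
        self.scale14_lj = 0.5
        self.scale14_coul = 0.8333
        self._pairs = None
        self._tors_arrays = None

    # -- construction helpers ------------------------------------------------

    def add_bond(self, i, j, r0, kb):
        self.bonds.append((i, j, float(r0), float(kb)))
        self._pairs = None

    def add_angle(self, i, j, k, theta0_deg, ka):
        self.angles.append((i, j, k, float(theta0_deg), float(ka)))
        self._pairs = None

    def set_torsion_terms(self, quartet: TorsionQuartet, terms: list[TorsionTerm]):
        self.torsions[quartet] = list(terms)
        self._tors_arrays = None

    @property
    def adjacency(self) -> list[list[int]]:
        adj = [[] for _ in range(self.n_atoms)]
        for i, j, *_ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    # -- compiled views ------------------------------------------------------

    def _compile_pairs(self):
        """Nonbonded pair list with per-pair LJ/Coulomb scale factors."""
        n = self.n_atoms
        adj = self.adjacency
        excluded, one_four = set(), set()
        for a in range(n):
            for b in adj[a]:
                excluded.add(frozenset((a, b)))
                for c in adj[b]:
                    if c != a:
                        excluded.add(frozenset((a, c)))
                        for d in adj[c]:
                            if d not in (a, b) and frozenset((a, d)) not in excluded:
                                one_four.add(frozenset((a, d)))
        one_four -= excluded
        ii, jj, s_lj, s_q = [], [], [], []
        for a in range(n):
            for b in range(a + 1, n):
                key = frozenset((a, b))
                if key in excluded:
                    continue
                ii.append(a)
                jj.append(b)
                if key in one_four:
                    s_lj.append(self.scale14_lj)
                    s_q.append(self.scale14_coul)
                else:
                    s_lj.append(1.0)
                    s_q.append(1.0)
        ii, jj = np.array(ii, dtype=int), np.array(jj, dtype=int)
        sig = 0.5 * (self.sigma[ii] + self.sigma[jj])
        eps = np.sqrt(self.epsilon[ii] * self.epsilon[jj]) * np.array(s_lj)
        qq = COULOMB_KCAL * self.charges[ii] * self.charges[jj] * np.array(s_q)
        self._pairs = (ii, jj, sig, eps, qq)
        # packed bond/angle arrays for vectorized evaluation
        barr = np.array([[i, j] for i, j, *_ in self.bonds], dtype=int).reshape(-1, 2)
        bpar = np.array([[r0, kb] for *_, r0, kb in self.bonds]).reshape(-1, 2)
        aarr = np.array([[i, j, k] for i, j, k, *_ in self.angles], dtype=int).reshape(-1, 3)
        apar = np.array(
            [[np.deg2rad(t0), ka] for *_, t0, ka in self.angles]
        ).reshape(-1, 2)
        self._bond_arrays = (barr, bpar)
        self._angle_arrays = (aarr, apar)

    def _compile_torsions(self):
        quart, ks, ns, phases = [], [], [], []
        for q, terms in sorted(self.torsions.items(), key=lambda kv: kv[0].atoms):
            for t in terms:
                quart.append(q.atoms)
                ks.append(t.k)
                ns.append(t.n)
                phases.append(np.deg2rad(t.phase))
        self._tors_arrays = (
            np.array(quart, dtype=int).reshape(-1, 4),
            np.array(ks),
            np.array(ns, dtype=float),
            np.array(phases),
        )

    # -- energy and gradient -------------------------------------------------

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_and_gradient(coords)[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_and_gradient(coords)[1]

    def energy_and_gradient(self, coords: np.ndarray):
        xyz = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        grad = np.zeros_like(xyz)
        energy = 0.0

        if self._pairs is None:
            self._compile_pairs()
        if self._tors_arrays is None:
            self._compile_torsions()

        # bonds: E = (kb/2) (r - r0)^2
        barr, bpar = self._bond_arrays
        if len(barr):
            d = xyz[barr[:, 0]] - xyz[barr[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dr = r - bpar[:, 0]
            energy += float(np.sum(0.5 * bpar[:, 1] * dr**2))
            g = (bpar[:, 1] * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(grad, barr[:, 0], g)
            np.add.at(grad, barr[:, 1], -g)

        # angles: E = (ka/2) (theta - theta0)^2
        aarr, apar = self._angle_arrays
        if len(aarr):
            u = xyz[aarr[:, 0]] - xyz[aarr[:, 1]]
            v = xyz[aarr[:, 2]] - xyz[aarr[:, 1]]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
            dtheta = theta - apar[:, 0]
            ka = apar[:, 1]
            energy += float(np.sum(0.5 * ka * dtheta**2))
            di = (cos_t[:, None] * u / nu[:, None] - v / nv[:, None]) / (nu * sin_t)[:, None]
            dk = (cos_t[:, None] * v / nv[:, None] - u / nu[:, None]) / (nv * sin_t)[:, None]
            np.add.at(grad, aarr[:, 0], ka[:, None] * dtheta[:, None] * di)
            np.add.at(grad, aarr[:, 2], ka[:, None] * dtheta[:, None] * dk)
            np.add.at(grad, aarr[:, 1], -ka[:, None] * dtheta[:, None] * (di + dk))

        # torsions (vectorized over all Fourier terms)
        quart, ks, ns, phases = self._tors_arrays
        if len(ks):
            phi, dphi = _dihedrals_and_grads(xyz, quart)
            arg = ns * phi - phases
            energy += float(np.sum(ks * (1.0 + np.cos(arg))))
            dE_dphi = -ks * ns * np.sin(arg)  # per term, kcal/mol/rad
            for col, atom_idx in enumerate(quart.T):
                np.add.at(grad, atom_idx, dE_dphi[:, None] * dphi[:, col, :])

        # nonbonded
        ii, jj, sig, eps, qq = self._pairs
        if len(ii):
            d = xyz[ii] - xyz[jj]
            r = np.linalg.norm(d, axis=1)
            if np.any(r < 0.1):
                raise NumericalGuardError(
                    f"atom overlap: min pair distance {r.min():.3g} A < 0.1 A"
                )
            sr6 = (sig / r) ** 6
            energy += float(np.sum(4.0 * eps * (sr6**2 - sr6)) + np.sum(qq / r))
            dEdr = (-24.0 * eps * (2.0 * sr6**2 - sr6) - qq / r) / r
            gpair = (dEdr / r)[:, None] * d
            np.add.at(grad, ii, gpair)
            np.add.at(grad, jj, -gpair)

        return energy, grad


def _dihedrals_and_grads(xyz: np.ndarray, quartets: np.ndarray):
    """Signed dihedrals (rad) and analytic gradients for an (m,4) index array.

    Returns phi (m,) and dphi/dx (m, 4, 3) ordered as the quartet columns.
    """
    ri, rj, rk, rl = (xyz[quartets[:, c]] for c in range(4))
    b1, b2, b3 = rj - ri, rk - rj, rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    phi = np.arctan2(
        np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.maximum(b2n, 1e-12),
        np.einsum("ij,ij->i", n1, n2),
    )
    n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
    n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
    t = -(b2n / n1sq)[:, None] * n1  # dphi/dri
    u = (b2n / n2sq)[:, None] * n2  # dphi/drl
    c12 = (np.einsum("ij,ij->i", b1, b2) / b2n**2)[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / b2n**2)[:, None]
    dj = -(1.0 + c12) * t + c32 * u
    dk = c12 * t - (1.0 + c32) * u
    return phi, np.stack([t, dj, dk, u], axis=1)


def dihedral_angle(xyz: np.ndarray, quartet) -> float:
    """Signed dihedral in degrees for one atom quartet."""
    idx = np.array([tuple(quartet)], dtype=int)
    phi, _ = _dihedrals_and_grads(np.asarray(xyz, dtype=float), idx)
    deg = float(np.rad2deg(phi[0]))
    return deg if deg > -180.0 else deg + 360.0


# ---------------------------------------------------------------------------
# System construction from a molecule


_COVALENT_RADII = {1: 0.32, 5: 0.85, 6: 0.75, 7: 0.71, 8: 0.63, 9: 0.64,
                   14: 1.16, 15: 1.11, 16: 1.03, 17: 0.99, 35: 1.14, 53: 1.33}
_BOND_LENGTH_SCALE = {1.0: 1.0, 1.5: 0.93, 2.0: 0.87, 3.0: 0.81}
_BOND_K = {1.0: 350.0, 1.5: 450.0, 2.0: 550.0, 3.0: 650.0}  # kcal/mol/A^2
_LJ_PARAMS = {  # sigma A, epsilon kcal/mol (UFF-like magnitudes)
    1: (2.57, 0.022), 6: (3.43, 0.086), 7: (3.26, 0.069), 8: (3.12, 0.060),
    9: (3.00, 0.050), 15: (3.70, 0.200), 16: (3.59, 0.250), 17: (3.52, 0.227),
    35: (3.73, 0.251), 53: (4.01, 0.339),
}
_ANGLE_K = 70.0  # kcal/mol/rad^2


def gasteiger_charges(mol: Molecule) -> np.ndarray:
    """Electronegativity-equalization partial charges (Gasteiger)."""
    from rdkit.Chem import AllChem

    rd = mol.rdmol
    AllChem.ComputeGasteigerCharges(rd)
    q = np.array([float(a.GetProp("_GasteigerCharge")) for a in rd.GetAtoms()])
    return np.nan_to_num(q)


def build_system(
    mol: Molecule,
    torsion_terms: dict[TorsionQuartet, list[TorsionTerm]] | None = None,
    charge_provider=gasteiger_charges,
) -> ParametrizedSystem:
    """Parametrize a molecule with generic class-1 valence and LJ parameters.

    Equilibrium bond lengths come from covalent-radius sums scaled by bond
    order; angle references follow the centre atom's hybridization.  Torsion
    terms are supplied by the caller (typically via force-field assignment);
    quartets without terms contribute zero torsional energy.
    """
    from rdkit import Chem

    rd = mol.rdmol
    system = ParametrizedSystem(mol.n_atoms)
    for bond in rd.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = bond.GetBondTypeAsDouble()
        order = order if order in _BOND_LENGTH_SCALE else 1.0
        r0 = (
            _COVALENT_RADII.get(rd.GetAtomWithIdx(i).GetAtomicNum(), 1.1)
            + _COVALENT_RADII.get(rd.GetAtomWithIdx(j).GetAtomicNum(), 1.1)
        ) * _BOND_LENGTH_SCALE[order]
        system.add_bond(i, j, r0, _BOND_K[order])

    for atom in rd.GetAtoms():
        j = atom.GetIdx()
        nbrs = mol.neighbors(j)
        if len(nbrs) < 2:
            continue
        theta0 = _reference_angle(atom)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                system.add_angle(nbrs[a], j, nbrs[b], theta0, _ANGLE_K)

    for atom in rd.GetAtoms():
        sig, eps = _LJ_PARAMS.get(atom.GetAtomicNum(), (3.4, 0.1))
        system.sigma[atom.GetIdx()] = sig
        system.epsilon[atom.GetIdx()] = eps
    system.charges = charge_provider(mol) if charge_provider else np.zeros(mol.n_atoms)

    for quartet, terms in (torsion_terms or {}).items():
        system.set_torsion_terms(quartet, terms)
    return system


def _reference_angle(atom) -> float:
    from rdkit import Chem

    hyb = atom.GetHybridization()
    if atom.GetIsAromatic() or hyb == Chem.HybridizationType.SP2:
        return 120.0
    if hyb == Chem.HybridizationType.SP:
        return 179.0  # avoid the exactly-linear singularity
    return 109.47


# ---------------------------------------------------------------------------
# Dihedral manipulation and minimization


def _far_side_atoms(adjacency, j: int, k: int) -> list[int]:
    """Atoms reachable from k without crossing the (j, k) bond (k excluded)."""
    seen = {j, k}
    stack = [k]
    out = []
    while stack:
        for nxt in adjacency[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                out.append(nxt)
                stack.append(nxt)
    return out


def set_dihedral(system: ParametrizedSystem, coords: np.ndarray, quartet, target_deg: float) -> np.ndarray:
    """Rigidly rotate the far side of the central bond to the exact target."""
    xyz = np.array(coords, dtype=float)
    i, j, k, l = tuple(quartet)
    current = dihedral_angle(xyz, (i, j, k, l))
    moving = _far_side_atoms(system.adjacency, j, k) + [  # k itself stays on axis
    ]
    delta = np.deg2rad(_wrap_deg(target_deg - current))
    axis = xyz[k] - xyz[j]
    axis = axis / np.linalg.norm(axis)
    rotated = _rotate_about_axis(xyz, moving, xyz[k], axis, delta)
    if abs(_wrap_deg(dihedral_angle(rotated, (i, j, k, l)) - target_deg)) > abs(
        _wrap_deg(dihedral_angle(_rotate_about_axis(xyz, moving, xyz[k], axis, -delta), (i, j, k, l)) - target_deg)
    ):
        rotated = _rotate_about_axis(xyz, moving, xyz[k], axis, -delta)
    return rotated


def _rotate_about_axis(xyz, atoms, origin, axis, angle):
    out = np.array(xyz)
    if not atoms:
        return out
    c, s = np.cos(angle), np.sin(angle)
    rel = out[atoms] - origin
    out[atoms] = (
        rel * c
        + np.cross(axis, rel) * s
        + np.outer(rel @ axis, axis) * (1.0 - c)
        + origin
    )
    return out


def _wrap_deg(x: float) -> float:
    return (x + 180.0) % 360.0 - 180.0


@dataclass
class MinimizationResult:
    coords: np.ndarray
    energy: float  # system energy, restraints excluded
    converged: bool
    message: str = ""


def minimize(
    system: ParametrizedSystem,
    coords: np.ndarray,
    frozen_dihedrals: list[tuple] | None = None,
    restraints: RestraintSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> MinimizationResult:
    """Quasi-Newton MM relaxation with optional frozen dihedrals/restraints.

    ``frozen_dihedrals`` is a list of (quartet, target degrees); each is held
    by a stiff dihedral restraint during optimization and snapped exactly
    afterwards.  The reported energy excludes all restraint contributions.
    The result never has higher system energy than the (snapped) input.
    """
    frozen = [(TorsionQuartet(*q) if not isinstance(q, TorsionQuartet) else q, t)
              for q, t in (frozen_dihedrals or [])]
    xyz0 = np.array(coords, dtype=float).reshape(system.n_atoms, 3)
    for quartet, target in frozen:
        xyz0 = set_dihedral(system, xyz0, _oriented(quartet), target)
    e_input = system.energy(xyz0)

    frozen_idx = np.array([_oriented(q) for q, _ in frozen], dtype=int).reshape(-1, 4)
    frozen_tgt = np.deg2rad(np.array([t for _, t in frozen]))
    r_atoms = np.array(restraints.atoms, dtype=int) if restraints else np.array([], dtype=int)
    r_ref = (np.asarray(restraints.reference, dtype=float).reshape(system.n_atoms, 3)[r_atoms]
             if restraints and len(r_atoms) else None)

    def fun(x):
        xyz = x.reshape(system.n_atoms, 3)
        energy, grad = system.energy_and_gradient(xyz)
        if len(frozen):
            phi, dphi = _dihedrals_and_grads(xyz, frozen_idx)
            dphi_wrapped = np.arctan2(np.sin(phi - frozen_tgt), np.cos(phi - frozen_tgt))
            energy += 0.5 * DIHEDRAL_RESTRAINT_K * float(np.sum(dphi_wrapped**2))
            coef = DIHEDRAL_RESTRAINT_K * dphi_wrapped
            for col, atom_idx in enumerate(frozen_idx.T):
                np.add.at(grad, atom_idx, coef[:, None] * dphi[:, col, :])
        if r_ref is not None:
            dr = xyz[r_atoms] - r_ref
            energy += 0.5 * restraints.force_constant * float(np.sum(dr**2))
            grad[r_atoms] += restraints.force_constant * dr
        return energy, grad.ravel()

    res = _scipy_minimize(
        fun, xyz0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-11},
    )
    xyz = res.x.reshape(system.n_atoms, 3)
    for quartet, target in frozen:
        xyz = set_dihedral(system, xyz, _oriented(quartet), target)
        achieved = dihedral_angle(xyz, _oriented(quartet))
        if abs(_wrap_deg(achieved - target)) > FROZEN_DIHEDRAL_TOL:  # pragma: no cover
            warnings.warn(f"frozen dihedral off target by {achieved - target:.2g} deg")
    e_final = system.energy(xyz)
    if e_final > e_input:  # never uphill relative to the snapped input
        xyz, e_final = xyz0, e_input
    # a stalled line search with a tiny residual gradient still counts
    converged = bool(res.success) or float(np.abs(fun(res.x)[1]).max()) < 1e-3
    if not converged:
        warnings.warn(f"minimization unconverged: {res.message}")
    return MinimizationResult(coords=xyz, energy=e_final, converged=converged,
                              message=str(res.message))


def _oriented(quartet: TorsionQuartet) -> tuple[int, int, int, int]:
    return quartet.atoms
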