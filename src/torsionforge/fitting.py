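"""Weighted, regularized least-squares fitting of bespoke torsion constants.

The torsional profile of each driven bond is represented by the truncated
Fourier series E = sum_i k_i (1 + cos(n_i phi - phi0_i)).  Phases,
periodicities and 1-4 scaling factors stay fixed; only the force constants
k are optimized.  Before fitting, every torsion type's periodicities are
fully expanded to n = 1..4, with zero initial k for the newly introduced
terms, so no assumption is made about which harmonics the profile needs.

The objective is a weighted sum over grid points of the squared deviation
between reference and MM relative energies (both normalized to their own
global minimum), divided by a scale factor S_f = 1 kcal/mol.  The weight is
1 up to 1 kcal/mol, attenuates smoothly to a hard cutoff at 10 kcal/mol,
and is zero beyond it, concentrating the fit on the chemically relevant
low-energy region.  An L1 penalty |delta k| / sigma_p (prior width 6.0)
shrinks redundant force constants toward their initial values — with many
near-collinear torsion bases through one bond, this is what keeps the
expansion from over-fitting; L2 is available as an alternative.

At every outer iteration the MM geometries are re-relaxed under the current
parameters: the four dihedral atoms are frozen at the grid angle and all
other atoms relax under a weak positional restraint (1 kcal/mol/A^2) toward
the reference geometry.  All targets are fitted simultaneously; parameters
keyed by the same SMIRKS are shared across targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .chem import TorsionTypeGroup
from .energy import (
    ParametrizedSystem,
    RestraintSpec,
    TorsionTerm,
    dihedral_angle,
    minimize,
)
from .errors import ConsistencyError, TorsionForgeError, UsageError
from .scan import TorsionScanResult

__all__ = [
    "ObjectiveConfig",
    "FitTarget",
    "FitResult",
    "expand_periodicities",
    "weight",
    "mm_profile",
    "objective",
    "fit",
    "evaluate_metrics",
]


@dataclass
class ObjectiveConfig:
    """Tunable knobs of the fitting objective.

    Defaults are the production operating point: S_f 1 kcal/mol, weight
    cutoffs 1/10 kcal/mol, L1 prior width 6.0, positional restraint
    1 kcal/mol/A^2.
    """

    scale_factor: float = 1.0  # S_f, kcal/mol
    weight_cutoff_low: float = 1.0  # E1, kcal/mol
    weight_cutoff_high: float = 10.0  # E2, kcal/mol
    prior_width: float = 6.0  # sigma_p, k units
    regularization: str = "L1"  # "L1" | "L2"
    restraint_k: float | None = 1.0  # kcal/mol/A^2; None disables restraints
    rmsd_in_objective: bool = False
    rmsd_weight: float = 1.0  # multiplies squared per-point RMSD (A^2)
    attenuation: str = "inverse_quadratic"  # or "linear"
    # plain weighted sum by default; per-target Sum(w) normalization optional
    normalize_by_weight_sum: bool = False
    k_bound: float = 20.0  # |k| guard, kcal/mol

    def __post_init__(self):
        if not (0 < self.weight_cutoff_low < self.weight_cutoff_high):
            raise UsageError("weight cutoffs must satisfy 0 < E1 < E2")
        if self.prior_width <= 0 or self.scale_factor <= 0:
            raise UsageError("prior width and scale factor must be positive")
        if self.regularization not in ("L1", "L2"):
            raise UsageError(f"unknown regularization {self.regularization!r}")


def weight(e_rel: float, config: ObjectiveConfig = ObjectiveConfig()) -> float:
    """Grid-point weight as a function of reference relative energy.

    Constant 1 below E1, zero at/above E2, smooth attenuation in between
    (w = (1 + (E - E1)^2)^(-1/2) by default; a linear ramp alternatively),
    continuous at E1.
    """
    if e_rel < 0:
        raise UsageError(f"relative energy must be >= 0, got {e_rel}")
    e1, e2 = config.weight_cutoff_low, config.weight_cutoff_high
    if e_rel <= e1:
        return 1.0
    if e_rel >= e2:
        return 0.0
    if config.attenuation == "linear":
        return float((e2 - e_rel) / (e2 - e1))
    return float(1.0 / np.sqrt(1.0 + (e_rel - e1) ** 2))


def expand_periodicities(initial: list[TorsionTerm]) -> list[TorsionTerm]:
    """Expand a torsion term list to exactly n = 1..4.

    Pre-existing (k, n, phase) triples are preserved; new periodicities enter
    with k = 0 and phase 0.
    """
    by_n: dict[int, TorsionTerm] = {}
    for term in initial:
        if term.n in by_n:
            raise ConsistencyError(f"duplicate periodicity n={term.n} in initial terms")
        by_n[term.n] = term
    return [by_n.get(n, TorsionTerm(k=0.0, n=n, phase=0.0)) for n in (1, 2, 3, 4)]


# ---------------------------------------------------------------------------
# Fit targets


@dataclass
class FitTarget:
    """One fragment's reference scan plus the torsion groups fitted to it.

    ``parameter_keys[g]`` names the shared parameter slot of group ``g``
    (SMIRKS text in the full workflow); targets using the same key are
    coupled through one set of force constants.
    """

    system: ParametrizedSystem
    reference: TorsionScanResult
    groups: list[TorsionTypeGroup]
    parameter_keys: list[str]
    initial_terms: dict[str, list[TorsionTerm]] = field(default_factory=dict)
    name: str = "target"

    def __post_init__(self):
        if len(self.groups) != len(self.parameter_keys):
            raise ConsistencyError("one parameter key per group required")
        if self.reference.quartet is None:
            raise ConsistencyError("reference scan lacks a driven quartet")
        for key in self.parameter_keys:
            expanded = expand_periodicities(self.initial_terms.get(key, []))
            self.initial_terms[key] = expanded


@dataclass
class _PreparedTarget:
    target: FitTarget
    weights: np.ndarray  # per grid point, from reference energies
    ref_rel: np.ndarray
    coords: list  # current relaxed geometry per point
    basis: np.ndarray | None = None  # (n_points, n_params) d E_raw / d k
    e_other: np.ndarray | None = None  # raw MM energy minus own torsion-k part


@dataclass
class FitResult:
    terms: dict[str, list[TorsionTerm]]
    delta: dict[str, np.ndarray]  # per-key k change from initial
    objective_trace: list[float]
    rmse: dict[str, float]  # weighted RMSE per target name (w > 0 points)
    rmse_full: dict[str, float]  # full-grid RMSE per target name
    converged: bool
    n_outer: int = 0


# ---------------------------------------------------------------------------
# MM profile


def mm_profile(
    system: ParametrizedSystem,
    reference: TorsionScanResult,
    config: ObjectiveConfig = ObjectiveConfig(),
    warm_coords: list | None = None,
):
    """Relax the molecule at every reference grid point under the current FF.

    The driven dihedral is frozen at the grid angle; all remaining atoms
    relax, pulled toward the reference geometry by a weak positional
    restraint (per ``config.restraint_k``; None = unrestrained).  Returns
    (list of relaxed coords, raw MM energies, relative MM energies).
    """
    quartet = reference.quartet
    coords_out, raw = [], []
    for idx, angle in enumerate(reference.angles):
        ref_geom = reference.geometries[idx]
        start = (
            warm_coords[idx]
            if warm_coords is not None and warm_coords[idx] is not None
            else ref_geom
        )
        if start is None:
            raise UsageError("reference scan has no geometries to relax from")
        restraint = None
        if config.restraint_k is not None and ref_geom is not None:
            restraint = RestraintSpec(
                atoms=list(range(system.n_atoms)),
                reference=np.asarray(ref_geom, dtype=float),
                force_constant=config.restraint_k,
            )
        res = minimize(
            system,
            np.asarray(start, dtype=float),
            frozen_dihedrals=[(quartet, angle)],
            restraints=restraint,
        )
        coords_out.append(res.coords)
        raw.append(res.energy)
    raw = np.asarray(raw)
    return coords_out, raw, raw - raw.min()


# ---------------------------------------------------------------------------
# Objective


def _torsion_basis(target: FitTarget, coords: list) -> np.ndarray:
    """Per-point, per-parameter basis: dE_raw/dk for each (key, n) slot.

    Entry [i, 4*g + (n-1)] = sum over the group's quartets of
    (1 + cos(n*phi_q(x_i) - phase)).
    """
    n_points = len(coords)
    n_params = 4 * len(target.groups)
    basis = np.zeros((n_points, n_params))
    for g, (group, key) in enumerate(zip(target.groups, target.parameter_keys)):
        phases = np.array([np.deg2rad(t.phase) for t in target.initial_terms[key]])
        for i, xyz in enumerate(coords):
            for quartet in group.quartets:
                phi = np.deg2rad(dihedral_angle(xyz, quartet.atoms))
                for slot, n in enumerate((1, 2, 3, 4)):
                    basis[i, 4 * g + slot] += 1.0 + np.cos(n * phi - phases[slot])
    return basis


def _param_layout(targets: list[FitTarget]):
    keys = sorted({k for t in targets for k in t.parameter_keys})
    offset = {k: 4 * i for i, k in enumerate(keys)}
    return keys, offset


def objective(
    phi: np.ndarray,
    prepared: list[_PreparedTarget],
    config: ObjectiveConfig,
    phi0: np.ndarray,
    offsets: dict[str, int],
) -> float:
    """Regularized objective at parameter vector ``phi`` (fixed geometries)."""
    total = 0.0
    for prep in prepared:
        wsum = prep.weights.sum()
        if wsum <= 0:
            continue
        cols = _target_columns(prep.target, offsets)
        e_raw = prep.e_other + prep.basis @ phi[cols]
        e_mm = e_raw - e_raw.min()
        resid = (prep.ref_rel - e_mm) / config.scale_factor
        data = float(np.sum(prep.weights * resid**2))
        if config.rmsd_in_objective:
            data += config.rmsd_weight * float(
                np.sum(prep.weights * prep.rmsd_sq)
            )
        total += data / wsum if config.normalize_by_weight_sum else data
    dphi = phi - phi0
    if config.regularization == "L1":
        total += float(np.sum(np.abs(dphi))) / config.prior_width
    else:
        total += float(np.sum((dphi / config.prior_width) ** 2))
    return total


def _target_columns(target: FitTarget, offsets: dict[str, int]) -> np.ndarray:
    cols = []
    for key in target.parameter_keys:
        cols.extend(range(offsets[key], offsets[key] + 4))
    return np.array(cols, dtype=int)


def _solve_inner(
    phi: np.ndarray,
    prepared: list[_PreparedTarget],
    config: ObjectiveConfig,
    phi0: np.ndarray,
    offsets: dict[str, int],
) -> np.ndarray:
    """Best-of-portfolio solve of the regularized problem at fixed geometries.

    The objective is piecewise smooth in the force constants (the grid point
    holding the MM global minimum can change), and the L1 penalty adds kinks,
    so no single local method is reliable: a direction-set search can stall
    on a kink, and the exact coordinate-descent solve is only exact for one
    pinned minimum index.  Three deterministic candidates are therefore
    computed — a Powell run from the current iterate, a Powell run from the
    initial values, and the iterated-pinning coordinate-descent solution —
    and the one with the lowest honest objective wins.
    """
    candidates = [
        _solve_pinned_cd(phi, prepared, config, phi0, offsets),
    ]
    for start in (phi, phi0):
        # unbounded Powell: scipy's bounded variant can terminate on a point
        # worse than its start; the |k| guard is applied afterwards instead
        res = _scipy_minimize(
            lambda p: objective(p, prepared, config, phi0, offsets),
            start,
            method="Powell",
            options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": 10000},
        )
        candidates.append(np.clip(res.x, -config.k_bound, config.k_bound))
    scored = [
        (objective(c, prepared, config, phi0, offsets), i, c)
        for i, c in enumerate(candidates)
    ]
    return min(scored)[2]


def _solve_pinned_cd(
    phi: np.ndarray,
    prepared: list[_PreparedTarget],
    config: ObjectiveConfig,
    phi0: np.ndarray,
    offsets: dict[str, int],
) -> np.ndarray:
    """Iterated coordinate-descent lasso with the MM-minimum index pinned.

    For a pinned per-target minimum index the data term is quadratic, so the
    L1 problem is solved exactly by soft-thresholding sweeps (ridge update
    for L2); the pin is then refreshed from the solution until it repeats,
    keeping the best honestly-scored iterate.
    """
    phi = phi.copy()
    best = (np.inf, phi.copy())
    seen_indices: set[tuple] = set()
    for _ in range(25):
        # pin each target's MM-minimum reference index at the current phi
        i0s = []
        rows_a, rows_y, rows_w = [], [], []
        for prep in prepared:
            cols = _target_columns(prep.target, offsets)
            e_raw = prep.e_other + prep.basis @ phi[cols]
            i0 = int(np.argmin(e_raw))
            i0s.append(i0)
            a_full = np.zeros((len(prep.ref_rel), len(phi)))
            a_full[:, cols] = prep.basis - prep.basis[i0]
            y = prep.ref_rel - (prep.e_other - prep.e_other[i0])
            w = prep.weights / config.scale_factor**2
            if config.normalize_by_weight_sum and prep.weights.sum() > 0:
                w = w / prep.weights.sum()
            rows_a.append(a_full)
            rows_y.append(y)
            rows_w.append(w)
        a = np.vstack(rows_a)
        y = np.concatenate(rows_y)
        w = np.concatenate(rows_w)

        u = phi - phi0  # optimize the deviation from the initial values
        y_c = y - a @ phi0
        lam = 1.0 / config.prior_width
        curv = 2.0 * np.einsum("i,ij->j", w, a**2)
        for _ in range(1000):
            u_prev = u.copy()
            resid = y_c - a @ u
            for p in range(len(u)):
                if curv[p] <= 0:
                    u[p] = 0.0
                    continue
                resid += a[:, p] * u[p]
                z = 2.0 * float(w @ (a[:, p] * resid))
                if config.regularization == "L1":
                    u[p] = np.sign(z) * max(abs(z) - lam, 0.0) / curv[p]
                else:
                    u[p] = z / (curv[p] + 2.0 * lam**2)
                u[p] = float(np.clip(u[p], -config.k_bound - phi0[p],
                                     config.k_bound - phi0[p]))
                resid -= a[:, p] * u[p]
            if np.abs(u - u_prev).max() < 1e-12:
                break
        phi = phi0 + u
        obj = objective(phi, prepared, config, phi0, offsets)
        if obj < best[0]:
            best = (obj, phi.copy())
        key = tuple(i0s)
        if key in seen_indices:
            break  # minimum indices cycling or stable: keep the best solve
        seen_indices.add(key)
    return best[1]


# ---------------------------------------------------------------------------
# Fit driver


def fit(
    targets: list[FitTarget],
    config: ObjectiveConfig = ObjectiveConfig(),
    max_outer: int = 30,
    obj_tol: float = 1e-6,
    step_tol: float = 1e-4,
) -> FitResult:
    """Simultaneous bespoke-torsion fit over all targets.

    Outer loop: re-relax every target's geometries under the current force
    constants, rebuild the torsion basis, then solve the regularized
    weighted least-squares problem over the shared parameter vector.
    Converges when the objective change and parameter step are both small.
    """
    if not targets:
        raise UsageError("no fit targets")
    keys, offsets = _param_layout(targets)
    phases: dict[str, list[float]] = {}
    phi0 = np.zeros(4 * len(keys))
    for target in targets:
        for key in target.parameter_keys:
            terms = target.initial_terms[key]
            phi0[offsets[key] : offsets[key] + 4] = [t.k for t in terms]
            phases[key] = [t.phase for t in terms]

    prepared: list[_PreparedTarget] = []
    for target in targets:
        w = np.array([weight(e, config) for e in target.reference.relative_energies])
        if np.count_nonzero(w) < 2:
            warnings.warn(f"target {target.name!r}: fewer than 2 nonzero-weight points; excluded")
            continue
        prepared.append(
            _PreparedTarget(
                target=target,
                weights=w,
                ref_rel=np.asarray(target.reference.relative_energies, dtype=float),
                coords=[None] * len(target.reference.angles),
            )
        )
    if not prepared:
        raise UsageError("all targets excluded (no nonzero-weight points)")

    phi = phi0.copy()
    trace: list[float] = []
    rises = 0
    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        for prep in prepared:
            _apply_parameters(prep.target, phi, offsets, phases)
            # each relaxation restarts from the reference geometry so the MM
            # profile is a deterministic function of the current parameters;
            # warm-starting from the previous iterate couples the profile to
            # the optimization path and can trap the outer loop in a limit
            # cycle when grid points hop between spectator-rotor basins
            coords, raw, _ = mm_profile(
                prep.target.system, prep.target.reference, config,
            )
            prep.coords = coords
            prep.basis = _torsion_basis(prep.target, coords)
            cols = _target_columns(prep.target, offsets)
            prep.e_other = raw - prep.basis @ phi[cols]
            if config.rmsd_in_objective:
                prep.rmsd_sq = np.array([
                    _heavy_rmsd(c, r) ** 2
                    for c, r in zip(coords, prep.target.reference.geometries)
                ])

        new_phi = _solve_inner(phi, prepared, config, phi0, offsets)
        if np.any(np.isclose(np.abs(new_phi), config.k_bound, atol=1e-6)):
            warnings.warn("a force constant hit the +-20 kcal/mol bound")
        obj = objective(new_phi, prepared, config, phi0, offsets)
        step = float(np.linalg.norm(new_phi - phi))
        phi = new_phi
        # geometry re-relaxation can lift the objective by a vanishing amount
        # while the outer fixed point is approached; only sustained,
        # significant growth counts as divergence
        if trace and obj > trace[-1] + 1e-3 * max(1.0, abs(trace[-1])):
            rises += 1
            if rises >= 5:
                raise TorsionForgeError(
                    f"fit diverging: objective rose 5 consecutive outer steps "
                    f"(trace tail {trace[-5:]} -> {obj})"
                )
        else:
            rises = 0
        if trace and abs(trace[-1] - obj) < obj_tol and step < step_tol:
            trace.append(obj)
            converged = True
            break
        trace.append(obj)

    terms_out: dict[str, list[TorsionTerm]] = {}
    delta: dict[str, np.ndarray] = {}
    for key in keys:
        sl = slice(offsets[key], offsets[key] + 4)
        terms_out[key] = [
            TorsionTerm(k=float(k), n=n, phase=ph)
            for k, n, ph in zip(phi[sl], (1, 2, 3, 4), phases[key])
        ]
        delta[key] = phi[sl] - phi0[sl]

    rmse, rmse_full = {}, {}
    for prep in prepared:
        _apply_parameters(prep.target, phi, offsets, phases)
        cols = _target_columns(prep.target, offsets)
        e_raw = prep.e_other + prep.basis @ phi[cols]
        e_mm = e_raw - e_raw.min()
        resid = prep.ref_rel - e_mm
        w = prep.weights
        rmse[prep.target.name] = float(np.sqrt(np.sum(w * resid**2) / w.sum()))
        rmse_full[prep.target.name] = float(np.sqrt(np.mean(resid**2)))

    return FitResult(
        terms=terms_out,
        delta=delta,
        objective_trace=trace,
        rmse=rmse,
        rmse_full=rmse_full,
        converged=converged,
        n_outer=n_outer,
    )


def _apply_parameters(target: FitTarget, phi, offsets, phases):
    for group, key in zip(target.groups, target.parameter_keys):
        sl = slice(offsets[key], offsets[key] + 4)
        terms = [
            TorsionTerm(k=float(k), n=n, phase=ph)
            for k, n, ph in zip(phi[sl], (1, 2, 3, 4), phases[key])
        ]
        for quartet in group.quartets:
            target.system.set_torsion_terms(quartet, terms)


# ---------------------------------------------------------------------------
# Evaluation metrics


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of coordinate sets a onto b."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ a.T).T - b
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _heavy_rmsd(a, b, heavy=None):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if heavy is not None:
        a, b = a[heavy], b[heavy]
    return _kabsch_rmsd(a, b)


def evaluate_metrics(
    system: ParametrizedSystem,
    reference: TorsionScanResult,
    heavy_atoms: list[int] | None = None,
) -> tuple[float, float]:
    """Scan RMSE (kcal/mol) and max per-point heavy-atom RMSD (Angstrom).

    From each reference geometry, the structure undergoes a full MM
    relaxation with only the driven dihedral fixed (no positional
    restraints); the RMSE compares relative energy profiles (each normalized
    to its own minimum, so both are invariant to uniform shifts) and the
    RMSD is taken after optimal rigid superposition, maximum over the scan.
    """
    config = ObjectiveConfig(restraint_k=None)
    coords, _, e_mm = mm_profile(system, reference, config)
    rmse = float(np.sqrt(np.mean((reference.relative_energies - e_mm) ** 2)))
    max_rmsd = 0.0
    for xyz, ref in zip(coords, reference.geometries):
        if ref is None:
            continue
        max_rmsd = max(max_rmsd, _heavy_rmsd(xyz, ref, heavy_atoms))
    return rmse, max_rmsd
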