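# Methods

`torsionforge` builds *bespoke* torsion parameters: instead of reusing a
handful of transferable torsion types, it carves a small capped fragment
around every rotatable bond of the input molecule, scans the driven
dihedral against a reference potential, and fits a dedicated Fourier series
for each symmetry-distinct torsion through that bond. This note records the
model, the procedure, the defaults, and the choices made where the design
was genuinely open.

## Torsion model

Each torsion type contributes a truncated Fourier series

    E(phi) = sum_i  k_i * (1 + cos(n_i * phi - phi0_i))

with force constants `k_i` (kcal/mol), integer periodicities `n_i`, and
phases `phi0_i` (degrees). Before fitting, the periodicities of every
fitted type are expanded to the full set n = 1..4; terms inherited from the
base force field keep their `(k, n, phi0)`, newly introduced terms start at
k = 0 with phase 0. Only the force constants are optimized; periodicities,
phases and the 1-4 scaling factors stay fixed.

## Symmetry typing

Torsion quartets (i, j, k, l) through a rotatable bond (j, k) are grouped
by the 4-tuple of topological symmetry classes of their atoms, with a
quartet and its reverse identified. Symmetry classes come from an
iterative Morgan-style refinement: atoms are seeded with
(element, formal charge, degree, ring flag, H count) and repeatedly
re-partitioned by the sorted multiset of neighbour classes until the
partition is stable for two consecutive rounds (capped at N_atoms rounds).
Class ids are dense ranks of the refined invariants, so the partition is
invariant to atom renumbering. The test suite cross-checks this partition
against RDKit's canonical ranking with ties preserved on a 20-molecule
panel. Biphenyl's central bond yields one torsion type; the
ester-oxygen–aryl bond of aspirin yields two, because the two ortho
environments differ.

Rotatable bonds are non-ring, non-triple bonds whose atoms both have
further neighbours; bonds into sp centres (atoms in a triple bond) are
excluded because every dihedral through a linear centre is degenerate.
Amide bonds are *not* excluded. Hydrogens take part in quartets and
symmetry classes; improper torsions are never fitted.

## Fragmentation and the bond-order gate

The initial fragment around a bond keeps the bond's atoms, everything
within one bond of them, whole rings and aromatic systems (a ring is never
cut), and never cuts a non-single bond; open valences are hydrogen-capped,
and every hydrogen of an included heavy atom is kept. A fragment is
accepted only when the central-bond bond order computed on the fragment
matches the parent value within a threshold (default 0.03 e, boundary
inclusive with a 1e-9 epsilon against binary-representation noise).
Rejected fragments grow greedily: among the adjacent parent substituents
(each taken with its ring/multiple-bond closure), the one whose inclusion
most reduces the bond-order disruption is added; ties break by smallest
added atom count, then lowest parent atom index. The loop strictly grows
the fragment, and the parent itself is always accepted, so termination is
guaranteed.

Quantum Wiberg bond orders are out of scope by design. The default
provider is a *topological surrogate*: nominal bond order plus small
distance-weighted increments (0.02/0.01/0.005 at graph distance 1/2/3)
from nearby pi systems and heteroatoms. It is deterministic and
conjugation-aware, and any callable `(molecule, bond) -> float` can replace
it.

## SMIRKS generation

One pattern is generated per torsion type group. The common substructure
of fragment and parent (the fragment's own atom map — exact by
construction, validated for injectivity, connectivity and bond
consistency) is embedded in full: every pattern atom carries atomic
number, aromaticity, degree, total-H count, formal charge and ring
membership; bonds carry order and a ring flag. Attributes that differ
between parent and fragment — the hydrogen count at a cut-adjacent atom,
and everything about a cap hydrogen versus the substituent it replaced —
are written as OR alternatives, so the same pattern matches the fragment,
the parent, and any other molecule containing the exact substructure, and
nothing else. The four dihedral atoms carry map indices :1–:4. Rendering
is a DFS from the :1 atom in ascending fragment-index order, which makes
the text deterministic. Every generated pattern is self-checked: it must
re-match its own fragment and tag at least the group's quartets, otherwise
generation fails loudly.

## Reference scans

Scans run on a regular grid over (−180°, 180°], default spacing 15°
(configurable; the half-open convention avoids a duplicate ±180° point).
Each seed conformer is snapped to its nearest grid point and
constrained-minimized; whenever a grid point improves by more than
1e-6 kcal/mol, the improved structure is rotated by one spacing and queued
at both neighbours (wavefront propagation). Per-point best energies are
non-increasing, so the scan terminates; a scan fails if more than 10% of
points never produce a result. Up to four seed conformers are generated
by seeded ETKDG embedding, greedily filtered to pairwise heavy-atom RMSD
≥ 0.5 Å.

The two-rotor toy surface
`E = d(1+cos phi) + b(1−cos 2psi) + c·cos psi·cos phi` (b = 0.5, c = 3,
d = 1) is the oracle fixture: each spectator basin loses local stability
on part of the driven grid, so per-point optimization from a single seed
is provably trapped, while the exhaustive per-point global minimum is
computable by enumeration. Wavefront results must match that oracle to
1e-6 kcal/mol.

## MM model and minimization

The baseline model is deliberately minimal class-1 MM: harmonic bonds
(E = kb/2 (r−r0)², r0 from order-scaled covalent-radius sums), harmonic
angles (ka = 70 kcal/mol/rad², references 109.47°/120°/~180° by
hybridization), the Fourier torsions above, 12-6 Lennard-Jones with
Lorentz–Berthelot combination and UFF-like per-element parameters, and
Gasteiger charges (an electronegativity-equalization stand-in chosen
because semiempirical charge models are out of scope). 1-2/1-3 pairs are
excluded; 1-4 pairs are scaled by 0.5 (LJ) and 0.8333 (electrostatics).
Gradients are analytic and verified against central finite differences to
1e-4 kcal/mol/Å.

Minimization is L-BFGS with gradient tolerance 1e-6 kcal/mol/Å and a
2000-iteration cap. A dihedral is frozen by a stiff harmonic restraint
(5000 kcal/mol/rad²) *plus* an exact rigid-rotation snap of the far-side
subtree onto the target angle afterwards; the restraint alone would leave
a residual deflection of order k/5000 rad (~0.03°), while the contract is
1e-3°, hence the snap. The returned energy excludes restraint terms and
never exceeds the energy of the (snapped) input. Pair distances below
0.1 Å trip a numerical guard.

## Fitting objective

With reference and MM relative energies (each normalized to its own global
minimum over the scan), the data term is the plain weighted sum

    sum_i  w(E_ref(x_i)) * (E_ref(x_i) − E_MM(x_i))^2 / S_f^2 ,

S_f = 1 kcal/mol, summed over all targets. The weight is 1 up to
E1 = 1 kcal/mol, zero at and beyond E2 = 10 kcal/mol, and
`w = (1 + (E−E1)^2)^(−1/2)` in between — continuous at E1; a linear ramp
is available. An optional per-target division by the weight sum exists
(`normalize_by_weight_sum`) but is off by default: measured on the
synthetic recovery conditions it inflates the effective prior strength
roughly twentyfold, biasing each recovered force constant by
~0.05 kcal/mol, whereas the plain sum typically recovers injected
constants to ~0.03 kcal/mol (worst replicates near 0.1 across broader
seed streams, where the L1 prior admits a nearly degenerate alternative
optimum) with weighted RMSE of order 0.02.

Regularization defaults to L1, `sum_p |delta_p| / sigma_p` with prior
width sigma_p = 6.0 relative to the *initial* parameter values; L2
`(delta_p/sigma_p)^2` is available. L1 is what lets the fully expanded
periodicities coexist: harmonics the surface does not need shrink to zero
(the sparsity fixture drives the redundant n = 1, 2, 4 constants below
0.05 kcal/mol on a pure-n=3 surface).

At every outer iteration the geometry at each grid point is re-relaxed
under the current force constants — dihedral frozen at the grid angle,
all other atoms under a weak positional restraint (1 kcal/mol/Å²) toward
the reference geometry (off with `restraint_k=None`) — then the torsion
basis (dE/dk per grid point per term) is rebuilt and the regularized
problem solved over the full shared parameter vector. Each relaxation
restarts from the reference geometry rather than the previous iterate:
warm-starting couples the relaxed profile to the optimization path and
can trap the outer loop in a limit cycle when grid points hop between
spectator-rotor basins.

The inner problem is piecewise smooth (the grid point holding the MM
global minimum can change with k) with L1 kinks, and no single local
method proved reliable on it: scipy's bounded Powell can stop on a point
worse than its start, and an exact coordinate-descent lasso is exact only
per pinned minimum index. The solver therefore computes three
deterministic candidates — iterated-pinning coordinate descent
(soft-thresholding sweeps, ridge update under L2), Powell from the
current iterate, and Powell from the initial values — and keeps the one
with the lowest honestly-evaluated objective. Force constants are
clipped to ±20 kcal/mol as a numerical guard (hitting the bound warns).
Parameters keyed by the same SMIRKS are shared across targets, which is
both how coupled torsions on one molecule are fitted simultaneously and
how congeneric series reuse core parameters. Convergence: objective
change below 1e-6 and step norm below 1e-4. Because the geometry
re-relaxation step can lift the objective by a vanishing, decaying
amount while the outer fixed point is approached, only five consecutive
rises above a 1e-3 relative tolerance abort the fit as divergent.

An optional variant adds `rmsd_weight * w_i * RMSD_i^2` per grid point to
the objective (heavy-atom RMSD after optimal superposition onto the
reference geometry).

## Metrics

`evaluate_metrics` relaxes each reference geometry fully (driven dihedral
fixed, no positional restraints) and reports the RMSE between the two
relative-energy profiles — invariant to uniform energy shifts by
construction — and the maximum per-point RMSD after Kabsch superposition.

## Hierarchy, combining, caching

Torsion records are an ordered list; assignment takes the *last* matching
record, so bespoke records appended at the bottom override the generic
base exactly where their substructure occurs. Combining force fields
requires an identical base, deduplicates identical (SMIRKS, terms)
records, and treats identical SMIRKS with different terms as a hard error.
The parameter cache is keyed by the canonical SMILES of the fragment with
map indices 1–4 on the torsion atoms, minimized over the two quartet
orientations, so graph-isomorphic fragments with equivalent driven
torsions hit the same entry and receive bit-identical constants. No
idivf-style division by quartet multiplicity is applied: a record's k is
the per-quartet constant.

## Synthetic reference data — what it shows and what it does not

All quantitative fixtures are scans of the package's own baseline MM model
with injected Fourier terms of known coefficients, so fits have an exact
right answer. The recovery fixture uses dimethyl peroxide (10 atoms,
flexible): its O–O bond carries exactly one torsion type with one quartet,
which makes the injected coefficients identifiable from a 1D scan. That
choice is deliberate — on a bond with several torsion types the rigid
Fourier bases of the types are nearly collinear (for an ideal threefold
rotor, exactly proportional), so a 1D scan cannot attribute amplitude to
individual types and only their regularized combination is determined.
Injected terms use |k| between 0.5 and 3 kcal/mol and n drawn from 1..4,
two terms per target. The synthetic data reproduces the *shape* of a
quantum torsion drive but none of its electronic structure; passing these
tests demonstrates that the machinery (typing, scanning, weighting,
regularized fitting, caching) is correct, not that the surrogate bond
orders or Gasteiger charges are chemically accurate.

## Problem sizes and defaults used in the checks

The shipped checks use 24-point grids (15°) for scans fitted quantities
and 12-point grids (30°) with a single seed conformer for the end-to-end
workflow demonstrations on ethanol/propanol; ten seeded recovery
replicates. These sizes were chosen so the whole battery is a
desk-scale computation while every contract (tolerances above) is still
sharply testable.

## Known limitations

- The bond-order surrogate and Gasteiger charges are topological
  stand-ins; absolute torsion profiles are not chemically predictive.
- 2D torsion drives, improper torsions, tautomer/protomer enumeration and
  fitting of non-torsion parameters are out of scope.
- Per-type attribution of torsion amplitude on multi-type bonds is
  regularization-determined (see above), as in any 1D-scan bespoke fit.
- The grow loop is greedy; it finds *an* accepted fragment, not provably
  the smallest one.
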