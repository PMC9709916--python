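# torsionforge

Bespoke torsion force-field parametrization for drug-like molecules.

General-purpose force fields describe a torsion with a handful of
transferable types, which is often too coarse for the rotatable bonds that
decide a ligand's bound conformation. `torsionforge` instead derives a
dedicated torsion potential for every rotatable bond of a given molecule:

1. **Fragment** — carve a small hydrogen-capped fragment around each
   rotatable bond, accepted only when the central-bond Wiberg-style bond
   order is conserved within 0.03 e (rings are never cut; rejected
   fragments grow greedily until accepted).
2. **Type** — group the atom quartets through the bond by topological
   symmetry classes (Morgan-style refinement), one parameter set per
   symmetry-distinct torsion. Biphenyl's central bond gives one type;
   aspirin's ester-oxygen–aryl bond gives two.
3. **Encode** — generate a highly specific SMIRKS pattern per type,
   embedding the parent/fragment common substructure and writing their
   differences as OR alternatives, with the dihedral atoms tagged `:1`–`:4`.
4. **Scan** — drive the dihedral over a regular grid (default 15°) with
   wavefront propagation: any newly found low-energy structure re-seeds its
   neighbouring grid points, avoiding hysteresis when spectator rotors have
   multiple basins. Energy backends are pluggable.
5. **Fit** — expand each type's periodicities to n = 1..4 and optimize the
   force constants k of

       E(phi) = sum_i k_i (1 + cos(n_i phi - phi0_i))

   by minimizing `sum_i w(E_ref) (E_ref - E_MM)^2 / S_f^2 + sum_p |dk_p| / sigma_p`,
   with weights flat below 1 kcal/mol and zero above 10 kcal/mol, an L1
   prior of width sigma_p = 6 toward the initial values, and restrained MM
   re-relaxation (1 kcal/mol/Å², dihedral frozen) at every grid point. All
   fragments are fitted simultaneously; parameters with the same SMIRKS are
   shared.
6. **Store** — append the fitted records at the bottom of a hierarchical
   SMIRKS-keyed force field (last match wins), combine per-ligand force
   fields, and cache fitted constants by canonical mapped fragment SMILES
   so congeneric series reuse their core parameters.

Quantum backends are represented only as a contract; reference data here
comes from user-supplied scan files or from the built-in synthetic
generator (baseline MM plus injected Fourier terms with known
coefficients), which makes every fit exactly checkable. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```bash
torsionforge run --smiles OO --reference analytic --grid-spacing 30 \
    --seed 3 --output report.json --output-force-field bespoke.json
```

prints

```
wrote report.json and bespoke.json (1 bespoke record(s))
```

Hydrogen peroxide has one rotatable bond (O–O) with a single torsion type
(the H–O–O–H quartet). The `analytic` reference injects seeded Fourier
terms onto the baseline MM model and the fit recovers them;
`report.json` records the fragment, its bond-order check, the scan
provenance and the fit trace:

```json
"fit": {
  "converged": true,
  "n_outer": 2,
  "n_parameters": 4,
  "rmse_weighted": {"fragment-0": 0.01794538}
}
```

— the weighted RMSE (kcal/mol) between the reference scan and the refitted
MM profile. `bespoke.json` ends with the fitted record, whose SMIRKS
matches exactly the H–O–O–H substructure; the L1 prior has kept the
unneeded n = 1 and n = 4 harmonics at zero:

```json
{"id": "t-bespoke-0",
 "smirks": "[#1;A;X1;H0;+0;!R:1]-;!@[#8;A;X2;H1;+0;!R:2]-;!@[#8;A;X2;H1;+0;!R:3]-;!@[#1;A;X1;H0;+0;!R:4]",
 "terms": [{"k": 0.0, "n": 1, "phase": 0.0},
           {"k": -0.5507018903734391, "n": 2, "phase": 0.0},
           {"k": -0.48166978235416696, "n": 3, "phase": 0.0},
           {"k": 0.0, "n": 4, "phase": 0.0}]}
```

Scoring the fitted force field against a scan generated from itself closes
the loop:

```bash
torsionforge evaluate --smiles OO --scan scan.json --ff bespoke.json
# scan RMSE: 0.0000 kcal/mol
# max heavy-atom RMSD: 0.0000 A
```

Other subcommands: `torsionforge ff combine a.json b.json -o c.json`
(merge bespoke force fields, deduplicating shared records) and
`torsionforge dataset build --smiles ... -o dataset.json` (filter,
fragment, embed conformers, deduplicate scans).

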