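# fragcharge

Fragment-based ESP atomic charges, molecular electrostatic potential (MEP)
analysis and Poisson–Boltzmann (PB) continuum solvation for polypeptides.

A protein chain is cut through its peptide bonds into capped three-residue
fragments with conjugate-cap (concap) overlap corrections and two-body
subsystems for spatially close, sequence-distant residue pairs.  Every
subsystem is ESP-fitted in the electrostatic field of the point charges of
the remaining atoms (with link-atom equality restraints between concap and
fragment fits), and the per-subsystem charges are combined into per-atom
protein charges by signed assembly.  The assembled charge model feeds:

- **MEP analysis** — potentials on a 2.5–4.5 Å shell grid around the
  protein, with RMSD/correlation comparison between charge models and a
  sweep over the two-body distance threshold λ;
- **PB solvation** — an in-repo finite-difference linearized PB solver
  (ε_in = 1, ε_out = 80, probe 1.4 Å, optional Debye screening) iterated
  self-consistently: induced surface charges are fed back into the
  subsystem backgrounds until the reaction-field energy converges.

A deterministic mock QM backend (Coulomb potential of bundled reference
charges, with an optional linear polarization response to the embedding
field) makes the entire pipeline testable offline; an optional pyscf
backend implements the same contract for desk-scale ab initio runs.

## Layout

| module | contents |
|---|---|
| `fragcharge.structure` | atom/residue/charge data model, PDB in, PQR out, bundled charge + radius tables |
| `fragcharge.fragmentation` | capped fragments, concaps, two-body pairs, link hydrogens, embedding backgrounds |
| `fragcharge.qm` | QM backend contract, mock Coulomb backend, optional pyscf backend, content-hash caching |
| `fragcharge.espfit` | Merz–Kollman shell grids, charge-constrained restrained ESP fitting |
| `fragcharge.assembly` | per-atom charge assembly, total-energy assembly with the pairwise double-count deduction |
| `fragcharge.mep` | shell grids, potential evaluation, RMSD/correlation, λ sweep |
| `fragcharge.pb` | FD linearized PB solver, induced surface charges, SCRF loop, conformer tables |
| `fragcharge.fixtures` | ideal-geometry peptide generator, conformer ensembles, contact fixtures |
| `fragcharge.cli` / `config` / `pipeline` | CLI, YAML config schema, run manifests |

## CLI

```bash
# generate an ideal-geometry fixture peptide (writes PDB + charge JSON)
fragcharge fixture --seq AAAAA --phi -57 --psi -47 --out pent.pdb

# fragment manifest (fragments / concaps / two-body pairs, link atoms flagged)
fragcharge fragment pent.pdb --lambda 4.0 --out frags.json

# assembled per-atom charges (mock backend by default)
fragcharge charges pent.pdb --lambda 4.0 --backend mock --out charges.json

# MEP comparison of two charge models on the 2.5-4.5 A shell
fragcharge mep pent.pdb --charges charges.json --ref pent.charges.json

# self-consistent PB solvation
fragcharge solvate pent.pdb --backend mock --tol 0.1 --max-iter 10 --out solv.json

# RMSD vs the two-body threshold
fragcharge sweep-lambda pent.pdb --lambdas 0,1.7,2.7,4.0 --out sweep.json
```

All open parameters (λ, fit shells/density, link-restraint weight, PB grid
spacing/padding, SCRF tolerance) live in a YAML config (`--config`); every
run writes a manifest JSON recording the config snapshot and input hashes.

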