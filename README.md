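# pepbuild

**pepbuild** builds capped peptide model structures for quantum-chemistry
workflows: fragments of arbitrary sequence with *exact* control of every
backbone (φ, ψ, ω) and side-chain (χ) torsion angle, continuous sampling of
realistic conformations, a clash-removing "regularization" procedure that
preserves the requested torsions, and writers for PDB/XYZ files and
Gaussian-/GAMESS-style input decks.

It is aimed at computational chemists who need many well-defined peptide
geometries — for force-field or chemical-shift parametrization, torsion
scans, or benchmark sets — without running a molecular-dynamics engine or
hand-editing Z-matrices.

## The model

A peptide is assembled in internal coordinates: each atom is placed from
three previously placed reference atoms by bond length *r*, bond angle θ and
dihedral τ (the NeRF construction), so the molecule is born with exactly the
requested torsions.  Conventions:

- φ(i) = C(i−1)–N(i)–Cα(i)–C(i), ψ(i) = N(i)–Cα(i)–C(i)–N(i+1),
  ω(i) = Cα(i−1)–C(i−1)–N(i)–Cα(i) (the peptide bond preceding residue i);
  χₙ follows the standard IUPAC quadruples.
- All torsions live in the canonical range [−180°, 180°); fresh builds are
  extended strands with (φ, ψ, ω) = (−120°, 140°, −180°).
- Termini are capped with methyl groups (acetyl / N-methylamide, the
  default) or as charged (NH₃⁺ / COO⁻) or neutral (NH₂ / COOH) termini.

Conformations are sampled from mixtures of von Mises distributions on the
torus,

  f(x) = Σₖ wₖ ∏ⱼ exp(κₖⱼ cos(xⱼ − μₖⱼ)) / (2π I₀(κₖⱼ)),

with backbone components at the α, β and left-handed-α Ramachandran basins
and rotamer-like χ components at gauche±/trans; side-chain weights are
re-weighted by the current backbone basin.  Every sample carries its exact
log-density.

Steric clashes are removed by *regularization*: cycles of restrained
conjugate-gradient minimization (harmonic torsion restraints, a simple
bonded + r⁻¹² repulsion force field) alternating with exact rigid-body
torsion resets, until the restrained minimum agrees with the requested
angles to below 0.002°.

## Worked example

```python
from pepbuild import Peptide

pep = Peptide("GLG")                  # Gly-Leu-Gly, methyl caps, 45 atoms
pep.set_bb_angles(2, [-60.0, -30.0])  # leucine backbone
pep.set_chi_angles(2, [180.0, 60.0])  # leucine side chain
print(pep.get_bb_angles(2))           # [-60.0, -30.0, -180.0]
print(pep.get_chi_angles(2))          # [-180.0, 60.0]  (180 == -180)
pep.regularize()
pep.write_xyz("pep.xyz")
```

Sampling and clash removal (`examples/` holds one short script per
capability; the numbers below are their actual output):

```text
$ python examples/regularize_clash.py
clashing conformer: min H...O distance 1.453 A, energy 33.00 kcal/mol
regularized in 100 CG steps: energy 16.02 kcal/mol
min H...O distance now 1.610 A (clash relieved by bond/angle relaxation)
max torsion deviation before the final reset: 1.18e-03 deg (self-consistent < 2e-3)
```

The minimum H···O contact grows from far inside van der Waals overlap to a
plausible hydrogen-bond distance while every set torsion stays put — the
structure is now safe to hand to a QM geometry optimization.

The same workflows are available from the shell:

```bash
pepbuild build --seq GLG --set 2:phi=-60 --set 2:psi=-30 --out pep.pdb
pepbuild scan --seq GLG --res 2 --torsion psi --start 100 --step 20 \
    --count 10 --out pep.xyz
pepbuild build --seq GLG --sample --seed 42 --regularize --out pep.com
pepbuild pdb-info structure.pdb
```

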