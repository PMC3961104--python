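# Methods

This note records the models, parameter choices and numerical conventions
behind pepbuild, and what its synthetic tests do and do not demonstrate.

## Geometry construction

Peptides are assembled atom by atom in internal coordinates (NeRF): atom D
is placed from references A, B, C so that |C−D| = r, ∠(B,C,D) = θ and the
dihedral A–B–C–D = τ, each reproduced to ~1e−9 of the request.  Dihedrals
follow the IUPAC sign convention and are wrapped into the canonical range
[−180°, 180°); −180° is canonical so the default trans peptide bond
(ω = −180°) is representable verbatim, and +180° wraps to −180°.  Reference
frames are rejected as degenerate when the sine of the frame angle falls
below 1e−8.

Torsion changes are rigid rotations of the connectivity subtree distal to
the torsion's central bond, so bond lengths and angles are preserved to
1e−9 Å under any sequence of set operations.  Ring closures (the proline
pyrrolidine) are tracked as extra bonds; a rotation whose moving set would
sever a closure is refused, which makes proline's φ fixed by construction.
Proline's ring torsions are likewise not controllable, and backbone
sampling on proline applies ψ only.

## Residue and cap templates

Template internal coordinates were measured once, at development time, from
Chemical Component Dictionary ideal residue geometries, with Engh/Huber-style
constants at the inter-residue junction (C–N 1.329 Å, Cα–C–N 116.2°,
C–N–Cα 121.7°, N–H 1.010 Å), and frozen into plain-text files
(`src/pepbuild/data/templates/*.tmpl`; one file per residue or cap,
columns: atom, element, three reference atoms, r, θ, τ-offset, torsion
reference).  Downstream behavior depends on torsions, not on the exact
stereochemical set; any self-consistent set would serve.

Protonation is fixed and neutral everywhere: Asp/Glu carry their acid
proton, Lys is a neutral amine, Arg a neutral guanidine, His the neutral
Nε2–H tautomer, Cys a thiol.  Fragment charge is therefore set by the
termini alone (+1 for a charged N-terminus, −1 for a charged C-terminus),
which is the rule the QM deck writers apply.  Alternative protonation
states and D-amino acids are out of scope; Cα chirality is L for all
templates (validated by a signed-volume test).

Default side-chain conformations are the least-clashing standard rotamer
(all gauche±/trans combinations scored with the shipped force field in an
extended G-X-G context): χ₁ = −60° for most types, Val t, Leu (−60°, 180°),
etc.  A uniform χ = 180° default leaves severe intra-residue clashes for
aromatic and branched residues, so "extended where chemically sensible" is
resolved per residue in the template data.

## Conformational sampling

Angle distributions are mixtures of independent-per-dimension von Mises
components (`data/mixtures.json`):

- backbone, generic residue: α basin μ = (−63°, −43°), κ = (8, 8), w = 0.40;
  β basin μ = (−120°, 135°), κ = (4, 3), w = 0.50; left-handed α
  μ = (60°, 45°), κ = (8, 8), w = 0.10;
- glycine: φ-symmetric four-component mixture; proline: φ pinned near −65°
  (κ = 50) with α- and β-like ψ components;
- side chains: components at −60°/180°/+60° per dimension, κ = 12,
  weights (0.45, 0.35, 0.20), re-weighted by the Ramachandran basin of the
  current backbone when backbone-dependent sampling is on (the default).

These are conventional textbook basin positions, chosen for plausibility
and replaceability, not fitted to any structural survey.  The sampler
recovers whatever mixture it is configured with (verified by chi-square
tests against quadrature-derived expected masses); passing those tests
says nothing about agreement with experimental Ramachandran or rotamer
statistics.  Users wanting data-derived distributions should supply their
own parameter file to `MixtureLibrary`.

Densities and log-likelihoods use the natural per-radianᵈ convention.
Seeding follows numpy best practice: one process-global generator reset by
`set_seed`, or explicit `SamplerState` objects (which also accept
`SeedSequence` children for independent streams).

## Energy model

The shipped force field is deliberately minimal — its job is clash relief
under torsion restraints, not quantitative energetics:

| term       | form                    | default                       |
|------------|-------------------------|-------------------------------|
| bond       | k_b (r − r₀)²           | k_b = 300 kcal mol⁻¹ Å⁻²      |
| angle      | k_a (θ − θ₀)²           | k_a = 80 kcal mol⁻¹ rad⁻²     |
| torsion    | (V₃/2)(1 + cos 3τ)      | V₃ = 0.05 kcal mol⁻¹          |
| repulsion  | ε (σᵢⱼ/r)¹²             | ε = 0.10 kcal mol⁻¹           |

σᵢⱼ = 0.85 × (Bondi radius sum); 1–2 and 1–3 pairs are excluded, 1–4 pairs
scaled by 0.5.  Reference r₀/θ₀ are the as-built template values, so the
bonded energy is zero at construction and the analytic gradient matches
central finite differences to ~1e−5 relative (tested).  There are no
electrostatics, no attractive dispersion and no solvent; absolute energies
are not comparable to MMFF94 or any published force field.  The backend is
pluggable: anything exposing `energy_gradient(coords) -> (E, grad)` can
replace the compiled model.

## Minimization and regularization

Minimization is Polak–Ribière conjugate gradient with restart on loss of
descent, an Armijo backtracking line search from a fixed initial trial
(largest per-atom move 0.05 Å) plus deterministic greedy step doubling
while the objective improves.  Convergence is declared when the energy
decrease of a step falls below `tol` (default 1e−6 kcal/mol, per accepted
step) — tested against steepest descent before stopping — or at
`max_steps` (default 500).  The optimizer is fully deterministic.

Constrained optimization adds a harmonic restraint k·Δ² (Δ = wrapped
angular deviation in radians) on every controllable φ/ψ/ω/χ at its stored
target.  The default k = 100 kcal mol⁻¹ rad⁻² was selected by a stiffness
sweep (50–200) on clashing tripeptide conformers as the smallest round
value keeping every restrained torsion within 2° of its target at the
restrained minimum; restraint energy is excluded from reported energies.

Regularization repeats [≤ 50 constrained CG steps; exact rigid reset of
every controllable torsion] up to 10 times, stopping early when the
*pre-reset* maximum torsion deviation drops below 0.002°.  At a restrained
minimum the deviation of torsion *i* is fᵢ/(2k), with fᵢ the residual
generalized force — 1–15 kcal mol⁻¹ rad⁻¹ near a clash — so the 0.002°
(3.5e−5 rad) self-consistency level requires k on the order of 10⁵–10⁶;
regularization therefore defaults to k = 10⁶ kcal mol⁻¹ rad⁻².  Because
every cycle starts with all torsions exactly at target, the stiff
restraints are never far from their minima and conditioning stays
manageable.  After the final reset every controllable torsion equals its
target to 1e−6°.

Unconstrained optimization refreshes the stored torsion targets from the
relaxed coordinates; constrained runs leave targets untouched.

## File I/O

PDB output is fixed-width v3.3 (occupancy 1.00, B 0.00, element column
filled, TER/END); methyl caps are written as ACE/NME residues, charged and
neutral termini as extra atoms of the first/last residue.  Reading (via
gemmi) uses the first model, collapses altlocs to the preferred conformer,
takes the first chain by default, and indexes amino acids 1-based in order
of appearance.  Torsions whose defining atoms are missing are reported as
`None`, never guessed.

Precision: PDB coordinates carry 3 decimals, so ±0.0005 Å quantization on
the four defining atoms propagates to torsion read-back errors up to
~0.1° (measured worst case 0.096° over 50 random tripeptide conformers).
This is a property of the format, not of the reader.  XYZ output carries 8
decimals and round-trips essentially exactly.

QM decks: Gaussian-style `.com` (route line `# method [opt|NMR=GIAO]`,
title, charge/multiplicity, Cartesians; method defaults to PM6) and a
minimal GAMESS-style `.inp` ($CONTRL/$DATA, C1 symmetry).  Other formats
pass through the `obabel` converter when it is installed.

## Problem sizes and test scope

The test and acceptance workloads use tripeptides (45–56 atoms): large
enough to exercise caps, side chains, ring closure and inter-residue
clashes, small enough that the full suite runs in well under a minute of
CPU plus ~15 s for the 10,000-draw-per-residue-type sampler checks.  The
synthetic clash fixture (Trp-Asp-Gly, backbone (φ₂, ψ₂, φ₃, ψ₃) =
(−45°, −30°, −60°, −15°)) places the C-cap amide hydrogen 1.45 Å from the
residue-1 carbonyl oxygen, emulating the over-short hydrogen-bond contact
that blocks QM optimizations; it does not emulate lever-arm clashes in
long chains, aromatic stacking overlaps, or disulfide strain.

## Known limitations

- Single chains only; no disulfides, no non-standard residues, no altloc
  or insertion-code handling on output.
- The force field is qualitative; energies are useful for ranking clash
  relief, nothing else.
- Sampling mixtures are conventional defaults, not trained densities.
- Proline φ and ring χ are fixed at template geometry.
- Torsions read from PDB are limited to ~0.1° by the format's coordinate
  precision.
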