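"""Build a capped tripeptide and control its torsions exactly.

A freshly built peptide is an ideal extended beta strand
(phi = -120, psi = 140, omega = -180); individual backbone and
side-chain angles can then be dialed to any value and are reproduced
exactly when re-measured from the Cartesian coordinates.
"""

from pepbuild import Peptide

pep = Peptide("GLG")  # glycine-leucine-glycine, methyl caps (ACE/NME)
print(f"built {pep.sequence}: {pep.n_atoms} atoms")
for res in (1, 2, 3):
    phi, psi, omega = pep.get_bb_angles(res)
    print(f"  residue {res} ({pep.get_resname(res)}): "
          f"phi={phi:8.3f}  psi={psi:8.3f}  omega={omega:8.3f}")

# place the leucine in a right-handed helical backbone conformation with
# a trans/gauche+ side chain
pep.set_bb_angles(2, [-60.0, -30.0])
pep.set_chi_angles(2, [180.0, 60.0])

phi, psi, omega = pep.get_bb_angles(2)
chi1, chi2 = pep.get_chi_angles(2)
print("after assignment, re-measured from coordinates:")
print(f"  phi={phi:.6f}  psi={psi:.6f}  (requested -60, -30)")
print(f"  chi1={chi1:.6f}  chi2={chi2:.6f}  (requested 180, 60; "
      "180 and -180 are the same torsion)")

pep.write_xyz("glg.xyz")
print("wrote glg.xyz (atom count on line 1, coordinates in Angstrom)")
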