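"""Extract sequence and torsion angles from a PDB file.

Writes a conformer to PDB, reads it back, and prints the torsions
measured from the file coordinates.  Angles whose defining atoms are
absent (e.g. phi of a residue with no preceding carbonyl carbon) are
reported as None, never fabricated.  PDB stores coordinates at 3
decimals, so read-back torsions agree with the originals to ~0.1 degree.
"""

from pepbuild import Peptide, read_pdb

pep = Peptide("GLG", nterm="charged", cterm="methyl")
pep.set_bb_angles(2, [-60.0, -30.0])
pep.set_chi_angles(2, [180.0, 60.0])
pep.write_pdb("structure.pdb")

pdbfile = read_pdb("structure.pdb")
print(f"sequence: {pdbfile.get_sequence()}")
for i in range(1, pdbfile.n_residues + 1):
    bb = ["None" if x is None else f"{x:8.3f}"
          for x in pdbfile.get_bb_angles(i)]
    chi = [f"{x:8.3f}" for x in pdbfile.get_chi_angles(i)]
    print(f"  {i} {pdbfile.get_resname(i)}: phi/psi/omega = {bb}  "
          f"chi = {chi}")
print("note: residue 1 has a charged -NH3+ terminus, so its phi and "
      "omega are undefined (no preceding C)")
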