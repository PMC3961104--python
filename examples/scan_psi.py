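"""Generate a torsion scan: ten conformers stepping psi by 20 degrees.

Angles outside [-180, 180) wrap canonically, so the scan walks off +180
and re-enters at -180 — the printed psi values show the wrap.
"""

from pepbuild import Peptide

pep = Peptide("GLG")
for i in range(10):
    pep.set_bb_angles(2, [-120.0, 100.0 + 20.0 * i])
    pep.write_xyz(f"pep_{i}.xyz")
    print(f"pep_{i}.xyz: psi(2) = {pep.get_bb_angles(2)[1]:8.2f}")
print("ten structures written; each differs only in the residue-2 psi")
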