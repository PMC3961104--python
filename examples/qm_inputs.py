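"""Write quantum-chemistry input decks for a built peptide.

The Gaussian-style writer emits a route line, title, charge/multiplicity
and the Cartesian block; with no method set it defaults to the PM6
semi-empirical Hamiltonian.  The fragment charge follows from the cap
kinds: a charged N-terminus (+1), a charged C-terminus (-1), zero for
methyl or neutral caps.
"""

from pepbuild import Peptide, QmJobSpec, write_qm_input
from pepbuild.fileio import fragment_charge

pep = Peptide("GAG")
write_qm_input(pep, QmJobSpec(job_kind="opt",
                              method="B3LYP/6-31G(d)"), "gaussian",
               "gag_opt.com")
print("gag_opt.com route line:",
      open("gag_opt.com").readline().strip())

write_qm_input(pep, QmJobSpec(job_kind="nmr"), "gaussian", "gag_nmr.com")
print("gag_nmr.com route line:",
      open("gag_nmr.com").readline().strip())

write_qm_input(pep, QmJobSpec(job_kind="energy"), "gamess", "gag.inp")
print("gag.inp control group:", open("gag.inp").readline().strip())

charged = Peptide("GAG", nterm="charged", cterm="methyl")
print(f"charged N-terminus fragment: total charge "
      f"{fragment_charge(charged):+d} (written into the deck)")
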