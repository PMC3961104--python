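"""Sample realistic conformations from continuous angle distributions.

Backbone (phi, psi) pairs come from a Ramachandran-style von Mises
mixture (alpha / beta / left-handed-alpha basins); side chains come from
rotamer-like mixtures whose weights depend on the sampled backbone basin.
Each draw is a fresh continuous sample, not a library entry, and carries
its exact log-density (ll) under the model.
"""

from pepbuild import Peptide, TorsionSampler, set_seed

set_seed(42)  # reproducible stream: rerunning prints identical numbers

pep = Peptide("GLG")
new_bb = pep.sample_bb_angles(2)
new_chi = pep.sample_chi_angles(2)
print(f"sampled and applied to the leucine: bb={new_bb} chi={new_chi}")
print(f"re-measured: bb={pep.get_bb_angles(2)[:2]} "
      f"chi={pep.get_chi_angles(2)}")

# direct access to the sampler without building a peptide
dbn = TorsionSampler()
chi, bb, ll = dbn.get_sample("L")
print(f"direct leucine draw: chi={chi} bb={bb}")
print(f"log-likelihood of that draw under the mixture model: ll={ll:.4f}")
print("(higher ll = more typical conformation; density is per radian^d)")
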