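import numpy as np
import pytest

from pepbuild import Peptide

#: backbone assignment producing a cap-H...O(res 1) steric clash in WDG,
#: analogous to a too-close hydrogen-bonding pair in a turn conformation
CLASH_BB = {2: (-45.0, -30.0), 3: (-60.0, -15.0)}


@pytest.fixture
def glg():
    return Peptide("GLG")


@pytest.fixture
def clashed_wdg():
    pep = Peptide("WDG")
    for res, (phi, psi) in CLASH_BB.items():
        pep.set_bb_angles(res, [phi, psi])
    return pep


def min_nonbonded_ho_distance(pep):
    """Smallest nonbonded H...O distance (Angstrom) in a peptide."""
    from pepbuild.forcefield import _compiled

    comp = _compiled(pep, None)
    c = pep.coords
    dmin = np.inf
    for p, q in comp.nb_idx:
        elems = {pep.atoms[p].element, pep.atoms[q].element}
        if elems == {"H", "O"}:
            dmin = min(dmin, float(np.linalg.norm(c[p] - c[q])))
    return dmin
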