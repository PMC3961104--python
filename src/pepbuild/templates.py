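"""Idealized residue and cap geometry templates.

Each of the 20 standard amino acids (and each terminal cap) ships as a
plain-text template file under ``pepbuild/data/templates/``.  A template
lists, per atom, the three reference atoms and the internal coordinates
(bond length in Angstrom, bond angle and dihedral offset in degrees) needed
to place it with the NeRF construction, plus the torsion-definition tables
(chi atom quadruples) and per-chi default values.

Reference-atom naming conventions inside a template file:

``N``, ``CA`` ...   atom of the same residue
``-N``, ``-CA`` ... atom of the preceding residue (or the role-equivalent
                    atom of the N-terminal cap, see ``handoff`` lines)
``+N``, ``+CA`` ... atom of the following residue (used by terminal caps
                    that attach atoms to the first/last amino acid)
``.``               no reference (seed atoms at the start of a molecule)

The ``tau_ref`` column names the controllable torsion the dihedral offset
is measured against (``phi``, ``psi``, ``omega``, ``prev_psi``,
``chi1`` ... ``chi5``) or ``abs`` for a fixed offset.

Bond lengths and angles are idealized standard-stereochemistry values
(measured from Chemical Component Dictionary ideal coordinates, with
Engh/Huber-style constants at the inter-residue junction).  Side chains are
modeled in their neutral protonation forms (Asp/Glu protonated, Lys/Arg
neutral amine/guanidine, His as the neutral N-epsilon-2-H tautomer) so that
the total charge of a fragment is determined by its termini alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "TemplateAtom",
    "ResidueTemplate",
    "CapTemplate",
    "get_template",
    "get_cap",
    "AMINO_ACIDS",
    "CODE1_TO_CODE3",
    "CAP_KINDS",
]

#: one-letter -> three-letter codes of the 20 standard amino acids
CODE1_TO_CODE3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
CODE3_TO_CODE1 = {v: k for k, v in CODE1_TO_CODE3.items()}
AMINO_ACIDS = frozenset(CODE1_TO_CODE3)

CAP_KINDS = ("methyl", "charged", "neutral")

#: cap kind/terminus -> template file stem
_CAP_FILES = {
    ("methyl", "N"): "ACE",
    ("methyl", "C"): "NME",
    ("charged", "N"): "NCAP_CHARGED",
    ("neutral", "N"): "NCAP_NEUTRAL",
    ("charged", "C"): "CCAP_CHARGED",
    ("neutral", "C"): "CCAP_NEUTRAL",
}


class TemplateError(ValueError):
    """Raised for unknown residue codes or cap kinds."""


@dataclass(frozen=True)
class TemplateAtom:
    """One atom of a template with its NeRF internal coordinates."""

    name: str
    element: str
    refs: tuple[str, str, str]  # (a, b, c); c is the bonded parent
    bond_length: float          # Angstrom
    bond_angle: float           # degrees, angle(b, c, self)
    dihedral_offset: float      # degrees, relative to tau_ref
    tau_ref: str                # "abs", "phi", "psi", "omega", "prev_psi", "chiN"

    def __post_init__(self):
        if self.refs[2] != "." and not self.bond_length > 0:
            raise TemplateError(
                f"atom {self.name}: bond length must be positive"
            )
        if self.refs[2] != "." and not 0.0 < self.bond_angle < 180.0:
            raise TemplateError(
                f"atom {self.name}: bond angle must lie in (0, 180)"
            )


@dataclass(frozen=True)
class ResidueTemplate:
    """Idealized geometry and torsion definitions for one residue type."""

    code3: str
    code1: str
    atoms: tuple[TemplateAtom, ...]
    chi_defs: tuple[tuple[str, str, str, str], ...]
    default_chi: tuple[float, ...]
    closures: tuple[tuple[str, str], ...] = field(default=())

    @property
    def n_chi(self) -> int:
        return len(self.chi_defs)

    def atom(self, name: str) -> TemplateAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.atoms)


@dataclass(frozen=True)
class CapTemplate:
    """Terminal cap: methyl (ACE/NME) or charged/neutral termini."""

    kind: str       # methyl | charged | neutral
    terminus: str   # N | C
    resname: str    # residue name used in PDB output (ACE/NME) or ""
    atoms: tuple[TemplateAtom, ...]
    #: role mapping exposed to the following residue: template ref name
    #: ("-N"/"-CA"/"-C") -> cap atom name
    handoff: dict[str, str] = field(default_factory=dict)
    #: value substituted for the ``prev_psi`` torsion of the next residue
    handoff_psi: float = 180.0


def _data_text(fname: str) -> str:
    return (
        resources.files("pepbuild.data.templates").joinpath(fname).read_text()
    )


def _parse_atoms(lines):
    atoms, chi_defs, default_chi, closures, header = [], [], [], [], None
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0]
        if key in ("residue", "cap"):
            header = parts
        elif key == "atom":
            name, element, a, b, c = parts[1:6]
            r, theta, tau = (float(x) for x in parts[6:9])
            atoms.append(
                TemplateAtom(name, element, (a, b, c), r, theta, tau, parts[9])
            )
        elif key == "chi":
            chi_defs.append(tuple(parts[2:6]))
        elif key == "defchi":
            default_chi = [float(x) for x in parts[1:]]
        elif key == "closure":
            closures.append((parts[1], parts[2]))
        elif key in ("handoff", "handoff_psi"):
            pass  # consumed by the cap loader
        else:
            raise TemplateError(f"unrecognized template line: {raw!r}")
    return header, atoms, chi_defs, default_chi, closures


def get_template(code: str) -> ResidueTemplate:
    """Return the immutable template for a one-letter amino-acid code."""
    return _get_template(str(code).upper())


@lru_cache(maxsize=None)
def _get_template(code: str) -> ResidueTemplate:
    if code not in CODE1_TO_CODE3:
        raise TemplateError(
            f"unknown amino-acid code {code!r}; expected one of the 20 "
            "standard one-letter codes"
        )
    code3 = CODE1_TO_CODE3[code]
    text = _data_text(f"{code3}.tmpl")
    header, atoms, chi_defs, default_chi, closures = _parse_atoms(
        text.splitlines()
    )
    tmpl = ResidueTemplate(
        code3=code3,
        code1=code,
        atoms=tuple(atoms),
        chi_defs=tuple(chi_defs),
        default_chi=tuple(default_chi),
        closures=tuple(closures),
    )
    if len(tmpl.default_chi) != tmpl.n_chi:
        raise TemplateError(f"{code3}: default_chi/chi_defs length mismatch")
    names = set(tmpl.atom_names)
    for quad in tmpl.chi_defs:
        for nm in quad:
            if nm not in names:
                raise TemplateError(f"{code3}: chi atom {nm} not in template")
    return tmpl


@lru_cache(maxsize=None)
def get_cap(kind: str, terminus: str) -> CapTemplate:
    """Return the cap template for ``kind`` in {methyl, charged, neutral}."""
    kind = str(kind).lower()
    terminus = str(terminus).upper()
    if kind not in CAP_KINDS:
        raise TemplateError(
            f"unknown cap kind {kind!r}; expected one of {CAP_KINDS}"
        )
    if terminus not in ("N", "C"):
        raise TemplateError(f"terminus must be 'N' or 'C', got {terminus!r}")
    stem = _CAP_FILES[(kind, terminus)]
    text = _data_text(f"{stem}.tmpl")
    _, atoms, _, _, _ = _parse_atoms(text.splitlines())
    handoff, handoff_psi, resname = {}, 180.0, ""
    for raw in text.splitlines():
        parts = raw.split("#", 1)[0].split()
        if not parts:
            continue
        if parts[0] == "cap":
            resname = parts[3] if len(parts) > 3 else ""
        elif parts[0] == "handoff":
            handoff[parts[1]] = parts[2]
        elif parts[0] == "handoff_psi":
            handoff_psi = float(parts[1])
    return CapTemplate(
        kind=kind,
        terminus=terminus,
        resname=resname,
        atoms=tuple(atoms),
        handoff=handoff,
        handoff_psi=handoff_psi,
    )
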