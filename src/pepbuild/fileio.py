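"""Structure file I/O: PDB reading/writing, XYZ output, QM input decks.

PDB output follows the v3.3 fixed-column ATOM record layout.  Methyl caps
are written as their standard residue names (ACE before residue 1, NME
after residue n); charged and neutral termini are written as extra atoms
of the first/last amino-acid residue, as is standard PDB practice
(H1/H2/H3 on N, OXT/HXT on C).

Reading goes through gemmi: the first model is used, alternative
conformations are collapsed to the preferred altloc, and residues are
indexed 1-based over amino acids in order of appearance.  Torsions are
measured from the file coordinates with the same atom quadruples as the
in-memory peptide; an angle whose defining atoms are absent (chain
termini, incomplete side chains) is reported as ``None``, never guessed.

QM input decks are written for a Gaussian-style ``.com`` layout (route
line, title, charge/multiplicity, Cartesian block) and a minimal
GAMESS-style ``.inp`` ($CONTRL/$DATA groups, C1 symmetry).  When no method
is specified the writers default to the PM6 semi-empirical method.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import dihedral
from .templates import CODE3_TO_CODE1, get_template

__all__ = [
    "PdbModel",
    "QmJobSpec",
    "read_pdb",
    "pdb_get_bb_angles",
    "pdb_get_chi_angles",
    "pdb_get_resname",
    "write_pdb",
    "write_xyz",
    "write_qm_input",
    "write_file",
]


class FileIOError(ValueError):
    """Raised for unreadable files or unsupported formats."""


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------
def _pdb_atom_name(name: str, element: str) -> str:
    """Format an atom name into PDB columns 13-16."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _pdb_records(pep):
    """Yield (serial, name, element, resname, resseq, xyz) per atom."""
    n = pep.n_residues
    merge_n = pep.nterm_cap.kind != "methyl"
    merge_c = pep.cterm_cap.kind != "methyl"
    for atom, pos in zip(pep.atoms, pep.coords):
        res = atom.res_index
        if res == 0:
            resname = pep.residues[0].code3 if merge_n else "ACE"
            resseq = 1 if merge_n else 0
        elif res == n + 1:
            resname = pep.residues[-1].code3 if merge_c else "NME"
            resseq = n if merge_c else n + 1
        else:
            resname = pep.residues[res - 1].code3
            resseq = res
        yield atom.serial, atom.name, atom.element, resname, resseq, pos


def write_pdb(pep, path) -> None:
    """Write the peptide as fixed-width PDB v3.3 ATOM records."""
    lines = []
    last = None
    for serial, name, element, resname, resseq, pos in _pdb_records(pep):
        lines.append(
            f"ATOM  {serial:>5} {_pdb_atom_name(name, element)} "
            f"{resname:>3} A{resseq:>4}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2}"
        )
        last = (serial, resname, resseq)
    lines.append(
        f"TER   {last[0] + 1:>5}      {last[1]:>3} A{last[2]:>4}"
    )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(pep, path) -> None:
    """Write XYZ: atom count, a sequence comment, then element x y z."""
    lines = [str(pep.n_atoms), f"pepbuild peptide sequence={pep.sequence}"]
    for atom, pos in zip(pep.atoms, pep.coords):
        lines.append(
            f"{atom.element:<2} {pos[0]:14.8f} {pos[1]:14.8f} {pos[2]:14.8f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class QmJobSpec:
    """Specification of a quantum-chemistry job for the deck writers."""

    job_kind: str = "opt"            # opt | energy | nmr
    method: str | None = None        # e.g. "B3LYP/6-31G(d)"; None -> PM6
    charge: int | None = None        # None -> derived from the cap kinds
    multiplicity: int = 1
    title: str = "pepbuild generated structure"
    header_options: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.job_kind not in ("opt", "energy", "nmr"):
            raise FileIOError(
                f"job_kind must be opt, energy or nmr, got {self.job_kind!r}"
            )
        if self.multiplicity < 1:
            raise FileIOError("multiplicity must be >= 1")

    @property
    def method_string(self) -> str:
        return self.method or "PM6"


def fragment_charge(pep) -> int:
    """Total charge from the cap kinds (+1 charged N-term, -1 charged C-term)."""
    q = 0
    if pep.nterm_cap.kind == "charged":
        q += 1
    if pep.cterm_cap.kind == "charged":
        q -= 1
    return q


_GAUSSIAN_JOB_KW = {"opt": "opt", "energy": "", "nmr": "NMR=GIAO"}
_GAMESS_RUNTYP = {"opt": "OPTIMIZE", "energy": "ENERGY", "nmr": "NMR"}

#: nuclear charges for the GAMESS $DATA block
_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}


def write_qm_input(pep, spec: QmJobSpec | None = None,
                   dialect: str = "gaussian", path="job.com") -> None:
    """Write a QM input deck for the peptide's current coordinates."""
    spec = spec or QmJobSpec()
    charge = spec.charge if spec.charge is not None else fragment_charge(pep)
    if dialect == "gaussian":
        kw = _GAUSSIAN_JOB_KW[spec.job_kind]
        route = f"# {spec.method_string}" + (f" {kw}" if kw else "")
        lines = list(spec.header_options)
        lines += [route, "", spec.title, "", f"{charge} {spec.multiplicity}"]
        for atom, pos in zip(pep.atoms, pep.coords):
            lines.append(
                f"{atom.element:<2} {pos[0]:14.8f} {pos[1]:14.8f} "
                f"{pos[2]:14.8f}"
            )
        lines.append("")
    elif dialect == "gamess":
        lines = [
            f" $CONTRL SCFTYP=RHF RUNTYP={_GAMESS_RUNTYP[spec.job_kind]}"
            f" ICHARG={charge} MULT={spec.multiplicity} $END",
            " $DATA",
            spec.title,
            "C1",
        ]
        for atom, pos in zip(pep.atoms, pep.coords):
            z = _Z.get(atom.element)
            if z is None:
                raise FileIOError(f"no nuclear charge for {atom.element}")
            lines.append(
                f"{atom.element:<2} {z:4.1f} {pos[0]:14.8f} "
                f"{pos[1]:14.8f} {pos[2]:14.8f}"
            )
        lines.append(" $END")
    else:
        raise FileIOError(
            f"unknown dialect {dialect!r}; expected 'gaussian' or 'gamess'"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_file(pep, filetype: str, path) -> None:
    """Write the structure in a named format.

    XYZ, PDB, Gaussian (``com``) and GAMESS (``inp``/``gamin``) are written
    natively; any other format string is handed to the ``obabel``
    conversion tool when it is installed.
    """
    ft = filetype.lower()
    if ft == "xyz":
        write_xyz(pep, path)
    elif ft == "pdb":
        write_pdb(pep, path)
    elif ft in ("com", "gaussian", "gjf"):
        write_qm_input(pep, None, "gaussian", path)
    elif ft in ("inp", "gamin", "gamess"):
        write_qm_input(pep, None, "gamess", path)
    elif shutil.which("obabel"):
        import tempfile

        with tempfile.NamedTemporaryFile(suffix=".xyz", mode="w",
                                         delete=False) as tmp:
            tmp_path = tmp.name
        try:
            write_xyz(pep, tmp_path)
            proc = subprocess.run(
                ["obabel", tmp_path, f"-o{ft}", "-O", str(path)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0 or not Path(path).exists():
                raise FileIOError(
                    f"obabel conversion to {filetype!r} failed: "
                    f"{proc.stderr.strip()}"
                )
        finally:
            Path(tmp_path).unlink(missing_ok=True)
    else:
        raise FileIOError(
            f"unsupported format {filetype!r} and no conversion backend"
        )


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------
class PdbModel:
    """Torsion-oriented view of one chain of a PDB file.

    Residues are indexed 1-based over amino acids in order of appearance;
    ACE/NME cap residues are kept aside and used only as flanking atoms
    for the terminal torsions.
    """

    def __init__(self, path, chain: str | None = None):
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError, OSError) as exc:
            raise FileIOError(f"cannot read PDB file {path}: {exc}") from exc
        st.remove_alternative_conformations()
        if len(st) == 0:
            raise FileIOError(f"{path}: no models")
        model = st[0]
        if chain is None:
            if len(model) == 0:
                raise FileIOError(f"{path}: no chains")
            ch = model[0]
        else:
            ch = model[chain]
            if ch is None:
                raise FileIOError(f"{path}: no chain {chain!r}")
        self.source = str(path)
        self.chain_id = ch.name
        self._records = []          # all residues incl. caps, in order
        for residue in ch:
            atoms = {
                a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                for a in residue
            }
            self._records.append((residue.name, residue.seqid.num, atoms))
        self._aa = [
            i for i, (name, _, _) in enumerate(self._records)
            if name in CODE3_TO_CODE1
        ]
        if not self._aa:
            raise FileIOError(f"{path}: no amino acid residues")

    # -- bookkeeping ----------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self._aa)

    def __len__(self) -> int:
        return self.n_residues

    def _rec(self, res: int):
        if not 1 <= res <= self.n_residues:
            raise FileIOError(
                f"residue index {res} out of range 1..{self.n_residues}"
            )
        return self._records[self._aa[res - 1]]

    def _flank(self, res: int, direction: int):
        """Record physically adjacent to amino acid ``res`` (may be a cap)."""
        pos = self._aa[res - 1] + direction
        if 0 <= pos < len(self._records):
            return self._records[pos]
        return None

    def get_sequence(self) -> str:
        return "".join(
            CODE3_TO_CODE1[self._records[i][0]] for i in self._aa
        )

    def get_resname(self, res: int) -> str:
        return self._rec(res)[0]

    # -- torsions -------------------------------------------------------
    @staticmethod
    def _pick(record, *names):
        if record is None:
            return None
        _, _, atoms = record
        for nm in names:
            if nm in atoms:
                return atoms[nm]
        return None

    def get_bb_angles(self, res: int):
        """[phi, psi, omega] measured from file coordinates; None if undefined."""
        rec = self._rec(res)
        prev_rec = self._flank(res, -1)
        next_rec = self._flank(res, +1)
        atoms = rec[2]
        n = atoms.get("N")
        ca = atoms.get("CA")
        c = atoms.get("C")
        prev_c = self._pick(prev_rec, "C")
        prev_ca = self._pick(prev_rec, "CA", "CH3")
        next_n = self._pick(next_rec, "N")
        out = []
        for quad in (
            (prev_c, n, ca, c),
            (n, ca, c, next_n),
            (prev_ca, prev_c, n, ca),
        ):
            if any(p is None for p in quad):
                out.append(None)
            else:
                out.append(dihedral(*quad))
        return out

    def get_chi_angles(self, res: int):
        """Chi angles measured from file coordinates; None where atoms miss."""
        rec = self._rec(res)
        name, _, atoms = rec
        code1 = CODE3_TO_CODE1[name]
        tmpl = get_template(code1)
        out = []
        for quad in tmpl.chi_defs:
            pts = [atoms.get(nm) for nm in quad]
            out.append(None if any(p is None for p in pts)
                       else dihedral(*pts))
        return out


def read_pdb(path, chain: str | None = None) -> PdbModel:
    """Parse a PDB file into a :class:`PdbModel` (first model, one chain)."""
    return PdbModel(path, chain=chain)


def pdb_get_bb_angles(model: PdbModel, res: int):
    return model.get_bb_angles(res)


def pdb_get_chi_angles(model: PdbModel, res: int):
    return model.get_chi_angles(res)


def pdb_get_resname(model: PdbModel, res: int) -> str:
    return model.get_resname(res)
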