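"""Capped peptide assembly and torsion manipulation.

A :class:`Peptide` is built residue by residue from internal-coordinate
templates: every atom is placed with the NeRF construction from three
previously placed reference atoms, so the molecule is born with exactly the
requested backbone torsions (phi = -120, psi = 140, omega = -180 by
default, a typical extended beta strand) and side chains at their template
default chi values.

Torsion conventions (atom quadruples):

* phi(i)   = C(i-1) - N(i) - CA(i) - C(i)
* psi(i)   = N(i) - CA(i) - C(i) - N(i+1)
* omega(i) = CA(i-1) - C(i-1) - N(i) - CA(i), i.e. the peptide bond
  *preceding* residue i.  ``set_bb_angles(i, [phi, psi, omega])`` therefore
  controls the omega on the N-terminal side of residue i.
* chi_k    = the standard IUPAC side-chain quadruples stored per template.

For terminal residues the heavy atoms of a methyl cap stand in for the
missing neighbour residue (the acetyl C plays C(0), the N-methylamide N
plays N(n+1)).  With charged or neutral termini no such atom exists and the
corresponding torsion is undefined: it is reported as ``None`` and cannot
be set.

The residue index is 1-based over amino acids; the N-terminal cap is
residue index 0 and the C-terminal cap index n+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import templates as tpl
from .geometry import (
    GeometryError,
    dihedral,
    place_atom,
    rotate_branch,
    wrap_angle,
)

__all__ = ["Atom", "Peptide", "PeptideError", "BB_DEFAULTS"]

#: default backbone torsions of a freshly built peptide (degrees)
BB_DEFAULTS = {"phi": -120.0, "psi": 140.0, "omega": -180.0}

_MEASURE_TOL = 1e-9


class PeptideError(ValueError):
    """Raised for invalid sequences, residue indices or torsion requests."""


@dataclass
class Atom:
    """One atom of an assembled peptide."""

    serial: int       # 1-based, contiguous
    name: str         # PDB-style atom name
    element: str
    res_index: int    # 0 = N-cap, 1..n = residues, n+1 = C-cap

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Atom({self.serial}, {self.name}, res={self.res_index})"


class _Torsion:
    """Bookkeeping record for one named torsion of the molecule."""

    __slots__ = ("key", "quad", "target", "rotatable")

    def __init__(self, key, quad, target, rotatable=True):
        self.key = key            # (res_index, name)
        self.quad = quad          # 4-tuple of 0-based atom indices
        self.target = target      # degrees, canonical range
        self.rotatable = rotatable


class Peptide:
    """A capped peptide with controllable backbone and side-chain torsions.

    Parameters
    ----------
    sequence:
        One-letter amino-acid sequence (case-insensitive).
    nterm, cterm:
        Cap kinds: ``"methyl"`` (default; acetyl / N-methylamide),
        ``"charged"`` (NH3+ / COO-) or ``"neutral"`` (NH2 / COOH).

    Examples
    --------
    >>> pep = Peptide("GLG")
    >>> pep.set_bb_angles(2, [-60.0, -30.0])
    >>> pep.set_chi_angles(2, [180.0, 60.0])
    >>> [round(x, 6) for x in pep.get_bb_angles(2)]
    [-60.0, -30.0, -180.0]
    """

    def __init__(self, sequence: str, nterm: str = "methyl",
                 cterm: str = "methyl"):
        seq = str(sequence)
        if not seq:
            raise PeptideError("sequence must not be empty")
        for pos, letter in enumerate(seq, start=1):
            if letter.upper() not in tpl.AMINO_ACIDS:
                raise PeptideError(
                    f"invalid amino-acid letter {letter!r} at position {pos}"
                )
        self.sequence = seq.upper()
        self.nterm_cap = tpl.get_cap(nterm, "N")
        self.cterm_cap = tpl.get_cap(cterm, "C")
        self.residues = [tpl.get_template(c) for c in self.sequence]

        self.atoms: list[Atom] = []
        self.coords = np.zeros((0, 3))
        self._index: dict[tuple[int, str], int] = {}
        self._parent: list[int] = []
        self._closures: list[tuple[int, int]] = []
        self._torsions: dict[tuple[int, str], _Torsion] = {}

        self._build()
        self._register_torsions()

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return self.n_residues

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _default_target(self, res: int, name: str) -> float:
        if name.startswith("chi"):
            k = int(name[3:])
            return self.residues[res - 1].default_chi[k - 1]
        return BB_DEFAULTS[name]

    def _placement_tau(self, res: int, ta: tpl.TemplateAtom) -> float:
        """Dihedral value to hand to the NeRF placement of one atom."""
        ref = ta.tau_ref
        if ref == "abs":
            return ta.dihedral_offset
        if ref == "prev_psi":
            if res <= 1:
                base = self.nterm_cap.handoff_psi
            else:
                base = self._default_target(res - 1, "psi")
            return wrap_angle(ta.dihedral_offset + base)
        if ref in ("phi", "psi", "omega") or ref.startswith("chi"):
            # a cap's own omega is keyed under index n+1
            r = res if res >= 1 else self.n_residues + 1
            return wrap_angle(ta.dihedral_offset + self._default_target_cap(r, ref))
        raise tpl.TemplateError(f"unknown torsion reference {ref!r}")

    def _default_target_cap(self, res: int, name: str) -> float:
        if res == self.n_residues + 1:
            return BB_DEFAULTS[name]
        return self._default_target(res, name)

    def _resolve_ref(self, res: int, name: str):
        """Map a template reference name to an atom index, or None."""
        if name == ".":
            return None
        if name.startswith("-"):
            base = name[1:]
            if res == 1 or (res == self.n_residues + 1 and self.n_residues == 0):
                mapped = self.nterm_cap.handoff.get(name)
                return self._index.get((0, mapped)) if mapped else None
            if res == self.n_residues + 1:
                return self._index.get((self.n_residues, base))
            return self._index.get((res - 1, base))
        if name.startswith("+"):
            return self._index.get((1, name[1:]))
        return self._index.get((res, name))

    def _place(self, res: int, ta: tpl.TemplateAtom) -> None:
        idx = len(self.atoms)
        refs = [self._resolve_ref(res, nm) for nm in ta.refs]
        a, b, c = refs
        if c is None or b is None or a is None:
            # seed placement: only legal while starting the molecule
            if idx == 0:
                pos = np.zeros(3)
                parent = -1
            elif idx == 1:
                if c is None:
                    raise tpl.TemplateError(
                        f"atom {ta.name}: second seed atom needs a parent"
                    )
                pos = self.coords[c] + np.array([ta.bond_length, 0.0, 0.0])
                parent = c
            elif idx == 2 and c is not None and b is not None:
                virtual_a = self.coords[b] + np.array([0.0, 0.0, 1.0])
                pos = place_atom(
                    virtual_a, self.coords[b], self.coords[c],
                    ta.bond_length, ta.bond_angle, 90.0,
                )
                parent = c
            else:
                raise tpl.TemplateError(
                    f"atom {ta.name} of residue {res}: unresolvable "
                    f"reference atoms {ta.refs}"
                )
        else:
            tau = self._placement_tau(res, ta)
            pos = place_atom(
                self.coords[a], self.coords[b], self.coords[c],
                ta.bond_length, ta.bond_angle, tau,
            )
            parent = c
        self.atoms.append(Atom(idx + 1, ta.name, ta.element, res))
        self.coords = np.vstack([self.coords, pos[None, :]])
        self._parent.append(parent)
        self._index[(res, ta.name)] = idx

    def _build(self) -> None:
        n = self.n_residues
        ncap, ccap = self.nterm_cap, self.cterm_cap
        if ncap.kind == "methyl":
            for ta in ncap.atoms:
                self._place(0, ta)
        for i, res_tpl in enumerate(self.residues, start=1):
            skip_h = i == 1 and ncap.kind != "methyl"
            for ta in res_tpl.atoms:
                if skip_h and ta.name == "H":
                    continue
                self._place(i, ta)
            if i == 1 and ncap.kind != "methyl":
                # cap protons hang off N(1); their c-reference is +N
                for ta in ncap.atoms:
                    self._place(0, ta)
            for u, v in res_tpl.closures:
                self._closures.append(
                    (self._index[(i, u)], self._index[(i, v)])
                )
        for ta in ccap.atoms:
            self._place(n + 1, ta)
        if ccap.kind != "methyl":
            # OXT (and HXT) belong to the bond graph of residue n's C
            pass

    # ------------------------------------------------------------------
    # torsion registry
    # ------------------------------------------------------------------
    def _atom_idx(self, res: int, name: str):
        return self._index.get((res, name))

    def _register(self, key, quad, rotatable=True):
        if any(q is None for q in quad):
            return
        res, name = key
        target = self._default_target_cap(res, name)
        self._torsions[key] = _Torsion(key, tuple(quad), target, rotatable)

    def _register_torsions(self) -> None:
        n = self.n_residues
        ace = self.nterm_cap.kind == "methyl"
        nme = self.cterm_cap.kind == "methyl"
        for i, res_tpl in enumerate(self.residues, start=1):
            prev_c = self._atom_idx(i - 1, "C") if i > 1 else (
                self._atom_idx(0, "C") if ace else None
            )
            prev_ca = self._atom_idx(i - 1, "CA") if i > 1 else (
                self._atom_idx(0, "CH3") if ace else None
            )
            next_n = self._atom_idx(i + 1, "N") if i < n else (
                self._atom_idx(n + 1, "N") if nme else None
            )
            ni, cai, ci = (self._atom_idx(i, nm) for nm in ("N", "CA", "C"))
            self._register(
                (i, "phi"), (prev_c, ni, cai, ci),
                rotatable=res_tpl.code3 != "PRO",
            )
            self._register((i, "psi"), (ni, cai, ci, next_n))
            self._register((i, "omega"), (prev_ca, prev_c, ni, cai))
            for k, quad in enumerate(res_tpl.chi_defs, start=1):
                self._register(
                    (i, f"chi{k}"),
                    tuple(self._atom_idx(i, nm) for nm in quad),
                )
        if nme:
            self._register(
                (n + 1, "omega"),
                (
                    self._atom_idx(n, "CA"), self._atom_idx(n, "C"),
                    self._atom_idx(n + 1, "N"), self._atom_idx(n + 1, "CH3"),
                ),
            )
        # proline phi is frozen by the ring: pin the target to the built value
        for t in self._torsions.values():
            if not t.rotatable:
                t.target = self.measure(*t.key)

    # ------------------------------------------------------------------
    # connectivity
    # ------------------------------------------------------------------
    def bonds(self):
        """All covalent bonds as 0-based index pairs (tree + ring closures)."""
        out = [
            (p, i) for i, p in enumerate(self._parent) if p >= 0
        ]
        out.extend(self._closures)
        return out

    def _descendants(self, root: int) -> set[int]:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self._parent):
            if p >= 0:
                children.setdefault(p, []).append(i)
        out: set[int] = set()
        stack = list(children.get(root, []))
        while stack:
            k = stack.pop()
            out.add(k)
            stack.extend(children.get(k, []))
        return out

    # ------------------------------------------------------------------
    # measurement and assignment
    # ------------------------------------------------------------------
    def _check_res(self, res: int) -> None:
        if not 1 <= res <= self.n_residues:
            raise PeptideError(
                f"residue index {res} out of range 1..{self.n_residues}"
            )

    def measure(self, res: int, name: str):
        """Measured torsion in degrees, or None when undefined."""
        t = self._torsions.get((res, name))
        if t is None:
            return None
        return dihedral(*(self.coords[q] for q in t.quad))

    def torsion_keys(self):
        """Keys of every registered torsion, in build order."""
        return list(self._torsions)

    def torsion_targets(self):
        """Mapping of torsion key -> stored target value (degrees)."""
        return {k: t.target for k, t in self._torsions.items()}

    def _set_torsion(self, res: int, name: str, value: float) -> None:
        t = self._torsions.get((res, name))
        value = wrap_angle(value)
        if t is None:
            raise PeptideError(
                f"torsion {name} of residue {res} is undefined for this "
                "cap style"
            )
        current = self.measure(res, name)
        if not t.rotatable:
            if abs(wrap_angle(value - current)) > 1e-6:
                raise PeptideError(
                    f"torsion {name} of residue {res} is fixed by the "
                    "proline ring and cannot be rotated"
                )
            return
        branch = self._descendants(t.quad[2])
        moving = branch | {t.quad[2]}
        for u, v in self._closures:
            if (u in moving) != (v in moving):
                raise PeptideError(
                    f"torsion {name} of residue {res} crosses a ring closure"
                )
        delta = wrap_angle(value - current)
        self.coords = rotate_branch(
            self.coords, t.quad[1], t.quad[2], branch, delta
        )
        t.target = value

    def set_bb_angles(self, res: int, angles) -> None:
        """Set [phi, psi] or [phi, psi, omega] of residue ``res`` (degrees)."""
        self._check_res(res)
        angles = list(angles)
        if len(angles) not in (2, 3):
            raise PeptideError(
                "set_bb_angles expects [phi, psi] or [phi, psi, omega], "
                f"got {len(angles)} values"
            )
        names = ("phi", "psi", "omega")[: len(angles)]
        for name, value in zip(names, angles):
            self._set_torsion(res, name, float(value))

    def set_chi_angles(self, res: int, angles) -> None:
        """Set the side-chain chi angles of residue ``res`` (degrees)."""
        self._check_res(res)
        angles = list(angles)
        n_chi = self.residues[res - 1].n_chi
        if len(angles) != n_chi:
            raise PeptideError(
                f"residue {res} ({self.residues[res - 1].code3}) has "
                f"{n_chi} controllable chi angle(s), got {len(angles)}"
            )
        for k, value in enumerate(angles, start=1):
            self._set_torsion(res, f"chi{k}", float(value))

    def get_bb_angles(self, res: int):
        """Measured [phi, psi, omega] of residue ``res``; None if undefined."""
        self._check_res(res)
        return [self.measure(res, nm) for nm in ("phi", "psi", "omega")]

    def get_chi_angles(self, res: int):
        """Measured chi angles of residue ``res`` (may be empty)."""
        self._check_res(res)
        n_chi = self.residues[res - 1].n_chi
        return [self.measure(res, f"chi{k}") for k in range(1, n_chi + 1)]

    def get_resname(self, res: int) -> str:
        """Three-letter residue name at 1-based index ``res``."""
        self._check_res(res)
        return self.residues[res - 1].code3

    # ------------------------------------------------------------------
    # sampling and optimization conveniences (delegate to sibling modules)
    # ------------------------------------------------------------------
    def sample_bb_angles(self, res: int, state=None):
        """Sample, apply and return backbone (phi, psi) for residue ``res``."""
        from . import sampling

        return sampling.sample_bb_angles(self, res, state)

    def sample_chi_angles(self, res: int, state=None, bb_dependent=True):
        """Sample, apply and return the chi angles for residue ``res``."""
        from . import sampling

        return sampling.sample_chi_angles(
            self, res, state, bb_dependent=bb_dependent
        )

    def get_energy(self, model=None) -> float:
        """Force-field energy (kcal/mol) of the current coordinates."""
        from . import forcefield

        return forcefield.energy(self, model)

    def optimize(self, constraint: bool = False, max_steps: int = 500,
                 tol: float = 1e-6, model=None, **kw):
        """Conjugate-gradient minimization; see :func:`pepbuild.forcefield.optimize`."""
        from . import forcefield

        return forcefield.optimize(
            self, model=model, constraint=constraint,
            max_steps=max_steps, tol=tol, **kw
        )

    def regularize(self, cycles: int = 10, steps_per_cycle: int = 50,
                   model=None, **kw):
        """Constrained-optimize / torsion-reset cycling; see :func:`pepbuild.forcefield.regularize`."""
        from . import forcefield

        return forcefield.regularize(
            self, model=model, cycles=cycles,
            steps_per_cycle=steps_per_cycle, **kw
        )

    def reset_torsions(self) -> None:
        """Rigidly rotate every rotatable torsion back to its stored target."""
        for key, t in self._torsions.items():
            if t.rotatable:
                self._set_torsion(key[0], key[1], t.target)

    def refresh_targets(self) -> None:
        """Overwrite stored torsion targets with the measured values."""
        for key, t in self._torsions.items():
            t.target = self.measure(*key)

    def max_torsion_deviation(self) -> float:
        """Largest wrapped |measured - target| over rotatable torsions (deg)."""
        devs = [
            abs(wrap_angle(self.measure(*k) - t.target))
            for k, t in self._torsions.items()
            if t.rotatable
        ]
        return max(devs) if devs else 0.0

    # ------------------------------------------------------------------
    # output conveniences
    # ------------------------------------------------------------------
    def write_pdb(self, path) -> None:
        from . import fileio

        fileio.write_pdb(self, path)

    def write_xyz(self, path) -> None:
        from . import fileio

        fileio.write_xyz(self, path)

    def chirality(self, res: int):
        """'L' or 'D' at the CA of residue ``res``; None for glycine."""
        self._check_res(res)
        idx = {
            nm: self._atom_idx(res, nm) for nm in ("N", "C", "CB", "HA")
        }
        if idx["CB"] is None or idx["HA"] is None:
            return None
        pn, pc, pcb, pha = (self.coords[idx[nm]] for nm in ("N", "C", "CB", "HA"))
        vol = np.dot(pc - pn, np.cross(pcb - pn, pha - pn))
        return "L" if vol < 0 else "D"

    def __repr__(self):  # pragma: no cover
        return (
            f"Peptide({self.sequence!r}, nterm={self.nterm_cap.kind!r}, "
            f"cterm={self.cterm_cap.kind!r}, atoms={self.n_atoms})"
        )
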