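"""Simplified molecular-mechanics energy, CG minimization and regularization.

The shipped energy model is a deliberately small bonded + repulsive force
field whose reference bond lengths and angles are the template values the
peptide was built with:

* harmonic bonds      ``k_b (r - r0)^2``
* harmonic angles     ``k_a (theta - theta0)^2``   (radians)
* 3-fold torsions     ``(V3 / 2) (1 + cos 3 tau)`` over every proper quadruple
* nonbonded repulsion ``eps (sigma_ij / r)^12`` with Bondi-radius sigma,
  1-2 and 1-3 pairs excluded and 1-4 pairs scaled by 0.5.

It is not MMFF94 and makes no claim to quantitative energies; its job is to
relieve steric clashes while harmonic torsion restraints (and the exact
angle resets of :func:`regularize`) preserve the requested conformation.
The energy backend is pluggable: any object implementing
``energy_gradient(coords) -> (E, grad)`` after compilation against a
peptide can be substituted.

Units: kcal/mol, Angstrom, degrees at the interface (radians internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral_gradient, dihedral_gradient_batch, wrap_angle

__all__ = [
    "EnergyModel",
    "TorsionRestraint",
    "OptimizationResult",
    "energy",
    "energy_components",
    "gradient",
    "optimize",
    "regularize",
]

#: Bondi van der Waals radii (Angstrom)
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: default harmonic restraint constant for constrained optimization
K_RESTRAINT = 100.0           # kcal mol^-1 rad^-2
#: stiffer constant used inside regularization cycles, where the goal is
#: self-consistency of the restrained minimum with the exact targets
K_REGULARIZE = 1.0e6          # kcal mol^-1 rad^-2


class ForceFieldError(RuntimeError):
    """Raised for degenerate geometries the energy model cannot score."""


@dataclass(frozen=True)
class EnergyModel:
    """Parameter set of the simplified bonded + repulsion force field."""

    k_bond: float = 300.0     # kcal mol^-1 A^-2
    k_angle: float = 80.0     # kcal mol^-1 rad^-2
    v3: float = 0.05          # kcal mol^-1, 3-fold torsion amplitude
    eps_rep: float = 0.10     # kcal mol^-1, repulsion prefactor
    sigma_scale: float = 0.85  # scales the Bondi radius sum into sigma_ij
    scale_14: float = 0.5
    identifier: str = "pepbuild-bonded-repulsion-1"


@dataclass(frozen=True)
class TorsionRestraint:
    """Harmonic restraint ``k (delta_rad)^2`` on one torsion quadruple."""

    quad: tuple[int, int, int, int]
    target: float             # degrees
    k_restraint: float = K_RESTRAINT

    def energy_gradient(self, coords):
        phi, dphi = dihedral_gradient(*(coords[q] for q in self.quad))
        delta = np.radians(wrap_angle(np.degrees(phi) - self.target))
        e = self.k_restraint * delta * delta
        g = np.zeros_like(coords)
        coef = 2.0 * self.k_restraint * delta
        for q, gq in zip(self.quad, dphi):
            g[q] += coef * gq
        return e, g


@dataclass
class OptimizationResult:
    """Outcome of a minimization or regularization run."""

    final_energy: float            # kcal/mol, restraints excluded
    steps: int
    converged: bool
    delta_E_last: float            # kcal/mol, last accepted energy decrease
    max_torsion_deviation: float   # degrees vs stored targets
    restraint_energy: float = 0.0

    def __repr__(self):  # pragma: no cover
        return (
            f"OptimizationResult(E={self.final_energy:.6f} kcal/mol, "
            f"steps={self.steps}, converged={self.converged}, "
            f"max_dev={self.max_torsion_deviation:.3e} deg)"
        )


class _CompiledFF:
    """Force-field terms compiled against one peptide's topology.

    Reference bond lengths and angles are taken from the geometry the
    peptide was built with (torsion rotations leave them untouched, so
    compiling lazily before the first energy call is equivalent to
    compiling at construction).
    """

    def __init__(self, pep, model: EnergyModel):
        self.model = model
        coords = pep.coords
        bonds = pep.bonds()
        n = len(coords)
        nbrs = [[] for _ in range(n)]
        for i, j in bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)

        self.b_idx = np.array(bonds, dtype=int).reshape(-1, 2)
        self.b_ref = np.linalg.norm(
            coords[self.b_idx[:, 0]] - coords[self.b_idx[:, 1]], axis=1
        )

        angles = []
        for j in range(n):
            adj = sorted(nbrs[j])
            for x in range(len(adj)):
                for y in range(x + 1, len(adj)):
                    angles.append((adj[x], j, adj[y]))
        self.a_idx = np.array(angles, dtype=int).reshape(-1, 3)
        self.a_ref = self._angles(coords)

        quads = []
        for b, c in bonds:
            for a in nbrs[b]:
                if a == c:
                    continue
                for d in nbrs[c]:
                    if d == b or d == a:
                        continue
                    quads.append((a, b, c, d))
        self.t_idx = np.array(quads, dtype=int).reshape(-1, 4)

        # nonbonded pair list with topological scaling
        dist = self._graph_distances(nbrs, n, cutoff=3)
        pairs, scales, sigma = [], [], []
        radii = np.array(
            [BONDI_RADII.get(a.element, 1.7) for a in pep.atoms]
        )
        for i in range(n):
            for j in range(i + 1, n):
                d = dist.get((i, j), 99)
                if d <= 2:
                    continue
                pairs.append((i, j))
                scales.append(model.scale_14 if d == 3 else 1.0)
                sigma.append(model.sigma_scale * (radii[i] + radii[j]))
        self.nb_idx = np.array(pairs, dtype=int).reshape(-1, 2)
        self.nb_scale = np.array(scales)
        self.nb_sigma = np.array(sigma)

    @staticmethod
    def _graph_distances(nbrs, n, cutoff):
        out = {}
        for src in range(n):
            seen = {src: 0}
            frontier = [src]
            for depth in range(1, cutoff + 1):
                nxt = []
                for u in frontier:
                    for v in nbrs[u]:
                        if v not in seen:
                            seen[v] = depth
                            nxt.append(v)
                frontier = nxt
            for v, d in seen.items():
                if src < v:
                    out[(src, v)] = d
        return out

    def _angles(self, coords):
        i, j, k = self.a_idx.T
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        return np.arccos(c)

    # ------------------------------------------------------------------
    def components(self, coords):
        m = self.model
        i, j = self.b_idx.T
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        e_bond = float(np.sum(m.k_bond * (r - self.b_ref) ** 2))

        th = self._angles(coords)
        e_angle = float(np.sum(m.k_angle * (th - self.a_ref) ** 2))

        if len(self.t_idx):
            phi, _ = dihedral_gradient_batch(coords, self.t_idx)
            e_tors = float(np.sum(0.5 * m.v3 * (1.0 + np.cos(3.0 * phi))))
        else:
            e_tors = 0.0

        p, q = self.nb_idx.T
        d = np.linalg.norm(coords[p] - coords[q], axis=1)
        if np.any(d < 1e-6):
            raise ForceFieldError("coincident atoms in nonbonded pair")
        e_rep = float(
            np.sum(self.nb_scale * m.eps_rep * (self.nb_sigma / d) ** 12)
        )
        return {
            "bond": e_bond,
            "angle": e_angle,
            "torsion": float(e_tors),
            "repulsion": e_rep,
        }

    def energy_gradient(self, coords):
        m = self.model
        g = np.zeros_like(coords)

        i, j = self.b_idx.T
        dv = coords[i] - coords[j]
        r = np.linalg.norm(dv, axis=1)
        e = float(np.sum(m.k_bond * (r - self.b_ref) ** 2))
        coef = (2.0 * m.k_bond * (r - self.b_ref) / r)[:, None] * dv
        np.add.at(g, i, coef)
        np.add.at(g, j, -coef)

        ai, aj, ak = self.a_idx.T
        u = coords[ai] - coords[aj]
        v = coords[ak] - coords[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cth = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        th = np.arccos(cth)
        sth = np.sqrt(np.maximum(1.0 - cth * cth, 1e-16))
        e += float(np.sum(m.k_angle * (th - self.a_ref) ** 2))
        pref = 2.0 * m.k_angle * (th - self.a_ref)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        dth_di = (cth[:, None] * uh - vh) / (nu * sth)[:, None]
        dth_dk = (cth[:, None] * vh - uh) / (nv * sth)[:, None]
        np.add.at(g, ai, pref[:, None] * dth_di)
        np.add.at(g, ak, pref[:, None] * dth_dk)
        np.add.at(g, aj, -pref[:, None] * (dth_di + dth_dk))

        if len(self.t_idx):
            phi, dphi = dihedral_gradient_batch(coords, self.t_idx)
            e += float(np.sum(0.5 * m.v3 * (1.0 + np.cos(3.0 * phi))))
            coef = (-1.5 * m.v3 * np.sin(3.0 * phi))[:, None, None]
            np.add.at(g, self.t_idx.ravel(), (coef * dphi).reshape(-1, 3))

        p, q = self.nb_idx.T
        dv = coords[p] - coords[q]
        d = np.linalg.norm(dv, axis=1)
        if np.any(d < 1e-6):
            raise ForceFieldError("coincident atoms in nonbonded pair")
        erep = self.nb_scale * m.eps_rep * (self.nb_sigma / d) ** 12
        e += float(np.sum(erep))
        coef = (-12.0 * erep / (d * d))[:, None] * dv
        np.add.at(g, p, coef)
        np.add.at(g, q, -coef)
        return e, g


def _compiled(pep, model):
    model = model or EnergyModel()
    cache = getattr(pep, "_ff_cache", None)
    if cache is not None and cache[0] == model:
        return cache[1]
    ff = _CompiledFF(pep, model)
    pep._ff_cache = (model, ff)
    return ff


def energy(pep, model: EnergyModel | None = None) -> float:
    """Force-field energy (kcal/mol) of the peptide's current coordinates."""
    ff = _compiled(pep, model)
    e, _ = ff.energy_gradient(pep.coords)
    return e


def energy_components(pep, model: EnergyModel | None = None) -> dict:
    """Per-term energy decomposition (kcal/mol)."""
    return _compiled(pep, model).components(pep.coords)


def gradient(pep, model: EnergyModel | None = None) -> np.ndarray:
    """Analytic Cartesian gradient, (n_atoms, 3), kcal/mol/Angstrom."""
    ff = _compiled(pep, model)
    _, g = ff.energy_gradient(pep.coords)
    return g


def _restraints(pep, k_restraint):
    out = []
    for key, target in pep.torsion_targets().items():
        t = pep._torsions[key]
        if t.rotatable:
            out.append(TorsionRestraint(t.quad, target, k_restraint))
    return out


def _objective(ff, restraints, coords):
    e, g = ff.energy_gradient(coords)
    er = 0.0
    if restraints:
        quads = np.array([r.quad for r in restraints], dtype=int)
        targets = np.array([r.target for r in restraints])
        ks = np.array([r.k_restraint for r in restraints])
        phi, dphi = dihedral_gradient_batch(coords, quads)
        delta = np.radians(
            (np.degrees(phi) - targets + 180.0) % 360.0 - 180.0
        )
        er = float(np.sum(ks * delta * delta))
        coef = (2.0 * ks * delta)[:, None, None]
        np.add.at(g, quads.ravel(), (coef * dphi).reshape(-1, 3))
    return e, er, g


def optimize(pep, model: EnergyModel | None = None, constraint: bool = False,
             max_steps: int = 500, tol: float = 1e-6,
             k_restraint: float = K_RESTRAINT) -> OptimizationResult:
    """Polak-Ribiere conjugate-gradient minimization with Armijo line search.

    Stops when the energy decrease of an accepted step falls below ``tol``
    (kcal/mol) or after ``max_steps`` steps.  With ``constraint=True`` a
    harmonic restraint at the stored target is added for every controllable
    phi/psi/omega/chi torsion; restraint energy is excluded from the
    reported ``final_energy``.  After an *unconstrained* run the stored
    torsion targets are refreshed from the relaxed coordinates.
    """
    ff = _compiled(pep, model)
    restraints = _restraints(pep, k_restraint) if constraint else []
    x = pep.coords.copy()
    e, er, g = _objective(ff, restraints, x)
    f = e + er
    steps = 0
    converged = False
    delta = np.inf
    d = -g
    g_prev = g
    steepest = True
    while steps < max_steps:
        gd = float(np.sum(g_prev * d))
        if gd >= 0.0:  # loss of descent direction: restart along -g
            d = -g_prev
            steepest = True
            gd = -float(np.sum(g_prev * g_prev))
            if gd >= 0.0:
                converged = True
                break
        # fixed initial trial: largest per-atom move of 0.05 A
        dmax = np.max(np.abs(d))
        if dmax < 1e-14:
            converged = True
            break
        alpha = 0.05 / dmax
        accepted = False
        first_try = True
        for _ in range(40):
            x_new = x + alpha * d
            try:
                e_new, er_new, g_new = _objective(ff, restraints, x_new)
            except ForceFieldError:
                alpha *= 0.5
                first_try = False
                continue
            if e_new + er_new <= f + 1e-4 * alpha * gd:
                accepted = True
                break
            alpha *= 0.5
            first_try = False
        if not accepted:
            if not steepest:
                # conjugate direction exhausted; retry from steepest descent
                d = -g_prev
                steepest = True
                continue
            converged = True
            break
        if first_try:
            # the fixed trial step was immediately acceptable: greedily
            # double it while the objective keeps improving
            for _ in range(12):
                x_try = x + 2.0 * alpha * d
                try:
                    e_try, er_try, g_try = _objective(ff, restraints, x_try)
                except ForceFieldError:
                    break
                if e_try + er_try >= e_new + er_new:
                    break
                alpha *= 2.0
                x_new, e_new, er_new, g_new = x_try, e_try, er_try, g_try
        delta = f - (e_new + er_new)
        if delta < tol and not steepest:
            # a tiny gain may just reflect a stale conjugate direction;
            # exhaust steepest descent before declaring convergence
            d = -g_prev
            steepest = True
            continue
        steps += 1
        if delta < tol:
            # below the convergence threshold: treat as converged and do
            # not move the structure any further
            converged = True
            break
        beta = float(
            np.sum(g_new * (g_new - g_prev)) / max(np.sum(g_prev * g_prev), 1e-30)
        )
        beta = max(beta, 0.0)
        d = -g_new + beta * d
        steepest = False
        x, f, e, er, g_prev = x_new, e_new + er_new, e_new, er_new, g_new

    pep.coords = x
    dev = pep.max_torsion_deviation()
    if not constraint:
        pep.refresh_targets()
    return OptimizationResult(
        final_energy=e,
        steps=steps,
        converged=converged,
        delta_E_last=float(delta) if np.isfinite(delta) else 0.0,
        max_torsion_deviation=dev,
        restraint_energy=er,
    )


def regularize(pep, model: EnergyModel | None = None, cycles: int = 10,
               steps_per_cycle: int = 50, tol: float = 1e-6,
               k_restraint: float = K_REGULARIZE,
               dev_tol: float = 0.002) -> OptimizationResult:
    """Alternate constrained minimization with exact torsion resets.

    Each cycle runs up to ``steps_per_cycle`` conjugate-gradient steps with
    stiff harmonic torsion restraints, measures the maximum deviation of
    any controllable torsion from its stored target (the *pre-reset*
    deviation), then rigidly rotates every torsion back to its exact
    target.  Cycling stops early once the pre-reset deviation drops below
    ``dev_tol`` degrees (default 0.002), i.e. when the restrained minimum
    is self-consistent with the requested angles.  After the final reset
    every controllable torsion equals its target exactly.
    """
    total_steps = 0
    dev = np.inf
    last = None
    for _ in range(cycles):
        last = optimize(
            pep, model=model, constraint=True, max_steps=steps_per_cycle,
            tol=tol, k_restraint=k_restraint,
        )
        total_steps += last.steps
        dev = pep.max_torsion_deviation()  # pre-reset self-consistency gap
        pep.reset_torsions()
        if dev < dev_tol:
            break
    return OptimizationResult(
        final_energy=energy(pep, model),
        steps=total_steps,
        converged=bool(dev < dev_tol),
        delta_E_last=last.delta_E_last if last else 0.0,
        max_torsion_deviation=float(dev),
    )
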