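"""Vector geometry for internal-coordinate molecular construction.

All angles are in degrees at every public interface; radians are used only
inside function bodies.  Torsions are reported in the canonical range
[-180, 180), with -180 (not +180) as the canonical representation of the
anti conformation.  The dihedral sign follows the IUPAC convention: looking
from atom 2 toward atom 3, a clockwise rotation carrying atom 1 onto atom 4
is positive.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "dihedral",
    "bond_angle",
    "place_atom",
    "rotate_branch",
    "dihedral_gradient",
    "dihedral_gradient_batch",
]

#: sine of the smallest bond angle accepted in a reference frame
_COLLINEAR_TOL = 1e-8


class GeometryError(ValueError):
    """Raised for degenerate geometric reference frames."""


def wrap_angle(angle_deg: float) -> float:
    """Reduce an angle in degrees into the canonical range [-180, 180)."""
    wrapped = (float(angle_deg) + 180.0) % 360.0 - 180.0
    # The modulo can return +180.0 - eps rounding artifacts only; 180 itself
    # maps to -180 by the formula already, so no extra handling is needed.
    return wrapped


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeometryError("non-finite coordinate")
    return v


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees) defined by four points.

    Raises :class:`GeometryError` when consecutive points coincide or either
    reference triple is collinear (sine of the bond angle below 1e-8).
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-12:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _COLLINEAR_TOL * np.linalg.norm(b1) * nb2:
        raise GeometryError("collinear reference triple p1,p2,p3")
    if np.linalg.norm(n2) < _COLLINEAR_TOL * nb2 * np.linalg.norm(b3):
        raise GeometryError("collinear reference triple p2,p3,p4")
    # atan2 formulation is numerically stable near 0 and 180 degrees
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle (degrees) at p2 formed by p1-p2-p3."""
    p1, p2, p3 = (_as_vec(p) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("coincident points in bond angle")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def place_atom(a, b, c, r: float, theta: float, tau: float) -> np.ndarray:
    """Place a new atom D from reference atoms A, B, C (NeRF construction).

    The returned point d satisfies ``|c - d| = r``, ``angle(b, c, d) = theta``
    and ``dihedral(a, b, c, d) = tau`` (degrees), each to ~1e-9 of the request.
    """
    a, b, c = (_as_vec(p) for p in (a, b, c))
    if not r > 0:
        raise GeometryError(f"bond length must be positive, got {r}")
    if not 0.0 < theta < 180.0:
        raise GeometryError(f"bond angle must lie in (0, 180), got {theta}")
    bc = c - b
    ab = b - a
    nbc = np.linalg.norm(bc)
    if nbc < 1e-12 or np.linalg.norm(ab) < 1e-12:
        raise GeometryError("coincident reference atoms")
    u_bc = bc / nbc
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL * np.linalg.norm(ab) * nbc:
        raise GeometryError("collinear reference frame a,b,c")
    u_n = n / nn
    u_m = np.cross(u_n, u_bc)
    th = np.radians(theta)
    ta = np.radians(tau)
    # local displacement in the (u_bc, u_m, u_n) frame
    d_local = r * np.array(
        [-np.cos(th), np.sin(th) * np.cos(ta), np.sin(th) * np.sin(ta)]
    )
    return c + d_local[0] * u_bc + d_local[1] * u_m + d_local[2] * u_n


def rotate_branch(coords, i: int, j: int, branch, delta: float) -> np.ndarray:
    """Rigidly rotate a subset of atoms about the axis through atoms i and j.

    ``coords`` is an (N, 3) array; ``branch`` is an iterable of indices to
    rotate; ``delta`` is in degrees.  The rotation sense is chosen so that a
    torsion measured across the i->j bond with its distal atom in ``branch``
    increases by ``delta``.  Returns a new array; the input is not modified.
    """
    coords = np.array(coords, dtype=float)
    branch = np.asarray(sorted(set(int(k) for k in branch)), dtype=int)
    if i == j:
        raise GeometryError("rotation axis endpoints coincide")
    if i in branch or j in branch:
        raise GeometryError("axis atoms may not be part of the rotated branch")
    axis = coords[j] - coords[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise GeometryError("zero-length rotation axis")
    u = axis / norm
    ang = np.radians(delta)
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    rel = coords[branch] - coords[i]
    # Rodrigues rotation; positive delta advances the IUPAC dihedral
    rot = (
        rel * cos_a
        + np.cross(u, rel) * sin_a
        + np.outer(rel @ u, u) * (1.0 - cos_a)
    )
    coords[branch] = rot + coords[i]
    return coords


def dihedral_gradient(p1, p2, p3, p4):
    """Dihedral (radians) and its Cartesian gradient for four points.

    Returns ``(phi_rad, grads)`` with ``grads`` a (4, 3) array of
    d(phi)/d(point).  Used by torsion energy terms and restraints.
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = np.dot(n1, n1)
    n2sq = np.dot(n2, n2)
    if nb2 < 1e-12 or n1sq < 1e-24 or n2sq < 1e-24:
        raise GeometryError("degenerate frame in dihedral gradient")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    phi = np.arctan2(y, x)
    g1 = -(nb2 / n1sq) * n1
    g4 = (nb2 / n2sq) * n2
    d12 = np.dot(b1, b2) / (nb2 * nb2)
    d32 = np.dot(b3, b2) / (nb2 * nb2)
    g2 = -(1.0 + d12) * g1 + d32 * g4
    g3 = d12 * g1 - (1.0 + d32) * g4
    return phi, np.array([g1, g2, g3, g4])


def dihedral_gradient_batch(coords: np.ndarray, quads: np.ndarray):
    """Vectorized :func:`dihedral_gradient` over an (m, 4) index array.

    Returns ``(phi, grads)`` with ``phi`` of shape (m,) in radians and
    ``grads`` of shape (m, 4, 3).
    """
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    p = coords[quads]                     # (m, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    if np.any(nb2 < 1e-12) or np.any(n1sq < 1e-24) or np.any(n2sq < 1e-24):
        raise GeometryError("degenerate frame in batched dihedral gradient")
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2
    phi = np.arctan2(y, x)
    g1 = -(nb2 / n1sq)[:, None] * n1
    g4 = (nb2 / n2sq)[:, None] * n2
    nb2sq = nb2 * nb2
    d12 = (np.einsum("ij,ij->i", b1, b2) / nb2sq)[:, None]
    d32 = (np.einsum("ij,ij->i", b3, b2) / nb2sq)[:, None]
    g2 = -(1.0 + d12) * g1 + d32 * g4
    g3 = d12 * g1 - (1.0 + d32) * g4
    return phi, np.stack([g1, g2, g3, g4], axis=1)
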