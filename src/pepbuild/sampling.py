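"""Continuous torsion-angle sampling from von Mises mixture models.

Backbone (phi, psi) pairs are drawn from per-residue-type mixtures of
independent-per-dimension von Mises components located at the conventional
Ramachandran basins (alpha, beta, left-handed alpha); side-chain chi
vectors are drawn from rotamer-like mixtures with components at the
gauche-/trans/gauche+ positions.  The distributions are continuous — every
draw is a fresh point on the torus, not a library entry — and each sample
carries an exact log-density under the model.

Side-chain sampling is backbone-dependent by default: the component
weights of the chi mixture are re-weighted according to which Ramachandran
basin the residue's current (phi, psi) pair occupies.

The default parameters ship in ``pepbuild/data/mixtures.json`` and are
deliberately conventional, clearly replaceable values, not a fit to any
survey of experimental structures.  Pass a different parameter file to
:class:`MixtureLibrary` to substitute your own.

Densities are expressed per radian^d (the natural convention for the
von Mises distribution); log-likelihoods returned by :func:`get_sample`
follow that convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import i0e

from .geometry import wrap_angle

__all__ = [
    "AngleMixture",
    "MixtureLibrary",
    "SamplerState",
    "set_seed",
    "default_state",
    "sample_bb_angles",
    "sample_chi_angles",
    "get_sample",
    "mixture_density",
    "TorsionSampler",
]


class SamplingError(ValueError):
    """Raised for invalid residue types or malformed mixture models."""


@dataclass(frozen=True)
class AngleMixture:
    """A mixture of independent-per-dimension von Mises distributions.

    ``components`` is a tuple of ``(weight, means, kappas)`` with angles in
    degrees and concentrations kappa > 0; weights sum to one.
    """

    residue_type: str
    components: tuple[tuple[float, tuple[float, ...], tuple[float, ...]], ...]

    def __post_init__(self):
        if not self.components:
            raise SamplingError("mixture needs at least one component")
        w = np.array([c[0] for c in self.components])
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
            raise SamplingError(
                "component weights must be positive and sum to 1"
            )
        d = self.dimensionality
        for _, means, kappas in self.components:
            if len(means) != d or len(kappas) != d:
                raise SamplingError("inconsistent component dimensionality")
            if any(k <= 0 for k in kappas):
                raise SamplingError("kappa must be positive")

    @property
    def dimensionality(self) -> int:
        return len(self.components[0][1])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    def reweighted(self, scale) -> "AngleMixture":
        """Return a copy with component weights scaled and renormalized."""
        scale = np.asarray(scale, dtype=float)
        if scale.shape != (len(self.components),):
            raise SamplingError("one scale factor per component required")
        w = self.weights * scale
        w = w / w.sum()
        comps = tuple(
            (float(wi), means, kappas)
            for wi, (_, means, kappas) in zip(w, self.components)
        )
        return AngleMixture(self.residue_type, comps)


def _log_vm(delta_rad: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Log of the von Mises density, stable for large kappa."""
    # pdf = exp(kappa cos d) / (2 pi I0(kappa))
    #     = exp(kappa (cos d - 1)) / (2 pi i0e(kappa))
    return (
        kappa * (np.cos(delta_rad) - 1.0)
        - np.log(2.0 * np.pi * i0e(kappa))
    )


def mixture_density(model: AngleMixture, angles) -> float:
    """Mixture probability density at ``angles`` (degrees), per radian^d."""
    return math.exp(mixture_log_density(model, angles))


def mixture_log_density(model: AngleMixture, angles) -> float:
    """Exact log of :func:`mixture_density` (natural log)."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.shape != (model.dimensionality,):
        raise SamplingError(
            f"angle vector of length {model.dimensionality} expected, "
            f"got shape {angles.shape}"
        )
    logs = []
    for w, means, kappas in model.components:
        delta = np.radians(angles - np.asarray(means))
        logs.append(
            math.log(w) + float(np.sum(_log_vm(delta, np.asarray(kappas))))
        )
    m = max(logs)
    return m + math.log(sum(math.exp(x - m) for x in logs))


class SamplerState:
    """Deterministic random stream for torsion sampling.

    An explicit integer seed makes the stream reproducible; without one the
    generator is seeded from OS entropy.
    """

    def __init__(self, seed: int | None = None):
        self.seed = seed
        self.rng = np.random.default_rng(seed)

    def __repr__(self):  # pragma: no cover
        return f"SamplerState(seed={self.seed})"


_DEFAULT_STATE = SamplerState()


def set_seed(seed: int | None = None) -> SamplerState:
    """Reset the process-global sampler stream; returns the new state."""
    global _DEFAULT_STATE
    _DEFAULT_STATE = SamplerState(seed)
    return _DEFAULT_STATE


def default_state() -> SamplerState:
    return _DEFAULT_STATE


class MixtureLibrary:
    """Per-residue-type backbone and side-chain mixtures.

    Parameters are read from a JSON file shaped like the packaged
    ``data/mixtures.json``; see that file for the format.
    """

    def __init__(self, path=None):
        if path is None:
            text = (
                resources.files("pepbuild.data")
                .joinpath("mixtures.json")
                .read_text()
            )
        else:
            with open(path) as fh:
                text = fh.read()
        raw = json.loads(text)
        self.basins = {
            k: tuple(v) for k, v in raw["basins"].items()
        }
        self._bb_raw = raw["backbone"]
        self._chi_components = raw["chi_components"]
        self._chi_kappa = float(raw["chi_kappa"])
        self.bb_dependent_scale = {
            k: tuple(v) for k, v in raw["bb_dependent_scale"].items()
        }

    def backbone_mixture(self, residue_type: str) -> AngleMixture:
        from .templates import AMINO_ACIDS

        residue_type = residue_type.upper()
        if residue_type not in AMINO_ACIDS:
            raise SamplingError(
                f"unknown residue type {residue_type!r}"
            )
        spec = self._bb_raw.get(residue_type, self._bb_raw["default"])
        comps = tuple(
            (float(c["weight"]), tuple(c["mean"]), tuple(c["kappa"]))
            for c in spec["components"]
        )
        return AngleMixture(residue_type, comps)

    def chi_mixture(self, residue_type: str):
        """Rotamer-like chi mixture, or None for residues without chi."""
        from .templates import get_template

        tmpl = get_template(residue_type)
        n = tmpl.n_chi
        if n == 0:
            return None
        comps = tuple(
            (
                float(c["weight"]),
                tuple(float(c["value"]) for _ in range(n)),
                tuple(self._chi_kappa for _ in range(n)),
            )
            for c in self._chi_components
        )
        return AngleMixture(residue_type.upper(), comps)

    def assign_basin(self, phi: float, psi: float) -> str:
        """Nearest Ramachandran basin centre in toroidal distance."""
        best, best_d = None, None
        for name, (bp, bs) in self.basins.items():
            d = wrap_angle(phi - bp) ** 2 + wrap_angle(psi - bs) ** 2
            if best_d is None or d < best_d:
                best, best_d = name, d
        return best

    def chi_mixture_for_backbone(self, residue_type, phi, psi):
        mix = self.chi_mixture(residue_type)
        if mix is None:
            return None
        if phi is None or psi is None:
            return mix
        basin = self.assign_basin(phi, psi)
        return mix.reweighted(self.bb_dependent_scale[basin])


_DEFAULT_LIBRARY = MixtureLibrary()


def default_library() -> MixtureLibrary:
    return _DEFAULT_LIBRARY


def sample_mixture(model: AngleMixture, state: SamplerState) -> list[float]:
    """Draw one angle vector (degrees) from a mixture."""
    rng = state.rng
    k = rng.choice(len(model.components), p=model.weights)
    _, means, kappas = model.components[k]
    out = [
        wrap_angle(math.degrees(rng.vonmises(math.radians(mu), kap)))
        for mu, kap in zip(means, kappas)
    ]
    return out


def sample_bb_angles(pep, res: int, state: SamplerState | None = None,
                     library: MixtureLibrary | None = None) -> list[float]:
    """Sample backbone (phi, psi) for residue ``res``, apply it, return it.

    For proline only psi is applied (the ring fixes phi); the returned pair
    then contains the measured phi alongside the sampled psi.
    """
    state = state or _DEFAULT_STATE
    library = library or _DEFAULT_LIBRARY
    pep._check_res(res)
    mix = library.backbone_mixture(pep.sequence[res - 1])
    phi, psi = sample_mixture(mix, state)
    cur_phi, cur_psi, _ = pep.get_bb_angles(res)
    if pep.get_resname(res) == "PRO":
        phi = cur_phi
    if cur_phi is None:
        applied_phi = None
    else:
        applied_phi = phi
    if cur_psi is not None:
        pep._set_torsion(res, "psi", psi)
    if applied_phi is not None:
        pep._set_torsion(res, "phi", applied_phi)
    return [phi if cur_phi is not None else None,
            psi if cur_psi is not None else None]


def sample_chi_angles(pep, res: int, state: SamplerState | None = None,
                      bb_dependent: bool = True,
                      library: MixtureLibrary | None = None) -> list[float]:
    """Sample the chi vector for residue ``res``, apply it, return it.

    With ``bb_dependent=True`` (the default) the rotamer component weights
    are re-weighted by the Ramachandran basin of the residue's current
    (phi, psi).  Residues without controllable side-chain torsions
    (glycine, alanine, proline) return an empty list.
    """
    state = state or _DEFAULT_STATE
    library = library or _DEFAULT_LIBRARY
    pep._check_res(res)
    code = pep.sequence[res - 1]
    if bb_dependent:
        phi, psi, _ = pep.get_bb_angles(res)
        mix = library.chi_mixture_for_backbone(code, phi, psi)
    else:
        mix = library.chi_mixture(code)
    if mix is None:
        return []
    chis = sample_mixture(mix, state)
    pep.set_chi_angles(res, chis)
    return chis


def get_sample(residue_type: str, state: SamplerState | None = None,
               library: MixtureLibrary | None = None):
    """Draw (chi, bb, ll) for a residue type without building a peptide.

    The backbone pair is drawn first, then the chi vector in its
    backbone-dependent mode; ``ll`` is the exact log joint density of the
    returned angles under the model (per radian^d convention).
    """
    state = state or _DEFAULT_STATE
    library = library or _DEFAULT_LIBRARY
    bb_mix = library.backbone_mixture(residue_type)
    bb = sample_mixture(bb_mix, state)
    ll = mixture_log_density(bb_mix, bb)
    chi_mix = library.chi_mixture_for_backbone(residue_type, bb[0], bb[1])
    if chi_mix is None:
        return [], bb, ll
    chi = sample_mixture(chi_mix, state)
    ll += mixture_log_density(chi_mix, chi)
    return chi, bb, ll


class TorsionSampler:
    """Object-style front end to the sampler (mirrors a DBN-style API).

    >>> dbn = TorsionSampler()
    >>> chi, bb, ll = dbn.get_sample("L")
    """

    def __init__(self, library: MixtureLibrary | None = None,
                 state: SamplerState | None = None):
        self.library = library or _DEFAULT_LIBRARY
        self.state = state

    def get_sample(self, residue_type: str):
        return get_sample(
            residue_type, self.state or _DEFAULT_STATE, self.library
        )


# ----------------------------------------------------------------------
# quadrature helpers (used by tests and the acceptance checks)
# ----------------------------------------------------------------------
def _grid_points(model: AngleMixture, step_deg: float) -> np.ndarray:
    d = model.dimensionality
    axis = np.arange(-180.0, 180.0, step_deg)
    if d == 1:
        return axis[:, None]
    if d == 2:
        a, b = np.meshgrid(axis, axis, indexing="ij")
        return np.column_stack([a.ravel(), b.ravel()])
    raise SamplingError("grid helpers support 1 or 2 dimensions")


def density_batch(model: AngleMixture, points: np.ndarray) -> np.ndarray:
    """Mixture density (per radian^d) at an (m, d) array of angle vectors."""
    points = np.asarray(points, dtype=float)
    total = np.zeros(len(points))
    for w, means, kappas in model.components:
        delta = np.radians(points - np.asarray(means))
        total += w * np.exp(
            np.sum(_log_vm(delta, np.asarray(kappas)), axis=1)
        )
    return total


def grid_integral(model: AngleMixture, step_deg: float = 1.0) -> float:
    """Numerically integrate a 1-D or 2-D mixture density over the torus."""
    pts = _grid_points(model, step_deg)
    h = math.radians(step_deg) ** model.dimensionality
    return float(np.sum(density_batch(model, pts)) * h)


def component_region_probabilities(model: AngleMixture,
                                   step_deg: float = 2.0) -> np.ndarray:
    """Probability mass of each component's nearest-mean region.

    Partitions the torus by toroidal distance to the component means and
    integrates the mixture density over each cell; used as the expected
    frequencies for goodness-of-fit checks of the sampler.  Supports 1-D
    and 2-D mixtures.
    """
    pts = _grid_points(model, step_deg)
    h = math.radians(step_deg) ** model.dimensionality
    dens = density_batch(model, pts)
    dists = np.stack([
        np.sum(((pts - np.asarray(c[1]) + 180.0) % 360.0 - 180.0) ** 2,
               axis=1)
        for c in model.components
    ])
    assign = np.argmin(dists, axis=0)
    masses = np.zeros(len(model.components))
    np.add.at(masses, assign, dens)
    return masses * h


def nearest_component(model: AngleMixture, angles) -> int:
    """Index of the component whose mean is toroidally nearest."""
    angles = np.asarray(angles, dtype=float)
    dist = [
        float(
            np.sum(
                np.array([wrap_angle(x) for x in angles - np.asarray(c[1])])
                ** 2
            )
        )
        for c in model.components
    ]
    return int(np.argmin(dist))
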