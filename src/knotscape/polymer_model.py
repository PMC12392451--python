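"""Bead-spring ring-polymer model: geometry, potential, biases, alignment.

The ring is a closed homopolymer of N identical beads.  Adjacent beads
(cyclically) are joined by stiff harmonic springs; every other pair
interacts through a Lennard-Jones potential.  Because the springs are
stiff, bond lengths are nearly uniform in all local minima and the LJ
well depth epsilon sets the energy scale of the landscape.

Energy, gradient and Hessian are analytic.  The Hessian of any isolated
configuration has six zero modes (rigid translations and rotations);
the remaining kappa = 3N - 6 eigenvalues are the vibrational spectrum
used by the harmonic-superposition observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "RingConfiguration",
    "PotentialParams",
    "BiasParams",
    "AlignmentResult",
    "CoincidentBeadsError",
    "total_energy",
    "gradient",
    "energy_and_gradient",
    "hessian",
    "hessian_spectrum",
    "zero_mode_threshold",
    "radial_bias",
    "pulling_bias",
    "align",
    "ring_permutations",
    "apply_permutation",
]

_COINCIDENCE_CUTOFF = 1e-10


class CoincidentBeadsError(ValueError):
    """A nonbonded pair sits at (numerically) zero separation: the LJ
    energy diverges and the configuration must be rejected."""


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the bead-spring ring potential.

    epsilon : LJ well depth (sets the energy unit of the model).
    sigma   : LJ length parameter, in units of the equilibrium bond length.
    k_spring: harmonic bond force constant.
    r0      : equilibrium bond length (the length unit).
    """

    epsilon: float = 1.0
    sigma: float = 1.888
    k_spring: float = 1035.8
    r0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma", "k_spring", "r0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BiasParams:
    """Radial bias V = (k/2) sum_a |r_a - r_c|^p about the centroid r_c.

    k_bias < 0 expands the ring, k_bias > 0 compresses it.  p in {1, 2}.
    """

    k_bias: float
    power: int = 1

    def __post_init__(self) -> None:
        if self.power not in (1, 2):
            raise ValueError("power must be 1 or 2")
        if not np.isfinite(self.k_bias):
            raise ValueError("k_bias must be finite")


@dataclass
class RingConfiguration:
    """N ordered bead positions of a closed ring; bead i is bonded to
    beads (i-1) mod N and (i+1) mod N."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_beads, 3)")
        if self.coords.shape[0] < 3:
            raise ValueError("a ring needs at least 3 beads")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "RingConfiguration":
        return RingConfiguration(self.coords.copy())

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def radius_of_gyration(self) -> float:
        d = self.coords - self.centroid()
        return float(np.sqrt((d * d).sum() / self.n_beads))

    def mirror(self) -> "RingConfiguration":
        """Reflect through the xy plane (an improper operation: flips
        chirality and knot handedness)."""
        c = self.coords.copy()
        c[:, 2] *= -1.0
        return RingConfiguration(c)

    def bond_lengths(self) -> np.ndarray:
        d = np.roll(self.coords, -1, axis=0) - self.coords
        return np.linalg.norm(d, axis=1)


@dataclass(frozen=True)
class AlignmentResult:
    """Best superposition of two rings over translations, proper
    rotations and the 2N ring-preserving bead relabelings."""

    distance: float
    offset: int
    reversed: bool
    rotation: np.ndarray = field(repr=False)


# --- pair bookkeeping -------------------------------------------------------

@lru_cache(maxsize=64)
def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (i, j) for all unordered pairs, split into the N
    bonded pairs (cyclic neighbours) and the nonbonded rest.  Pairs
    separated by two bonds are nonbonded and do interact."""
    iu, ju = np.triu_indices(n, k=1)
    sep = ju - iu
    bonded = (sep == 1) | (sep == n - 1)
    return iu[bonded], ju[bonded], iu[~bonded], ju[~bonded]


def _pair_geometry(coords: np.ndarray, i: np.ndarray, j: np.ndarray):
    dvec = coords[j] - coords[i]
    r = np.linalg.norm(dvec, axis=1)
    return dvec, r


# --- energy / gradient / Hessian -------------------------------------------

def _lj_terms(r: np.ndarray, p: PotentialParams):
    """LJ energy, u'(r)/r and u''(r) for an array of separations."""
    sr6 = (p.sigma / r) ** 6
    sr12 = sr6 * sr6
    u = 4.0 * p.epsilon * (sr12 - sr6)
    # u'(r) = 4 eps (-12 sr12 + 6 sr6) / r
    du = 4.0 * p.epsilon * (-12.0 * sr12 + 6.0 * sr6) / r
    d2u = 4.0 * p.epsilon * (156.0 * sr12 - 42.0 * sr6) / r**2
    return u, du, d2u


def _bond_terms(r: np.ndarray, p: PotentialParams):
    u = 0.5 * p.k_spring * (r - p.r0) ** 2
    du = p.k_spring * (r - p.r0)
    d2u = np.full_like(r, p.k_spring)
    return u, du, d2u


def total_energy(config: RingConfiguration, params: PotentialParams) -> float:
    """Sum of harmonic bond terms and LJ terms over all nonbonded pairs."""
    bi, bj, ni, nj = _pair_indices(config.n_beads)
    _, rb = _pair_geometry(config.coords, bi, bj)
    e = float(_bond_terms(rb, params)[0].sum())
    if len(ni):
        _, rn = _pair_geometry(config.coords, ni, nj)
        if np.any(rn < _COINCIDENCE_CUTOFF):
            raise CoincidentBeadsError("coincident beads in a nonbonded pair")
        e += float(_lj_terms(rn, params)[0].sum())
    return e


def energy_and_gradient(
    config: RingConfiguration, params: PotentialParams
) -> tuple[float, np.ndarray]:
    """Energy and its analytic gradient, shape (N, 3)."""
    n = config.n_beads
    bi, bj, ni, nj = _pair_indices(n)
    grad = np.zeros((n, 3))
    e = 0.0
    for (ii, jj, terms) in ((bi, bj, _bond_terms), (ni, nj, _lj_terms)):
        if not len(ii):
            continue
        dvec, r = _pair_geometry(config.coords, ii, jj)
        if terms is _lj_terms and np.any(r < _COINCIDENCE_CUTOFF):
            raise CoincidentBeadsError("coincident beads in a nonbonded pair")
        u, du, _ = terms(r, params)
        e += float(u.sum())
        f = (du / r)[:, None] * dvec  # dU/dr_j for the pair
        np.add.at(grad, jj, f)
        np.add.at(grad, ii, -f)
    return e, grad


def gradient(config: RingConfiguration, params: PotentialParams) -> np.ndarray:
    return energy_and_gradient(config, params)[1]


def batch_energy_gradient(
    coords_batch: np.ndarray, params: PotentialParams
) -> tuple[np.ndarray, np.ndarray]:
    """Energies and gradients for a stack of configurations (M, N, 3)
    in one vectorised pass (used by band relaxation)."""
    m, n, _ = coords_batch.shape
    bi, bj, ni, nj = _pair_indices(n)
    energies = np.zeros(m)
    grads = np.zeros_like(coords_batch)
    for (ii, jj, terms) in ((bi, bj, _bond_terms), (ni, nj, _lj_terms)):
        if not len(ii):
            continue
        dvec = coords_batch[:, jj] - coords_batch[:, ii]   # (M, P, 3)
        r = np.linalg.norm(dvec, axis=2)
        if terms is _lj_terms and np.any(r < _COINCIDENCE_CUTOFF):
            raise CoincidentBeadsError("coincident beads in a nonbonded pair")
        u, du, _ = terms(r, params)
        energies += u.sum(axis=1)
        f = (du / r)[..., None] * dvec
        rows = np.arange(m)[:, None]
        np.add.at(grads, (rows, jj[None, :]), f)
        np.add.at(grads, (rows, ii[None, :]), -f)
    return energies, grads


def hessian(config: RingConfiguration, params: PotentialParams) -> np.ndarray:
    """Analytic second-derivative matrix, shape (3N, 3N).

    For a pair potential u(r) the off-diagonal 3x3 block for pair (i, j)
    is -[(u'' - u'/r) rhat rhat^T + (u'/r) I]; diagonal blocks accumulate
    the negatives of the off-diagonal blocks (translational invariance).
    """
    n = config.n_beads
    bi, bj, ni, nj = _pair_indices(n)
    h = np.zeros((n, n, 3, 3))
    eye = np.eye(3)
    for (ii, jj, terms) in ((bi, bj, _bond_terms), (ni, nj, _lj_terms)):
        if not len(ii):
            continue
        dvec, r = _pair_geometry(config.coords, ii, jj)
        if terms is _lj_terms and np.any(r < _COINCIDENCE_CUTOFF):
            raise CoincidentBeadsError("coincident beads in a nonbonded pair")
        _, du, d2u = terms(r, params)
        rhat = dvec / r[:, None]
        outer = rhat[:, :, None] * rhat[:, None, :]
        block = (d2u - du / r)[:, None, None] * outer + (du / r)[:, None, None] * eye
        np.add.at(h, (ii, jj), -block)
        np.add.at(h, (jj, ii), -block)
        np.add.at(h, (ii, ii), block)
        np.add.at(h, (jj, jj), block)
    return h.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def zero_mode_threshold(eigenvalues: np.ndarray) -> float:
    """Scale-free cut below which an eigenvalue is treated as numerical
    noise rather than genuine curvature: |lam| < 1e-9 * max |lam|.

    The stiff bonds put the top of the spectrum near K ~ 1e3 while the
    softest genuine bending modes of large rings fall to ~1e-5, so the
    cut must sit orders of magnitude below both; rigid-body modes are
    handled separately by exact projection (vibrational_spectrum), not
    by this magnitude cut."""
    return 1e-9 * float(np.abs(eigenvalues).max())


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the six rigid-body modes (3 translations +
    3 rotations about the centroid) at the given geometry."""
    n = coords.shape[0]
    c = coords - coords.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        modes.append(t.ravel())
    for axis in np.eye(3):
        modes.append(np.cross(axis, c).ravel())
    q, _ = np.linalg.qr(np.stack(modes, axis=1))
    return q


def vibrational_spectrum(
    config: RingConfiguration, params: PotentialParams
) -> np.ndarray:
    """The 3N - 6 vibrational Hessian eigenvalues, sorted ascending.

    Rather than thresholding magnitudes (soft bending modes approach
    zero as N grows, making any fixed cut unreliable), the exactly
    known rigid-body subspace is projected out and shifted to the top
    of the spectrum."""
    h = hessian(config, params)
    q = rigid_body_basis(config.coords)
    p = np.eye(h.shape[0]) - q @ q.T
    shift = 10.0 * float(np.abs(h).max()) + 1.0
    lam = np.linalg.eigvalsh(p @ h @ p + shift * (q @ q.T))
    return lam[:-6]


def hessian_spectrum(
    config: RingConfiguration, params: PotentialParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues split into (negative, rigid-body, positive) classes;
    the rigid-body class always has six members by construction."""
    vib = vibrational_spectrum(config, params)
    tol = zero_mode_threshold(vib)
    neg = vib[vib <= -tol]
    pos = vib[vib >= tol]
    return neg, np.zeros(6), pos


# --- bias potentials --------------------------------------------------------

def radial_bias(
    config: RingConfiguration, bias: BiasParams
) -> tuple[float, np.ndarray]:
    """Isotropic radial potential about the instantaneous centroid.

    V = (k/2) sum_a |r_a - r_c|^p with r_c = (1/N) sum r_a.  The gradient
    accounts for the dependence of r_c on every coordinate.  A bead
    sitting exactly at the centroid contributes a zero (sub)gradient
    when p = 1.
    """
    d = config.coords - config.centroid()
    dist = np.linalg.norm(d, axis=1)
    k, p = bias.k_bias, bias.power
    energy = 0.5 * k * float((dist**p).sum())
    if p == 2:
        inner = 2.0 * d
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            inner = np.where(dist[:, None] > 0, d / np.where(dist == 0, 1, dist)[:, None], 0.0)
    # chain rule through the centroid: grad_b = (k/2) [inner_b - mean(inner)]
    grad = 0.5 * k * (inner - inner.mean(axis=0))
    return energy, grad


def pulling_bias(
    config: RingConfiguration, bead_a: int, bead_b: int, force: float
) -> tuple[float, np.ndarray]:
    """Constant-magnitude separating force between two beads:
    V = -f |r_a - r_b|, so minimisation pulls them apart."""
    if bead_a == bead_b:
        raise ValueError("bead_a and bead_b must differ")
    if force < 0:
        raise ValueError("force must be non-negative")
    d = config.coords[bead_a] - config.coords[bead_b]
    r = float(np.linalg.norm(d))
    grad = np.zeros_like(config.coords)
    if force == 0.0:
        return 0.0, grad
    if r < _COINCIDENCE_CUTOFF:
        raise CoincidentBeadsError("pulled beads coincide: direction undefined")
    grad[bead_a] = -force * d / r
    grad[bead_b] = force * d / r
    return -force * r, grad


# --- permutation-aware alignment -------------------------------------------

def ring_permutations(n: int):
    """The 2N bond-preserving bead relabelings of a ring: N cyclic
    shifts, with and without traversal reversal."""
    base = np.arange(n)
    for rev in (False, True):
        seq = base[::-1] if rev else base
        for off in range(n):
            yield off, rev, np.roll(seq, -off)


def apply_permutation(coords: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return coords[perm]


def _kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation mapping centred b onto centred a, and the
    residual distance.  Inversions are excluded (chirality preserved)."""
    c = b.T @ a
    u, s, vt = np.linalg.svd(c)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.array([1.0, 1.0, d])
    rot = (u * diag) @ vt
    dist2 = (a * a).sum() + (b * b).sum() - 2.0 * (s[0] + s[1] + d * s[2])
    return rot, float(np.sqrt(max(dist2, 0.0)))


def align(config_a: RingConfiguration, config_b: RingConfiguration) -> AlignmentResult:
    """Minimum Euclidean distance between two rings over translation,
    proper rotation and all 2N ring relabelings, enumerated exhaustively.
    For a homopolymer ring these relabelings are the only bond-preserving
    permutations, so the enumeration is exact."""
    if config_a.n_beads != config_b.n_beads:
        raise ValueError("rings must have the same number of beads")
    a = config_a.coords - config_a.centroid()
    bc = config_b.coords - config_b.centroid()
    best: AlignmentResult | None = None
    for off, rev, perm in ring_permutations(config_a.n_beads):
        rot, dist = _kabsch(a, bc[perm])
        if best is None or dist < best.distance:
            best = AlignmentResult(distance=dist, offset=off, reversed=rev, rotation=rot)
    assert best is not None
    return best
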