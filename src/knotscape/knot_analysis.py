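"""Projection-based knot analysis of closed bead rings.

A ring is rotated, projected onto the xy plane, and its segment-pair
crossings extracted with over/under flags (from interpolated z) and
signs (positive when the overpassing strand runs left-to-right while
the underpassing strand runs bottom-to-top, i.e. the z component of
d_over x d_under is positive).  The fewest-crossing projection feeds a
Kauffman-bracket state sum that yields the Jones polynomial, which is
matched against a reference table of knots through seven crossings.
Crossing counts, writhe and winding number averaged over uniformly
random projections serve as order parameters for landscape colouring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .polymer_model import RingConfiguration

__all__ = [
    "DegenerateProjection",
    "CrossingCapExceeded",
    "Crossing",
    "ProjectedDiagram",
    "KnotClass",
    "random_rotation",
    "project_diagram",
    "minimal_diagram",
    "jones_polynomial",
    "jones_from_pd",
    "mirror_jones",
    "classify_knot",
    "crossing_statistics",
    "writhe",
    "gauss_writhe",
    "winding_number",
    "winding_number_of_projection",
    "reference_table",
    "format_jones",
]

_PARAM_EPS = 1e-9
_Z_EPS = 1e-9


class DegenerateProjection(Exception):
    """The projection direction produced an ambiguous diagram (grazing
    intersection, parallel overlap, or unresolved over/under); the
    caller should retry with a fresh rotation."""


class CrossingCapExceeded(Exception):
    """Too many crossings for the bracket state sum; expand the
    structure first."""


@dataclass(frozen=True)
class Crossing:
    """A transverse double point of the projected curve.

    Segment i joins bead i to bead (i+1) mod N.  ``over_param`` /
    ``under_param`` locate the crossing along each segment in [0, 1].
    """

    over_segment: int
    under_segment: int
    position2d: tuple[float, float]
    sign: int
    over_param: float
    under_param: float


@dataclass
class ProjectedDiagram:
    """Ordered crossing data of one projection plus the along-curve
    traversal (each crossing visited once as over, once as under)."""

    crossings: list[Crossing]
    n_segments: int

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)

    def traversal(self) -> list[tuple[int, bool]]:
        """Passages (crossing index, is_over) in order along the curve."""
        events = []
        for idx, c in enumerate(self.crossings):
            events.append((c.over_segment, c.over_param, idx, True))
            events.append((c.under_segment, c.under_param, idx, False))
        events.sort(key=lambda e: (e[0], e[1]))
        out = [(idx, over) for _, _, idx, over in events]
        seen: dict[int, int] = {}
        for idx, _ in out:
            seen[idx] = seen.get(idx, 0) + 1
        if any(v != 2 for v in seen.values()):
            raise DegenerateProjection("crossing not visited exactly twice")
        return out

    def writhe(self) -> int:
        return sum(c.sign for c in self.crossings)

    def mirror(self) -> "ProjectedDiagram":
        """Swap over/under at every crossing (the mirror-image knot)."""
        flipped = [
            Crossing(
                over_segment=c.under_segment,
                under_segment=c.over_segment,
                position2d=c.position2d,
                sign=-c.sign,
                over_param=c.under_param,
                under_param=c.over_param,
            )
            for c in self.crossings
        ]
        return ProjectedDiagram(flipped, self.n_segments)

    def _combinatorics(self) -> list[tuple[int, int, int, int, int]]:
        """Per crossing: (sign, o_in, o_out, u_in, u_out) arc indices,
        where arc k runs from passage k to passage k+1 (cyclic)."""
        order = self.traversal()
        m = len(order)
        passage_of: dict[tuple[int, bool], int] = {
            (idx, over): k for k, (idx, over) in enumerate(order)
        }
        out = []
        for idx, c in enumerate(self.crossings):
            ko = passage_of[(idx, True)]
            ku = passage_of[(idx, False)]
            out.append((c.sign, (ko - 1) % m, ko, (ku - 1) % m, ku))
        return out


@dataclass(frozen=True)
class KnotClass:
    """Knot type assignment: Rolfsen-style label, chirality tag for
    chiral knots ('right' = Jones supported on positive powers of t),
    and the Jones polynomial as an exponent -> coefficient map."""

    label: str
    chirality: str | None
    jones: dict = field(hash=False)

    @property
    def full_label(self) -> str:
        return self.label if not self.chirality else f"{self.label}{'+' if self.chirality == 'right' else '-'}"


# --- rotations and raw crossing extraction ---------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via a uniform unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@lru_cache(maxsize=64)
def _nonadjacent_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Segment index pairs (i < j) that do not share a bead."""
    iu, ju = np.triu_indices(n, k=2)
    keep = ~((iu == 0) & (ju == n - 1))
    return iu[keep], ju[keep]


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _projection_crossings(coords_rot: np.ndarray):
    """All transverse crossings of the xy projection.

    Returns (over_seg, under_seg, over_param, under_param, sign, xpos)
    arrays; raises DegenerateProjection for grazing or parallel-overlap
    geometry or unresolved depth order.
    """
    n = coords_rot.shape[0]
    xy = coords_rot[:, :2]
    z = coords_rot[:, 2]
    d = np.roll(xy, -1, axis=0) - xy
    dz = np.roll(z, -1) - z
    i, j = _nonadjacent_pairs(n)
    denom = _cross2(d[i], d[j])
    r = xy[j] - xy[i]
    parallel = np.abs(denom) < 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(parallel, np.nan, _cross2(r, d[j]) / denom)
        t = np.where(parallel, np.nan, _cross2(r, d[i]) / denom)
    if np.any(parallel & (np.abs(_cross2(r, d[i])) < 1e-12)):
        # collinear segments: overlap would be a degenerate diagram
        mask = parallel & (np.abs(_cross2(r, d[i])) < 1e-12)
        for k in np.flatnonzero(mask):
            if _collinear_overlap(xy, i[k], j[k]):
                raise DegenerateProjection("collinear overlapping segments")
    inside = (s > _PARAM_EPS) & (s < 1 - _PARAM_EPS) & \
             (t > _PARAM_EPS) & (t < 1 - _PARAM_EPS)
    grazing = (
        (s > -_PARAM_EPS) & (s < 1 + _PARAM_EPS)
        & (t > -_PARAM_EPS) & (t < 1 + _PARAM_EPS)
        & ~inside & ~np.isnan(s)
    )
    if np.any(grazing):
        raise DegenerateProjection("intersection at or near a segment endpoint")
    si, ti = s[inside], t[inside]
    ii, jj = i[inside], j[inside]
    zi = z[ii] + si * dz[ii]
    zj = z[jj] + ti * dz[jj]
    if np.any(np.abs(zi - zj) < _Z_EPS):
        raise DegenerateProjection("unresolved over/under (|dz| too small)")
    i_over = zi > zj
    over_seg = np.where(i_over, ii, jj)
    under_seg = np.where(i_over, jj, ii)
    over_par = np.where(i_over, si, ti)
    under_par = np.where(i_over, ti, si)
    sign = np.sign(np.where(i_over, _cross2(d[ii], d[jj]), _cross2(d[jj], d[ii])))
    xpos = xy[ii] + si[:, None] * d[ii]
    return over_seg, under_seg, over_par, under_par, sign.astype(int), xpos


def _collinear_overlap(xy: np.ndarray, i: int, j: int) -> bool:
    n = xy.shape[0]
    a0, a1 = xy[i], xy[(i + 1) % n]
    b0, b1 = xy[j], xy[(j + 1) % n]
    u = a1 - a0
    L2 = float(u @ u)
    if L2 == 0.0:
        return True
    ta = sorted([0.0, 1.0])
    tb = sorted([float((b0 - a0) @ u) / L2, float((b1 - a0) @ u) / L2])
    return min(ta[1], tb[1]) - max(ta[0], tb[0]) > _PARAM_EPS


def project_diagram(
    config: RingConfiguration, rotation: np.ndarray
) -> ProjectedDiagram:
    """Rotate, project onto xy, and extract the crossing diagram."""
    coords = config.coords @ rotation.T
    over_seg, under_seg, over_par, under_par, sign, xpos = _projection_crossings(coords)
    crossings = [
        Crossing(
            over_segment=int(over_seg[k]),
            under_segment=int(under_seg[k]),
            position2d=(float(xpos[k, 0]), float(xpos[k, 1])),
            sign=int(sign[k]),
            over_param=float(over_par[k]),
            under_param=float(under_par[k]),
        )
        for k in range(len(sign))
    ]
    diagram = ProjectedDiagram(crossings, config.n_beads)
    diagram.traversal()  # validates the two-passage invariant
    return diagram


def minimal_diagram(
    config: RingConfiguration,
    n_rotations: int = 10000,
    rng: np.random.Generator | None = None,
) -> ProjectedDiagram:
    """Fewest-crossing non-degenerate diagram over random rotations."""
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    best: ProjectedDiagram | None = None
    attempts = 0
    produced = 0
    while produced < n_rotations and attempts < 20 * n_rotations:
        attempts += 1
        try:
            diag = project_diagram(config, random_rotation(rng))
        except DegenerateProjection:
            continue
        produced += 1
        if best is None or diag.n_crossings < best.n_crossings:
            best = diag
            if best.n_crossings == 0:
                break
    if best is None:
        raise DegenerateProjection("all projections degenerate")
    return best


# --- Laurent polynomials in one variable (exponent -> int coeff) -----------

def _poly_add(a: dict, b: dict) -> dict:
    out = dict(a)
    for e, c in b.items():
        out[e] = out.get(e, 0) + c
        if out[e] == 0:
            del out[e]
    return out


def _poly_mul(a: dict, b: dict) -> dict:
    out: dict[int, int] = {}
    for ea, ca in a.items():
        for eb, cb in b.items():
            e = ea + eb
            out[e] = out.get(e, 0) + ca * cb
    return {e: c for e, c in out.items() if c != 0}


def mirror_jones(jones: dict) -> dict:
    """Jones of the mirror image: t -> 1/t."""
    return {-e: c for e, c in jones.items()}


def format_jones(jones: dict) -> str:
    if not jones:
        return "0"
    parts = []
    for e in sorted(jones):
        c = jones[e]
        parts.append(f"{'+' if c >= 0 else '-'}{abs(c)}t^{e}")
    return " ".join(parts)


# --- Kauffman bracket state sum --------------------------------------------

class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _bracket_from_crossings(crossings: list[tuple[int, int, int, int, int]]) -> dict:
    """Kauffman bracket of a diagram given per-crossing combinatorics
    (sign, o_in, o_out, u_in, u_out) on 2C along-curve arcs.

    For a positive crossing the A-smoothing joins (o_in, u_out) and
    (o_out, u_in); for a negative crossing the pairings swap.  The
    bracket is the sum over all 2^C smoothing states of
    A^(a-b) d^(loops-1), with d = -A^2 - A^-2.
    """
    c = len(crossings)
    if c == 0:
        return {0: 1}
    if c > 24:
        raise CrossingCapExceeded(f"{c} crossings exceed the state-sum cap")
    n_arcs = 2 * c
    d_pow = [{0: 1}]
    d = {2: -1, -2: -1}
    for _ in range(c + 1):
        d_pow.append(_poly_mul(d_pow[-1], d))
    pairings = []
    for sign, o_in, o_out, u_in, u_out in crossings:
        if sign > 0:
            a_pairs = ((o_in, u_out), (o_out, u_in))
            b_pairs = ((o_in, u_in), (o_out, u_out))
        else:
            a_pairs = ((o_in, u_in), (o_out, u_out))
            b_pairs = ((o_in, u_out), (o_out, u_in))
        pairings.append((a_pairs, b_pairs))
    total: dict[int, int] = {}
    for state in range(1 << c):
        uf = _UnionFind(n_arcs)
        exp = 0
        for k, (a_pairs, b_pairs) in enumerate(pairings):
            if state >> k & 1:
                exp -= 1
                for x, y in b_pairs:
                    uf.union(x, y)
            else:
                exp += 1
                for x, y in a_pairs:
                    uf.union(x, y)
        loops = len({uf.find(x) for x in range(n_arcs)})
        total = _poly_add(total, {e + exp: co for e, co in d_pow[loops - 1].items()})
    return total


def _jones_from_bracket(bracket: dict, writhe_sum: int) -> dict:
    """Normalize by (-A)^(-3w) and substitute A = t^(-1/4)."""
    sign = -1 if (3 * writhe_sum) % 2 else 1
    f = {e - 3 * writhe_sum: sign * c for e, c in bracket.items()}
    jones: dict[int, int] = {}
    for e, c in f.items():
        if e % 4:
            raise ValueError("bracket exponents not divisible by 4: invalid diagram")
        jones[-e // 4] = jones.get(-e // 4, 0) + c
    return {e: c for e, c in jones.items() if c != 0}


def jones_polynomial(diagram: ProjectedDiagram, crossing_cap: int = 20) -> dict:
    """Jones polynomial V(t) of the diagram as {t-exponent: coeff}.

    Topological invariant: independent of which (non-degenerate)
    projection of the same ring produced the diagram.
    """
    if diagram.n_crossings > crossing_cap:
        raise CrossingCapExceeded(
            f"{diagram.n_crossings} crossings > cap {crossing_cap}; "
            "expand the configuration first"
        )
    comb = diagram._combinatorics()
    return _jones_from_bracket(_bracket_from_crossings(comb), diagram.writhe())


# --- PD codes and the reference table --------------------------------------

def _pd_to_crossings(pd_code: list[tuple[int, int, int, int]]):
    """Planar-diagram code -> per-crossing combinatorics.

    X(a, b, c, d) lists the four arcs counterclockwise starting from the
    incoming under arc a; arcs are numbered 1..2C along the orientation.
    The under strand runs a -> c; the over strand runs d -> b when
    b = d + 1 (positive crossing) and b -> d otherwise (negative).
    """
    m = 2 * len(pd_code)
    out = []
    for a, b, c, d in pd_code:
        if (b - d) % m == 1:
            sign, o_in, o_out = 1, d, b
        elif (d - b) % m == 1:
            sign, o_in, o_out = -1, b, d
        else:
            raise ValueError(f"invalid PD crossing X({a},{b},{c},{d})")
        out.append((sign, o_in - 1, o_out - 1, a - 1, c - 1))
    return out


def jones_from_pd(pd_code: list[tuple[int, int, int, int]]) -> dict:
    comb = _pd_to_crossings(pd_code)
    w = sum(c[0] for c in comb)
    return _jones_from_bracket(_bracket_from_crossings(comb), w)


# Standard minimal planar-diagram codes (Rolfsen-table diagrams) for the
# prime knots through seven crossings that arise for torus-knot rings
# and their neighbours.  The reference Jones polynomials are *computed*
# from these diagrams by the bracket evaluator at first use.
_PD_CODES: dict[str, list[tuple[int, int, int, int]]] = {
    "3_1": [(1, 4, 2, 5), (3, 6, 4, 1), (5, 2, 6, 3)],
    "4_1": [(4, 2, 5, 1), (8, 6, 1, 5), (6, 3, 7, 4), (2, 7, 3, 8)],
    "5_1": [(1, 6, 2, 7), (3, 8, 4, 9), (5, 10, 6, 1), (7, 2, 8, 3),
            (9, 4, 10, 5)],
    "5_2": [(1, 4, 2, 5), (3, 8, 4, 9), (5, 10, 6, 1), (9, 6, 10, 7),
            (7, 2, 8, 3)],
    "6_1": [(1, 4, 2, 5), (7, 10, 8, 11), (3, 9, 4, 8), (9, 3, 10, 2),
            (5, 12, 6, 1), (11, 6, 12, 7)],
    "6_2": [(1, 4, 2, 5), (5, 10, 6, 11), (3, 9, 4, 8), (9, 3, 10, 2),
            (7, 12, 8, 1), (11, 6, 12, 7)],
    "6_3": [(4, 2, 5, 1), (8, 4, 9, 3), (12, 9, 1, 10), (10, 5, 11, 6),
            (6, 11, 7, 12), (2, 8, 3, 7)],
    "7_1": [(1, 8, 2, 9), (3, 10, 4, 11), (5, 12, 6, 13), (7, 14, 8, 1),
            (9, 2, 10, 3), (11, 4, 12, 5), (13, 6, 14, 7)],
}

_AMPHICHIRAL = {"4_1", "6_3"}


def _chirality_tag(jones: dict) -> str:
    """'right' when the polynomial is supported on positive powers of t
    (the convention under which positive-crossing torus knots are
    right-handed), else 'left'."""
    return "right" if sum(e for e in jones) > 0 else "left"


@lru_cache(maxsize=1)
def reference_table() -> tuple:
    """Reference (label, chirality, jones) entries for knots through
    seven crossings, generated from the standard minimal diagrams."""
    entries: list[tuple[str, str | None, tuple]] = [("0_1", None, ((0, 1),))]
    for label, pd in _PD_CODES.items():
        jones = jones_from_pd(pd)
        mirror = mirror_jones(jones)
        if label in _AMPHICHIRAL:
            if jones != mirror:
                raise AssertionError(f"{label} diagram is not amphichiral")
            entries.append((label, None, tuple(sorted(jones.items()))))
        else:
            for poly in (jones, mirror):
                entries.append(
                    (label, _chirality_tag(poly), tuple(sorted(poly.items())))
                )
    return tuple(entries)


def _lookup_jones(jones: dict) -> KnotClass:
    key = tuple(sorted(jones.items()))
    for label, chir, ref in reference_table():
        if key == ref:
            return KnotClass(label=label, chirality=chir, jones=jones)
    return KnotClass(label="unresolved", chirality=None, jones=jones)


def classify_knot(
    config: RingConfiguration,
    params=None,
    rng: np.random.Generator | None = None,
    auto_expand: bool = True,
    n_rotations: int = 1000,
    crossing_cap: int = 20,
) -> KnotClass:
    """Assign the knot type via minimal projection + Jones lookup.

    Any non-degenerate projection with at most ``crossing_cap``
    crossings determines the polynomial exactly, so a moderate number
    of rotations suffices.  Compact structures whose every projection
    exceeds the cap are expanded with the radial potential first
    (topology-preserving), then re-projected.
    """
    rng = np.random.default_rng() if rng is None else rng
    work = config
    for attempt in range(3):
        diag = minimal_diagram(work, n_rotations=n_rotations, rng=rng)
        if diag.n_crossings <= crossing_cap:
            return _lookup_jones(jones_polynomial(diag, crossing_cap))
        if not auto_expand:
            raise CrossingCapExceeded(
                f"{diag.n_crossings} crossings > cap {crossing_cap}"
            )
        from . import sampling  # local import: sampling depends on this module

        if params is None:
            raise ValueError("auto_expand requires potential params")
        work = sampling.expand(work, params)
    raise CrossingCapExceeded("expansion did not reduce crossings below cap")


# --- projection-averaged order parameters -----------------------------------

def _projection_samples(config, n_rotations, rng, func):
    """Evaluate func(coords_rot) over non-degenerate random projections."""
    rng = np.random.default_rng() if rng is None else rng
    vals = []
    attempts = 0
    while len(vals) < n_rotations and attempts < 20 * n_rotations:
        attempts += 1
        rot = random_rotation(rng)
        try:
            vals.append(func(config.coords @ rot.T))
        except DegenerateProjection:
            continue
    if not vals:
        raise DegenerateProjection("all projections degenerate")
    return np.asarray(vals, dtype=float)


def crossing_statistics(
    config: RingConfiguration,
    n_rotations: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean and SD of the per-projection crossing count."""
    if n_rotations < 2:
        raise ValueError("n_rotations must be >= 2")
    vals = _projection_samples(
        config, n_rotations, rng, lambda c: len(_projection_crossings(c)[4])
    )
    return float(vals.mean()), float(vals.std(ddof=1))


def writhe(
    config: RingConfiguration,
    n_rotations: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean and SD of the per-projection signed crossing sum.  The mean
    over uniform projection directions estimates the 3D (Gauss) writhe."""
    if n_rotations < 2:
        raise ValueError("n_rotations must be >= 2")
    vals = _projection_samples(
        config, n_rotations, rng, lambda c: _projection_crossings(c)[4].sum()
    )
    return float(vals.mean()), float(vals.std(ddof=1))


def gauss_writhe(config: RingConfiguration) -> float:
    """Deterministic 3D writhe via the pairwise solid-angle (Gauss
    integral) formula over non-adjacent segment pairs."""
    coords = config.coords
    n = config.n_beads
    i, j = _nonadjacent_pairs(n)
    p1, p2 = coords[i], coords[(i + 1) % n]
    p3, p4 = coords[j], coords[(j + 1) % n]
    r13, r14 = p3 - p1, p4 - p1
    r23, r24 = p3 - p2, p4 - p2
    r34, r12 = p4 - p3, p2 - p1

    def unit(v):
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        if np.any(norms < 1e-14):
            raise ValueError("intersecting or touching segments")
        return v / norms

    n1 = unit(np.cross(r13, r14))
    n2 = unit(np.cross(r14, r24))
    n3 = unit(np.cross(r24, r23))
    n4 = unit(np.cross(r23, r13))

    def asin_dot(a, b):
        return np.arcsin(np.clip((a * b).sum(axis=1), -1.0, 1.0))

    omega_star = (
        asin_dot(n1, n2) + asin_dot(n2, n3) + asin_dot(n3, n4) + asin_dot(n4, n1)
    )
    sign = np.sign((np.cross(r34, r12) * r13).sum(axis=1))
    return float((omega_star * sign).sum() / (2.0 * np.pi))


def winding_number_of_projection(
    config: RingConfiguration, rotation: np.ndarray | None = None
) -> float:
    """|sum of signed successive angles| / 2pi about the projected
    centroid, including the closing step from the last bead back to the
    first (the loop is closed)."""
    coords = config.coords - config.centroid()
    if rotation is not None:
        coords = coords @ rotation.T
    v = coords[:, :2]
    r = np.linalg.norm(v, axis=1)
    if np.any(r < 1e-12):
        raise DegenerateProjection("projected bead at the origin")
    v_next = np.roll(v, -1, axis=0)
    chi = np.arctan2(_cross2(v, v_next), (v * v_next).sum(axis=1))
    return float(abs(chi.sum()) / (2.0 * np.pi))


def winding_number(
    config: RingConfiguration,
    n_rotations: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean and SD of the winding number over random projections."""
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    vals = []
    attempts = 0
    while len(vals) < n_rotations and attempts < 20 * n_rotations:
        attempts += 1
        try:
            vals.append(winding_number_of_projection(config, random_rotation(rng)))
        except DegenerateProjection:
            continue
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd
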