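"""Transition-state searches and kinetic transition networks.

Candidate saddles between two aligned minima come from a doubly nudged
elastic band (DNEB): interior images are relaxed under the true
gradient perpendicular to the band tangent plus the spring gradient
along it, retaining the portion of the perpendicular spring gradient
orthogonal to the perpendicular true gradient (the "doubly nudged"
component that stabilises the band).  Band maxima are refined to
index-1 saddles by hybrid eigenvector-following: walk uphill along the
lowest non-zero Hessian eigenvector while minimising in the orthogonal
complement.  Each converged transition state is connected to its two
minima by steepest-descent paths started just off the saddle.

The network lumps permutationally related stationary points (energy
window + alignment distance) to one id, supports the missing-connection
selector for unfinished connection profiles, and Dijkstra fastest-path
queries with -ln(branching probability) edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .polymer_model import (
    PotentialParams,
    RingConfiguration,
    align,
    energy_and_gradient,
    hessian,
    zero_mode_threshold,
)
from .sampling import (
    MinimizerSettings,
    MinimumRecord,
    MinimizationFailure,
    minimize,
)

__all__ = [
    "TransitionStateRecord",
    "KineticTransitionNetwork",
    "SaddleSearchFailure",
    "BandCollapse",
    "dneb",
    "hybrid_ef",
    "ts_endpoints",
    "missing_connection",
    "fastest_path",
    "expansion_guided_connect",
    "connect_minima",
]


class SaddleSearchFailure(RuntimeError):
    pass


class BandCollapse(RuntimeError):
    pass


@dataclass
class TransitionStateRecord:
    """Index-1 saddle: exactly one negative Hessian eigenvalue beyond
    the zero-mode threshold; ``log_prod_pos_eig`` runs over the
    kappa - 1 positive eigenvalues."""

    id: int
    energy: float
    coords: np.ndarray | None
    log_prod_pos_eig: float
    neg_eigenvalue: float
    min_a: int
    min_b: int


@dataclass
class KineticTransitionNetwork:
    """Minima and the transition states that connect them, stored after
    permutational lumping (multi-edges allowed; a TS whose two
    steepest-descent endpoints lump to the same minimum is kept as a
    degenerate-rearrangement self-loop)."""

    minima: dict[int, MinimumRecord] = field(default_factory=dict)
    transition_states: dict[int, TransitionStateRecord] = field(default_factory=dict)
    energy_tol: float = 1e-6
    dist_tol: float = 1e-3

    def add_minimum(self, record: MinimumRecord) -> int:
        """Insert with lumping; returns the (possibly pre-existing) id."""
        found = self._find_minimum(record)
        if found is not None:
            return found
        new_id = max(self.minima, default=0) + 1
        record.id = new_id
        self.minima[new_id] = record
        return new_id

    def _find_minimum(self, record: MinimumRecord) -> int | None:
        for mid, m in self.minima.items():
            if abs(m.energy - record.energy) < self.energy_tol:
                d = align(
                    RingConfiguration(m.coords), RingConfiguration(record.coords)
                ).distance
                if d < self.dist_tol:
                    return mid
        return None

    def add_transition_state(self, record: TransitionStateRecord) -> int:
        for tid, ts in self.transition_states.items():
            if abs(ts.energy - record.energy) < self.energy_tol:
                d = align(
                    RingConfiguration(ts.coords), RingConfiguration(record.coords)
                ).distance
                if d < self.dist_tol:
                    return tid
        if record.min_a not in self.minima or record.min_b not in self.minima:
            raise ValueError("transition state references unknown minima")
        new_id = max(self.transition_states, default=0) + 1
        record.id = new_id
        self.transition_states[new_id] = record
        return new_id

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.minima)
        for tid, ts in self.transition_states.items():
            g.add_edge(ts.min_a, ts.min_b, key=tid, energy=ts.energy)
        return g

    def connected_pairs(self) -> set[frozenset]:
        return {
            frozenset((ts.min_a, ts.min_b))
            for ts in self.transition_states.values()
            if ts.min_a != ts.min_b
        }


# --- doubly nudged elastic band ---------------------------------------------

def dneb(
    min_a: RingConfiguration,
    min_b: RingConfiguration,
    params: PotentialParams,
    n_images: int = 15,
    spring_k: float = 10.0,
    max_iterations: int = 600,
    rms_tol: float = 5e-3,
) -> list[RingConfiguration]:
    """Relax a band between two minima; return interior images that are
    energy maxima along the band (transition-state candidates)."""
    res = align(min_a, min_b)
    from .polymer_model import apply_permutation, ring_permutations

    perm = None
    for off, rev, pm in ring_permutations(min_a.n_beads):
        if off == res.offset and rev == res.reversed:
            perm = pm
            break
    b = apply_permutation(min_b.coords - min_b.centroid(), perm) @ res.rotation.T
    a = min_a.coords - min_a.centroid()
    if np.linalg.norm(a - b) < 1e-8:
        return []
    n_total = n_images + 2
    ts = np.linspace(0.0, 1.0, n_total)[:, None, None]
    band = (1 - ts) * a[None] + ts * b[None]
    band = _relax_band(band, params, spring_k, max_iterations, rms_tol)
    energies = np.array(
        [energy_and_gradient(RingConfiguration(x), params)[0] for x in band]
    )
    cands = [
        RingConfiguration(band[i])
        for i in range(1, n_total - 1)
        if energies[i] >= energies[i - 1] and energies[i] >= energies[i + 1]
    ]
    return cands


def _dneb_force(x, params, spring_k):
    """DNEB force on every interior image (vectorised over the band),
    clipped per image so the hard-core wall of a bad initial
    interpolation cannot blow up the integrator."""
    from .polymer_model import batch_energy_gradient

    n_total = x.shape[0]
    m = n_total - 2
    _, grads = batch_energy_gradient(x[1:-1], params)
    g = grads.reshape(m, -1)
    tau = (x[2:] - x[:-2]).reshape(m, -1)
    tau /= np.linalg.norm(tau, axis=1, keepdims=True)
    g_par = (g * tau).sum(axis=1, keepdims=True)
    g_perp = g - g_par * tau
    gs = (-spring_k * (x[2:] - 2 * x[1:-1] + x[:-2])).reshape(m, -1)
    gs_par = (gs * tau).sum(axis=1, keepdims=True) * tau
    gs_perp = gs - gs_par
    npg = np.linalg.norm(g_perp, axis=1, keepdims=True)
    u = np.where(npg > 1e-12, g_perp / np.where(npg == 0, 1, npg), 0.0)
    gs_star = gs_perp - (gs_perp * u).sum(axis=1, keepdims=True) * u
    f = -(g_perp + gs_par + gs_star)
    fmax = np.abs(f).max(axis=1, keepdims=True)
    scale = np.where(fmax > 50.0, 50.0 / np.where(fmax == 0, 1, fmax), 1.0)
    f *= scale
    force = np.zeros_like(x)
    force[1:-1] = f.reshape(m, -1, 3)
    return force


def _relax_band(band, params, spring_k, max_iterations, rms_tol):
    """FIRE relaxation of the interior images under the DNEB force."""
    n_total = band.shape[0]
    x = band.copy()
    v = np.zeros_like(x)
    dt, dt_max = 0.01, 0.08
    alpha, alpha0 = 0.1, 0.1
    n_good = 0
    for _ in range(max_iterations):
        for i in range(1, n_total - 1):
            if np.linalg.norm(x[i + 1] - x[i]) < 1e-6 or \
               np.linalg.norm(x[i] - x[i - 1]) < 1e-6:
                raise BandCollapse("adjacent images collapsed")
        force = _dneb_force(x, params, spring_k)
        fnorm = np.sqrt((force[1:-1] ** 2).mean())
        if fnorm < rms_tol:
            break
        # FIRE update
        p = float((force * v).sum())
        if p > 0:
            n_good += 1
            if n_good > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
            fn = np.linalg.norm(force)
            vn = np.linalg.norm(v)
            if fn > 0:
                v = (1 - alpha) * v + alpha * vn * force / fn
        else:
            n_good = 0
            dt *= 0.5
            alpha = alpha0
            v[:] = 0.0
        v += dt * force
        step = dt * v
        smax = np.abs(step).max()
        if smax > 0.1:  # per-coordinate move cap
            step *= 0.1 / smax
        x += step
        x[0], x[-1] = band[0], band[-1]
    return x


# --- hybrid eigenvector-following ------------------------------------------

from .polymer_model import rigid_body_basis as _rigid_body_basis


def _lowest_mode(config: RingConfiguration, params: PotentialParams):
    """Lowest eigenpair of the Hessian with rigid-body modes projected
    out (they would otherwise contaminate the search direction)."""
    h = hessian(config, params)
    q = _rigid_body_basis(config.coords)
    p = np.eye(h.shape[0]) - q @ q.T
    shift = 10.0 * np.abs(h).max()
    hp = p @ h @ p + shift * (q @ q.T)
    lam, vec = np.linalg.eigh(hp)
    return float(lam[0]), vec[:, 0]


def hybrid_ef(
    candidate: RingConfiguration,
    params: PotentialParams,
    settings: MinimizerSettings | None = None,
    max_iterations: int = 300,
    trust_radius: float = 0.15,
) -> TransitionStateRecord:
    """Refine a candidate to an index-1 saddle.

    Alternates an uphill step along the lowest non-zero eigenvector
    (Newton when the curvature is negative, a bounded push otherwise)
    with minimisation of the gradient component orthogonal to that
    eigenvector.  Accepts only with exactly one negative eigenvalue.
    """
    settings = settings or MinimizerSettings()
    x = candidate.coords.copy()
    for _ in range(max_iterations):
        cfg = RingConfiguration(x)
        h = hessian(cfg, params)
        q = _rigid_body_basis(cfg.coords)
        p = np.eye(h.shape[0]) - q @ q.T
        shift = 10.0 * np.abs(h).max()
        lam, vec = np.linalg.eigh(p @ h @ p + shift * (q @ q.T))
        _, g = energy_and_gradient(cfg, params)
        gflat = g.ravel()
        rms = np.sqrt((gflat * gflat).mean())
        if rms < settings.rms_grad_tol and lam[0] < 0:
            break
        # uphill along the lowest non-zero mode, Newton downhill in the rest
        gv = vec.T @ gflat
        denom = np.abs(lam)
        denom[0] = max(denom[0], 1e-3)  # bounded uphill push in convex regions
        step = np.zeros_like(gv)
        step[0] = gv[0] / denom[0]
        step[1:] = -gv[1:] / np.maximum(denom[1:], 1e-8)
        dx = vec @ step
        norm = np.linalg.norm(dx)
        if norm > trust_radius:
            dx *= trust_radius / norm
        x = x + dx.reshape(-1, 3)
    else:
        raise SaddleSearchFailure("hybrid EF did not converge")
    return _accept_saddle(RingConfiguration(x), params)



def _accept_saddle(
    config: RingConfiguration, params: PotentialParams
) -> TransitionStateRecord:
    from .polymer_model import vibrational_spectrum

    energy, g = energy_and_gradient(config, params)
    lam = vibrational_spectrum(config, params)
    tol = zero_mode_threshold(lam)
    neg = lam[lam <= -tol]
    pos = lam[lam >= tol]
    if len(neg) != 1:
        raise SaddleSearchFailure(
            f"{len(neg)} negative eigenvalues (need exactly 1)"
        )
    if len(pos) != 3 * config.n_beads - 7:
        raise SaddleSearchFailure("unexpected zero-mode count at saddle")
    return TransitionStateRecord(
        id=-1,
        energy=float(energy),
        coords=config.coords.copy(),
        log_prod_pos_eig=float(np.log(pos).sum()),
        neg_eigenvalue=float(neg[0]),
        min_a=-1,
        min_b=-1,
    )


def ts_endpoints(
    ts: TransitionStateRecord,
    params: PotentialParams,
    settings: MinimizerSettings | None = None,
    delta: float = 0.01,
) -> tuple[MinimumRecord, MinimumRecord]:
    """Minima reached by steepest descent started +-delta along the
    negative-curvature eigenvector of the saddle."""
    cfg = RingConfiguration(ts.coords)
    _, v = _lowest_mode(cfg, params)
    recs = []
    for sgn in (+1.0, -1.0):
        start = RingConfiguration(ts.coords + sgn * delta * v.reshape(-1, 3))
        recs.append(minimize(start, params, settings))
    return recs[0], recs[1]


# --- network assembly and queries ------------------------------------------

def missing_connection(
    ktn: KineticTransitionNetwork, source: int, target: int,
    discouraged: set | None = None,
) -> list[tuple[int, int]]:
    """Unconnected minimum pairs on the current cheapest source-target
    path: Dijkstra on the complete graph where existing TS edges cost 0
    and absent edges cost the squared alignment distance.  Pairs in
    ``discouraged`` (e.g. already-failed searches) are up-weighted so
    alternative routes are proposed first."""
    if source not in ktn.minima or target not in ktn.minima:
        raise KeyError("source/target not in network")
    discouraged = discouraged or set()
    connected = ktn.connected_pairs()
    g = nx.Graph()
    ids = list(ktn.minima)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if frozenset((a, b)) in connected:
                w = 0.0
            else:
                d = align(
                    RingConfiguration(ktn.minima[a].coords),
                    RingConfiguration(ktn.minima[b].coords),
                ).distance
                w = d * d
                if frozenset((a, b)) in discouraged:
                    w *= 100.0
            g.add_edge(a, b, weight=w)
    path = nx.dijkstra_path(g, source, target)
    return [
        (a, b)
        for a, b in zip(path[:-1], path[1:])
        if frozenset((a, b)) not in connected
    ]


def fastest_path(
    ktn: KineticTransitionNetwork, a: int, b: int, temperature: float
):
    """Maximum-probability discrete path from a to b at the given
    temperature: Dijkstra with edge weights -ln(branching probability)
    built from harmonic TST rates.  Returns (alternating minimum/TS id
    sequence, barrier relative to V_a)."""
    from .observables import tst_rates

    rates = tst_rates(ktn, temperature)
    g = nx.DiGraph()
    g.add_nodes_from(ktn.minima)
    for (src, dst), k in rates.rate.items():
        p_branch = k * rates.waiting_time[src]
        if p_branch > 0:
            g.add_edge(src, dst, weight=-np.log(p_branch))
    try:
        path = nx.dijkstra_path(g, a, b)
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"minima {a} and {b} are not connected") from exc
    sequence: list[tuple[str, int]] = [("min", path[0])]
    barrier = 0.0
    for u, v in zip(path[:-1], path[1:]):
        best_ts = min(
            (
                ts
                for ts in ktn.transition_states.values()
                if {ts.min_a, ts.min_b} == {u, v}
            ),
            key=lambda t: t.energy,
        )
        barrier = max(barrier, best_ts.energy - ktn.minima[a].energy)
        sequence.append(("ts", best_ts.id))
        sequence.append(("min", v))
    return sequence, barrier


def expansion_guided_connect(
    min_a: RingConfiguration,
    min_b: RingConfiguration,
    params: PotentialParams,
    m: int = 10,
    rng: np.random.Generator | None = None,
) -> list[RingConfiguration]:
    """Anchor configurations for connecting hard minimum pairs.

    Both minima are expanded with the radial potential (saving frames),
    one frame sequence is reversed, and m evenly spaced configurations
    from the combined trajectory serve as successive double-ended
    search anchors.  Requires equal knot class (expansion never crosses
    the chain, so anchors inherit it)."""
    from . import knot_analysis as ka
    from .sampling import expand

    rng = np.random.default_rng(0) if rng is None else rng
    ka_a = ka.classify_knot(min_a, params, rng, n_rotations=300)
    ka_b = ka.classify_knot(min_b, params, rng, n_rotations=300)
    if ka_a.full_label != ka_b.full_label:
        raise ValueError(
            f"knot classes differ: {ka_a.full_label} vs {ka_b.full_label}"
        )
    if m < 2:
        raise ValueError("need at least the two expanded endpoints")
    _, frames_a, _ = expand(min_a, params, return_frames=True)
    _, frames_b, _ = expand(min_b, params, return_frames=True)
    combined = frames_a + frames_b[::-1]
    idx = np.linspace(0, len(combined) - 1, m).round().astype(int)
    return [combined[i] for i in idx]


def connect_minima(
    minima: list[MinimumRecord],
    params: PotentialParams,
    rng: np.random.Generator | None = None,
    settings: MinimizerSettings | None = None,
    max_rounds: int = 40,
) -> KineticTransitionNetwork:
    """Build a single-component network over the given minima.

    Repeatedly asks the missing-connection selector for the next gap on
    the cheapest path between the lowest minimum and each unreached
    one, then runs DNEB + hybrid EF + endpoint assignment on that gap.
    """
    ktn = KineticTransitionNetwork()
    ids = [ktn.add_minimum(m) for m in minima]
    targets = set(ids)
    lowest = min(ids, key=lambda i: ktn.minima[i].energy)
    tried: set[frozenset] = set()
    for _round in range(max_rounds):
        g = ktn.graph()
        comp = nx.node_connected_component(g, lowest)
        # only the input minima must reach the lowest one; incidental
        # minima discovered by endpoint assignment are kept as-is
        missing = [i for i in targets if i not in comp]
        if not missing:
            break
        boost = _round >= max_rounds // 2
        progressed = False
        for tgt in missing:
            pairs = missing_connection(ktn, lowest, tgt, discouraged=tried)
            for a, b in pairs:
                key = frozenset((a, b))
                if key in tried and not boost:
                    continue
                first_try = key not in tried
                tried.add(key)
                if _attempt_connection(
                    ktn, a, b, params, settings, boost=not first_try
                ):
                    progressed = True
            if progressed:
                break
        if not progressed and boost:
            break
    return ktn


def _attempt_connection(ktn, a, b, params, settings, boost=False) -> bool:
    cfg_a = RingConfiguration(ktn.minima[a].coords)
    cfg_b = RingConfiguration(ktn.minima[b].coords)
    try:
        if boost:
            candidates = dneb(cfg_a, cfg_b, params, n_images=31,
                              max_iterations=2000)
        else:
            candidates = dneb(cfg_a, cfg_b, params)
    except BandCollapse:
        return False
    added = False
    for cand in candidates:
        try:
            ts = hybrid_ef(cand, params, settings)
            ma, mb = ts_endpoints(ts, params, settings)
        except (SaddleSearchFailure, MinimizationFailure):
            continue
        ia = ktn.add_minimum(ma)
        ib = ktn.add_minimum(mb)
        if ts.energy < max(ktn.minima[ia].energy, ktn.minima[ib].energy) - 1e-9:
            continue  # inconsistent assignment; discard
        ts.min_a, ts.min_b = ia, ib
        ktn.add_transition_state(ts)
        added = True
    return added
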