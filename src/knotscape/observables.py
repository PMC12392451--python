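"""Harmonic-superposition thermodynamics and network kinetics.

The total partition function is a sum of per-minimum classical harmonic
contributions Z_g = w_g exp(-V_g/T) (2 pi T)^(kappa/2) / prod_i omega_i
with k_B = 1 and unit masses; the (2 pi T)^(kappa/2) factor and all
Planck/mass constants are common to every minimum of the same ring and
cancel in occupation probabilities, so only V_g, the degeneracy weight
w_g and the log-product of positive Hessian eigenvalues enter.

Heat capacity: C_V/k_B = kappa + (<V^2> - <V>^2)/T^2, equivalently
kappa + sum_g V_g dp_g/dT; both forms are computed and must agree.
Rates are harmonic transition-state theory,
k(T) = (1/2pi) exp([L_min - L_ts]/2) exp(-(E_ts - V_min)/T), which
satisfies detailed balance with the harmonic occupations.  Mean first
passage times use graph transformation (exact node elimination, stable
for barriers much larger than T); full first-passage-time distributions
use eigendecomposition of the absorbing-target master equation with a
graph-transformation fallback for a numerically lost slowest mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg

__all__ = [
    "OccupationResult",
    "ObservableSeries",
    "RateMatrix",
    "FPTResult",
    "occupations",
    "heat_capacity",
    "cv_decomposition",
    "tst_rates",
    "mfpt_graph_transform",
    "fpt_distribution",
    "n_vibrational_dof",
]


def n_vibrational_dof(minimum) -> int:
    """kappa = 3N - 6, recovered from the stored positive-eigenvalue
    count convention (log_prod_pos_eig runs over kappa eigenvalues)."""
    if minimum.coords is not None:
        return 3 * len(minimum.coords) - 6
    raise ValueError("cannot infer kappa without coordinates")


@dataclass
class OccupationResult:
    minima_ids: list
    p: np.ndarray        # occupation probabilities, sum = 1
    g: np.ndarray        # dp/dT, sum = 0


@dataclass
class ObservableSeries:
    temperatures: np.ndarray
    values: np.ndarray
    label: str = ""


@dataclass
class RateMatrix:
    """k_{dst<-src} under 'rate'; total escape rates and waiting times
    tau = 1/(total escape); branching probability = rate * tau."""

    ids: list
    rate: dict = field(default_factory=dict)          # (src, dst) -> k
    total_rate: dict = field(default_factory=dict)    # src -> sum k
    waiting_time: dict = field(default_factory=dict)  # src -> tau


@dataclass
class FPTResult:
    """p(theta) = sum_j a_j nu_j exp(-nu_j theta); P(ln theta) =
    theta p(theta).  sum a_j = 1 so the density is normalised; the mean
    is sum a_j / nu_j."""

    rates: np.ndarray       # nu_j > 0
    amplitudes: np.ndarray  # a_j
    slow_mode_recovered: bool = False

    def mean(self) -> float:
        return float((self.amplitudes / self.rates).sum())

    def density(self, theta: np.ndarray) -> np.ndarray:
        th = np.asarray(theta, dtype=float)[..., None]
        return (self.amplitudes * self.rates * np.exp(-self.rates * th)).sum(axis=-1)

    def log_density(self, ln_theta: np.ndarray) -> np.ndarray:
        """P(ln theta) = theta * p(theta) on a log-time axis."""
        th = np.exp(np.asarray(ln_theta, dtype=float))
        return th * self.density(th)

    def default_log_grid(self, n_points: int = 400) -> np.ndarray:
        tmin = 1.0 / self.rates.max()
        tmax = 1.0 / self.rates.min()
        return np.linspace(np.log(tmin / 1e3), np.log(tmax * 1e3), n_points)


# --- superposition thermodynamics ------------------------------------------

def _log_weights(minima, T: float) -> np.ndarray:
    return np.array(
        [np.log(m.weight) - m.energy / T - 0.5 * m.log_prod_pos_eig for m in minima]
    )


def occupations(minima, T: float) -> OccupationResult:
    """Normalised harmonic occupation probabilities and their analytic
    temperature gradients g_g = p_g (V_g - <V>)/T^2."""
    minima = list(minima)
    if not minima:
        raise ValueError("empty minima set")
    lw = _log_weights(minima, T)
    lw -= lw.max()
    w = np.exp(lw)
    p = w / w.sum()
    v = np.array([m.energy for m in minima])
    vbar = float(p @ v)
    g = p * (v - vbar) / T**2
    return OccupationResult(minima_ids=[m.id for m in minima], p=p, g=g)


def heat_capacity(minima, T_grid) -> ObservableSeries:
    """C_V(T)/k_B = kappa + (<V^2>-<V>^2)/T^2 over the temperature grid
    (moment form; the g-form decomposition is checked separately)."""
    minima = list(minima)
    T_grid = np.asarray(T_grid, dtype=float)
    if np.any(T_grid <= 0) or np.any(np.diff(T_grid) < 0):
        raise ValueError("T_grid must be positive and ascending")
    kappa = n_vibrational_dof(minima[0])
    v = np.array([m.energy for m in minima])
    out = np.empty_like(T_grid)
    for k, T in enumerate(T_grid):
        occ = occupations(minima, T)
        vbar = occ.p @ v
        var = occ.p @ (v - vbar) ** 2
        out[k] = kappa + var / T**2
    return ObservableSeries(temperatures=T_grid, values=out, label="Cv_over_kB")


def cv_decomposition(minima, T: float, fraction: float = 0.99):
    """Partition minima by the sign of g_g(T) and find the smallest
    subset reproducing >= fraction of the configurational C_V.

    Returns (positive_g_ids, negative_g_ids, minimal_subset_ids)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    minima = list(minima)
    occ = occupations(minima, T)
    v = np.array([m.energy for m in minima])
    contrib = v * occ.g  # per-minimum configurational Cv contribution
    total = contrib.sum()
    pos = [m.id for m, gg in zip(minima, occ.g) if gg > 0]
    neg = [m.id for m, gg in zip(minima, occ.g) if gg < 0]
    order = np.argsort(-np.abs(contrib))
    subset: list = []
    if total > 0:
        run = 0.0
        for idx in order:
            subset.append(minima[idx].id)
            run += contrib[idx]
            if run >= fraction * total:
                break
    return pos, neg, subset


# --- kinetics ---------------------------------------------------------------

def tst_rates(ktn, T: float) -> RateMatrix:
    """Harmonic TST rate constants, multi-edges between a pair summed.
    A TS below either endpoint minimum flags a corrupt database.
    Degenerate-rearrangement self-loops carry no inter-minimum flux and
    are excluded."""
    ids = list(ktn.minima)
    rm = RateMatrix(ids=ids)
    for ts in ktn.transition_states.values():
        a, b = ts.min_a, ts.min_b
        if a == b:
            continue
        va, vb = ktn.minima[a].energy, ktn.minima[b].energy
        if ts.energy < max(va, vb) - 1e-9:
            raise ValueError(
                f"transition state {ts.id} below an endpoint minimum"
            )
        for src, dst in ((a, b), (b, a)):
            m = ktn.minima[src]
            lnk = (
                0.5 * (m.log_prod_pos_eig - ts.log_prod_pos_eig)
                - (ts.energy - m.energy) / T
            )
            k = np.exp(lnk) / (2.0 * np.pi)
            rm.rate[(src, dst)] = rm.rate.get((src, dst), 0.0) + k
    for i in ids:
        tot = sum(k for (s, _), k in rm.rate.items() if s == i)
        rm.total_rate[i] = tot
        rm.waiting_time[i] = 1.0 / tot if tot > 0 else np.inf
    return rm


def _branching(rm: RateMatrix):
    """P[dst<-src] and waiting times tau_src."""
    p: dict = {}
    for (s, d), k in rm.rate.items():
        if rm.total_rate[s] > 0:
            p[(s, d)] = k / rm.total_rate[s]
    return p, dict(rm.waiting_time)


def mfpt_graph_transform(ktn, target: int, T: float) -> dict:
    """Mean first passage time to ``target`` from every other minimum by
    exact graph-transformation node elimination (order-invariant and
    stable for deep traps)."""
    rm = tst_rates(ktn, T)
    ids = [i for i in rm.ids]
    if target not in ids:
        raise KeyError("target not in network")
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from((s, d) for (s, d) in rm.rate)
    comp = nx.node_connected_component(g, target)
    missing = set(ids) - comp
    if missing:
        raise ValueError(f"minima not connected to target: {sorted(missing)}")
    out = {}
    for source in ids:
        if source == target:
            continue
        out[source] = _gt_single(rm, source, target)
    return out


def _gt_single(rm: RateMatrix, source: int, target: int) -> float:
    p, tau = _branching(rm)
    alive = [i for i in rm.ids if i not in (source, target)]
    p = dict(p)
    for x in alive:
        p, tau = _gt_eliminate(p, tau, x)
    # only source and the absorbing target remain, so the source's sole
    # escape channel is the direct jump: MFPT = tau_s / P(s -> t).  This
    # form avoids the catastrophic 1 - P_ss cancellation for deep traps.
    pst = p.get((source, target), 0.0)
    if pst <= 0.0:
        return np.inf
    return tau[source] / pst


def _gt_eliminate(p: dict, tau: dict, x):
    """Remove node x: P'_ba = P_ba + P_bx P_xa / (1 - P_xx),
    tau'_a = tau_a + P_xa tau_x / (1 - P_xx).

    The denominator 1 - P_xx is evaluated as the explicit sum of x's
    outgoing branching probabilities, which stays accurate when P_xx is
    within rounding of 1 (deep kinetic traps)."""
    out_edges = {d: q for (s, d), q in p.items() if s == x and d != x}
    in_edges = {s: q for (s, d), q in p.items() if d == x and s != x}
    denom = sum(out_edges.values())
    newp = {
        (s, d): q for (s, d), q in p.items() if s != x and d != x
    }
    newtau = {k: v for k, v in tau.items() if k != x}
    if denom <= 0.0:
        return newp, newtau  # x is a sink among the eliminated set
    for a, pxa in in_edges.items():
        newtau[a] = newtau[a] + pxa * tau[x] / denom
        for b, pbx in out_edges.items():
            key = (a, b)
            newp[key] = newp.get(key, 0.0) + pxa * pbx / denom
    return newp, newtau


def fpt_distribution(ktn, source: int, target: int, T: float) -> FPTResult:
    """First-passage-time distribution from a point source by
    eigendecomposition of the absorbing-target master equation.

    If the slowest relaxation is numerically degraded (amplitudes fail
    to normalise), its amplitude is recovered from the
    graph-transformation MFPT plus the normalisation condition."""
    rm = tst_rates(ktn, T)
    transient = [i for i in rm.ids if i != target]
    if source == target or source not in transient:
        raise ValueError("source must differ from target and be in the network")
    idx = {m: k for k, m in enumerate(transient)}
    n = len(transient)
    gen = np.zeros((n, n))
    for (s, d), k in rm.rate.items():
        if s == target:
            continue
        gen[idx[s], idx[s]] -= k
        if d != target:
            gen[idx[d], idx[s]] += k
    lam, vr = scipy.linalg.eig(gen)
    if np.abs(lam.imag).max() > 1e-8 * np.abs(lam.real).max():
        raise ValueError("rate matrix eigendecomposition not real")
    lam = lam.real
    vr = vr.real
    p0 = np.zeros(n)
    p0[idx[source]] = 1.0
    try:
        c = np.linalg.solve(vr, p0)
    except np.linalg.LinAlgError:
        c = np.linalg.lstsq(vr, p0, rcond=None)[0]
    ones = np.ones(n)
    amps = c * (ones @ vr)
    nu = -lam
    keep = nu > 0
    nu, amps = nu[keep], amps[keep]
    order = np.argsort(nu)
    nu, amps = nu[order], amps[order]
    recovered = False
    defect = 1.0 - amps.sum()
    if abs(defect) > 1e-8:
        # slowest mode lost to ill-conditioning: pin its amplitude with
        # the normalisation condition and the GT mean
        mfpt = _gt_single(rm, source, target)
        rest_mean = float((amps[1:] / nu[1:]).sum()) if len(nu) > 1 else 0.0
        a0 = defect + amps[0]
        nu0 = a0 / max(mfpt - rest_mean, 1e-300)
        nu = np.concatenate([[nu0], nu[1:]])
        amps = np.concatenate([[a0], amps[1:]])
        recovered = True
    return FPTResult(rates=nu, amplitudes=amps, slow_mode_recovered=recovered)
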