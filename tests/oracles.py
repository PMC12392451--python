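"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: finite
differences for derivatives, a recursive delooping evaluation of the
Kauffman bracket (versus the implementation's flat state sum), the
closed-form Jones polynomial of (2, q) torus knots, dense linear
algebra for mean hitting times, and brute-force path enumeration.
"""

import numpy as np

from knotscape.polymer_model import RingConfiguration, total_energy, gradient


# --- finite differences -----------------------------------------------------

def fd_gradient(config, params, h=1e-6):
    coords = config.coords
    out = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(3):
            cp = coords.copy()
            cm = coords.copy()
            cp[i, k] += h
            cm[i, k] -= h
            out[i, k] = (
                total_energy(RingConfiguration(cp), params)
                - total_energy(RingConfiguration(cm), params)
            ) / (2 * h)
    return out


def fd_hessian(config, params, h=1e-6):
    coords = config.coords
    n3 = coords.size
    out = np.zeros((n3, n3))
    for j in range(n3):
        cp = coords.copy().ravel()
        cm = cp.copy()
        cp[j] += h
        cm[j] -= h
        gp = gradient(RingConfiguration(cp.reshape(-1, 3)), params).ravel()
        gm = gradient(RingConfiguration(cm.reshape(-1, 3)), params).ravel()
        out[:, j] = (gp - gm) / (2 * h)
    return out


# --- brute-force pair summation --------------------------------------------

def brute_force_energy(config, params):
    """Term-by-term double loop, no vectorisation shared with the
    implementation."""
    n = config.n_beads
    c = config.coords
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(c[i] - c[j]))
            bonded = (j - i == 1) or (i == 0 and j == n - 1)
            if bonded:
                e += 0.5 * params.k_spring * (r - params.r0) ** 2
            else:
                sr6 = (params.sigma / r) ** 6
                e += 4.0 * params.epsilon * (sr6 * sr6 - sr6)
    return e


# --- recursive Kauffman bracket (delooping) ---------------------------------

def _merge_arcs(pairing, arcs):
    """Given current arc-connection pairs, count closed loops."""
    adj = {}
    for a, b in pairing:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seen = set()
    loops = 0
    for start in arcs:
        if start in seen:
            continue
        loops += 1
        stack = [start]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj.get(x, []))
    return loops


def recursive_bracket(crossings):
    """Kauffman bracket by explicit recursion over crossings with
    delooping at the leaves; input format matches the implementation's
    per-crossing combinatorics (sign, o_in, o_out, u_in, u_out)."""
    arcs = set()
    for _, o_in, o_out, u_in, u_out in crossings:
        arcs.update((o_in, o_out, u_in, u_out))

    def rec(idx, pairing, exp):
        if idx == len(crossings):
            loops = _merge_arcs(pairing, arcs)
            term = {}
            # d^(loops-1) with d = -A^2 - A^-2
            poly = {0: 1}
            for _ in range(loops - 1):
                nxt = {}
                for e, c in poly.items():
                    for de, dc in ((2, -1), (-2, -1)):
                        nxt[e + de] = nxt.get(e + de, 0) + c * dc
                poly = nxt
            for e, c in poly.items():
                term[e + exp] = term.get(e + exp, 0) + c
            return term
        sign, o_in, o_out, u_in, u_out = crossings[idx]
        if sign > 0:
            a_pairs = [(o_in, u_out), (o_out, u_in)]
            b_pairs = [(o_in, u_in), (o_out, u_out)]
        else:
            a_pairs = [(o_in, u_in), (o_out, u_out)]
            b_pairs = [(o_in, u_out), (o_out, u_in)]
        out = {}
        for br, dexp in ((a_pairs, +1), (b_pairs, -1)):
            sub = rec(idx + 1, pairing + br, exp + dexp)
            for e, c in sub.items():
                out[e] = out.get(e, 0) + c
        return {e: c for e, c in out.items() if c != 0}

    return rec(0, [], 0)


def jones_via_recursion(crossings):
    w = sum(c[0] for c in crossings)
    bracket = recursive_bracket(crossings)
    sign = -1 if (3 * w) % 2 else 1
    out = {}
    for e, c in bracket.items():
        e2 = e - 3 * w
        assert e2 % 4 == 0
        out[-e2 // 4] = out.get(-e2 // 4, 0) + sign * c
    return {e: c for e, c in out.items() if c != 0}


def torus_jones(q: int) -> dict:
    """Closed-form Jones polynomial of the right-handed (2, q) torus
    knot: t^((q-1)/2) (1 - t^3 - t^(q+1) + t^(q+2)) / (1 - t^2),
    expanded exactly over the integers."""
    # polynomial long division of the numerator by (1 - t^2)
    num = {0: 1, 3: -1, q + 1: -1, q + 2: 1}
    den_shift, den = 2, -1  # 1 - t^2: leading handling below
    # synthetic division: f(t) / (1 - t^2) with ascending powers
    out = {}
    work = dict(num)
    for e in range(0, max(work) + 1):
        c = work.get(e, 0)
        if c == 0:
            continue
        out[e] = out.get(e, 0) + c
        work[e] = 0
        work[e + 2] = work.get(e + 2, 0) + c
    assert all(v == 0 for v in work.values()), "division not exact"
    shift = (q - 1) // 2
    return {e + shift: c for e, c in out.items() if c != 0}


# --- kinetics oracles -------------------------------------------------------

def hitting_times_linear_solve(ktn, target, T):
    """Mean first passage times by dense solve of the fundamental
    equations K t = -1 on the transient generator."""
    from knotscape.observables import tst_rates

    rm = tst_rates(ktn, T)
    transient = [i for i in rm.ids if i != target]
    idx = {m: k for k, m in enumerate(transient)}
    n = len(transient)
    gen = np.zeros((n, n))
    for (s, d), k in rm.rate.items():
        if s == target:
            continue
        gen[idx[s], idx[s]] -= k
        if d != target:
            gen[idx[d], idx[s]] += k
    t = np.linalg.solve(gen.T, -np.ones(n))
    return {m: t[idx[m]] for m in transient}


def enumerate_best_path(ktn, a, b, T):
    """Max-probability path by exhaustive simple-path enumeration."""
    from knotscape.observables import tst_rates

    rm = tst_rates(ktn, T)
    ids = list(ktn.minima)
    best = (None, -np.inf)
    import networkx as nx

    g = nx.DiGraph()
    for (s, d), k in rm.rate.items():
        g.add_edge(s, d)
    for path in nx.all_simple_paths(g, a, b):
        logp = 0.0
        ok = True
        for u, v in zip(path[:-1], path[1:]):
            k = rm.rate.get((u, v), 0.0)
            if k <= 0:
                ok = False
                break
            logp += np.log(k * rm.waiting_time[u])
        if ok and logp > best[1]:
            best = (path, logp)
    return best
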