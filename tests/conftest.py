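import numpy as np
import pytest

from knotscape import sampling
from knotscape.io_cli import make_circle, make_torus_knot
from knotscape.polymer_model import PotentialParams, RingConfiguration
from knotscape.sampling import MinimumRecord
from knotscape.transition_network import (
    KineticTransitionNetwork,
    TransitionStateRecord,
)


@pytest.fixture(scope="session")
def params():
    return PotentialParams()


def random_ring(n: int, seed: int, scale: float = 0.15) -> RingConfiguration:
    """A circle with random bead displacements: valid, non-degenerate,
    and with all nonbonded pairs well separated."""
    rng = np.random.default_rng(seed)
    base = make_circle(n)
    return RingConfiguration(base.coords + rng.normal(scale=scale, size=(n, 3)))


@pytest.fixture(scope="session")
def trefoil30_minimum(params):
    """Relaxed N=30 trefoil ring (shared: minimisation is not free)."""
    return sampling.minimize(make_torus_knot(2, 3, 30), params)


@pytest.fixture(scope="session")
def trefoil40_minimum(params):
    return sampling.minimize(make_torus_knot(2, 3, 40), params)


@pytest.fixture(scope="session")
def n12_minima(params):
    """A few distinct N=12 minima from a short unrestricted basin-hop."""
    res = sampling.basin_hop(
        make_circle(12),
        params,
        sampling.BasinHoppingSettings(
            max_step=1.0, n_steps=60, move_kind="unrestricted", seed=4
        ),
    )
    return sorted(res.minima, key=lambda m: m.energy)


@pytest.fixture(scope="session")
def n12_ktn(n12_minima, params):
    from knotscape.transition_network import connect_minima

    return connect_minima(n12_minima[:3], params, rng=np.random.default_rng(1))


def synthetic_network(
    energies, ts_specs, kappa: int = 24, seed: int = 0
) -> KineticTransitionNetwork:
    """Hand-built network for kinetics/thermodynamics tests (synthetic:
    records carry fabricated harmonic summaries, no coordinates).

    ts_specs: iterable of (energy, min_a, min_b) with 1-based ids.
    """
    rng = np.random.default_rng(seed)
    ktn = KineticTransitionNetwork()
    for i, e in enumerate(energies, start=1):
        ktn.minima[i] = MinimumRecord(
            id=i,
            energy=float(e),
            coords=np.zeros((10, 3)),
            log_prod_pos_eig=float(rng.uniform(5.0, 8.0)),
            weight=20.0,
        )
    for j, (e, a, b) in enumerate(ts_specs, start=1):
        ktn.transition_states[j] = TransitionStateRecord(
            id=j,
            energy=float(e),
            coords=None,
            log_prod_pos_eig=float(rng.uniform(5.0, 8.0)),
            neg_eigenvalue=-1.0,
            min_a=a,
            min_b=b,
        )
    return ktn


def random_connected_network(n_nodes: int, seed: int) -> KineticTransitionNetwork:
    """Random connected network with consistent TS energies above their
    endpoint minima."""
    rng = np.random.default_rng(seed)
    energies = rng.uniform(-10.0, -5.0, size=n_nodes)
    ts = []
    order = rng.permutation(n_nodes)
    for k in range(1, n_nodes):  # random spanning tree keeps it connected
        a = int(order[k]) + 1
        b = int(order[rng.integers(0, k)]) + 1
        barrier = rng.uniform(0.5, 3.0)
        ts.append((max(energies[a - 1], energies[b - 1]) + barrier, a, b))
    for _ in range(n_nodes):
        a, b = rng.integers(1, n_nodes + 1, size=2)
        if a == b:
            continue
        barrier = rng.uniform(0.5, 3.0)
        ts.append((max(energies[a - 1], energies[b - 1]) + barrier, int(a), int(b)))
    return synthetic_network(energies, ts, seed=seed)
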