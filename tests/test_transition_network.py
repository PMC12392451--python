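import networkx as nx
import numpy as np
import pytest

from knotscape import sampling, transition_network as tn
from knotscape.polymer_model import RingConfiguration, align, hessian, \
    zero_mode_threshold
from knotscape.sampling import MinimumRecord

from .conftest import synthetic_network
from .oracles import enumerate_best_path


@pytest.fixture(scope="module")
def n12_ts(n12_minima, params):
    """One converged transition state between the two lowest N=12 minima."""
    a = RingConfiguration(n12_minima[0].coords)
    b = RingConfiguration(n12_minima[1].coords)
    cands = tn.dneb(a, b, params, max_iterations=1000)
    assert cands
    return tn.hybrid_ef(cands[0], params), cands


class TestDneb:
    def test_identical_endpoints_no_candidates(self, params, n12_minima):
        a = RingConfiguration(n12_minima[0].coords)
        rolled = RingConfiguration(np.roll(a.coords, 3, axis=0))
        assert tn.dneb(a, rolled, params) == []

    def test_candidate_energy_above_endpoints(self, params, n12_minima):
        from knotscape.polymer_model import energy_and_gradient

        a = RingConfiguration(n12_minima[0].coords)
        b = RingConfiguration(n12_minima[1].coords)
        cands = tn.dneb(a, b, params)
        assert len(cands) >= 1
        emax = max(n12_minima[0].energy, n12_minima[1].energy)
        for c in cands:
            assert energy_and_gradient(c, params)[0] >= emax

    def test_refined_ts_stays_near_band_maximum(self, params, n12_ts):
        ts, cands = n12_ts
        d = min(
            align(RingConfiguration(ts.coords), c).distance for c in cands
        )
        assert d < 0.5


class TestHybridEF:
    def test_fixed_point_at_known_ts(self, params, n12_ts):
        ts, _ = n12_ts
        again = tn.hybrid_ef(RingConfiguration(ts.coords), params)
        assert again.energy == pytest.approx(ts.energy, abs=1e-8)
        assert align(
            RingConfiguration(again.coords), RingConfiguration(ts.coords)
        ).distance < 1e-3

    def test_exactly_one_negative_eigenvalue(self, params, n12_ts):
        ts, _ = n12_ts
        lam = np.linalg.eigvalsh(hessian(RingConfiguration(ts.coords), params))
        tol = zero_mode_threshold(lam)
        assert (lam <= -tol).sum() == 1
        assert ts.neg_eigenvalue < 0

    def test_ts_energy_consistent_with_band_estimate(
        self, params, n12_minima, n12_ts
    ):
        # the saddle sits above both endpoint minima and close to the
        # discrete band maximum (which brackets it only to image
        # resolution), and its descent paths recover the two endpoints
        from knotscape.polymer_model import energy_and_gradient

        ts, cands = n12_ts
        band_max = max(energy_and_gradient(c, params)[0] for c in cands)
        assert max(n12_minima[0].energy, n12_minima[1].energy) - 1e-9 <= ts.energy
        assert abs(ts.energy - band_max) < 0.1
        ma, mb = tn.ts_endpoints(ts, params)
        found = sorted([round(ma.energy, 6), round(mb.energy, 6)])
        expected = sorted(
            [round(n12_minima[0].energy, 6), round(n12_minima[1].energy, 6)]
        )
        assert found == expected


class TestTsEndpoints:
    def test_endpoint_energies_below_ts(self, params, n12_ts):
        ts, _ = n12_ts
        ma, mb = tn.ts_endpoints(ts, params)
        assert ma.energy < ts.energy and mb.energy < ts.energy

    def test_endpoints_robust_to_delta(self, params, n12_ts):
        ts, _ = n12_ts
        ref = None
        for delta in (0.005, 0.01, 0.02):
            ma, mb = tn.ts_endpoints(ts, params, delta=delta)
            pair = tuple(sorted([round(ma.energy, 6), round(mb.energy, 6)]))
            if ref is None:
                ref = pair
            assert pair == ref


class TestNetworkAssembly:
    def test_permutational_copy_lumped(self, n12_minima):
        ktn = tn.KineticTransitionNetwork()
        m = n12_minima[0]
        i1 = ktn.add_minimum(
            MinimumRecord(-1, m.energy, m.coords.copy(), m.log_prod_pos_eig, m.weight)
        )
        rolled = np.roll(m.coords, 5, axis=0)
        i2 = ktn.add_minimum(
            MinimumRecord(-1, m.energy, rolled, m.log_prod_pos_eig, m.weight)
        )
        assert i1 == i2
        assert len(ktn.minima) == 1

    def test_monotone_growth(self, n12_minima):
        ktn = tn.KineticTransitionNetwork()
        counts = []
        for m in n12_minima:
            ktn.add_minimum(
                MinimumRecord(-1, m.energy, m.coords.copy(),
                              m.log_prod_pos_eig, m.weight)
            )
            counts.append(len(ktn.minima))
        assert counts == sorted(counts)

    def test_lumping_order_independent(self, n12_minima):
        records = []
        for m in n12_minima:
            for roll in (0, 3, 7):
                records.append(
                    MinimumRecord(-1, m.energy, np.roll(m.coords, roll, axis=0),
                                  m.log_prod_pos_eig, m.weight)
                )
        sizes = set()
        for perm_seed in range(3):
            order = np.random.default_rng(perm_seed).permutation(len(records))
            ktn = tn.KineticTransitionNetwork()
            for k in order:
                r = records[k]
                ktn.add_minimum(
                    MinimumRecord(-1, r.energy, r.coords.copy(),
                                  r.log_prod_pos_eig, r.weight)
                )
            sizes.add(len(ktn.minima))
        assert sizes == {len(n12_minima)}


class TestMissingConnection:
    def _chain_network(self):
        """Five fabricated minima along a 1-parameter deformation; TSs
        cover 1-2, 2-3 and 4-5, leaving the 3-4 gap."""
        from knotscape.io_cli import make_circle

        base = make_circle(10)
        rng = np.random.default_rng(0)
        direction = rng.normal(size=(10, 3))
        direction /= np.linalg.norm(direction)
        ktn = tn.KineticTransitionNetwork()
        for i in range(5):
            coords = base.coords + 0.4 * i * direction
            ktn.minima[i + 1] = MinimumRecord(i + 1, -10.0 + i, coords, 5.0, 20.0)
        for tid, (a, b) in enumerate([(1, 2), (2, 3), (4, 5)], start=1):
            ktn.transition_states[tid] = tn.TransitionStateRecord(
                tid, 0.0, None, 5.0, -1.0, a, b
            )
        return ktn

    def test_already_connected_pair_empty(self):
        ktn = self._chain_network()
        assert tn.missing_connection(ktn, 1, 3) == []

    def test_two_isolated_minima_returns_that_pair(self):
        from knotscape.io_cli import make_circle

        ktn = tn.KineticTransitionNetwork()
        base = make_circle(10)
        ktn.minima[1] = MinimumRecord(1, -1.0, base.coords.copy(), 5.0, 20.0)
        other = base.coords.copy()
        other[0] += np.array([0.3, 0.0, 0.0])
        ktn.minima[2] = MinimumRecord(2, -1.0, other, 5.0, 20.0)
        assert tn.missing_connection(ktn, 1, 2) == [(1, 2)]

    def test_single_gap_identified(self):
        ktn = self._chain_network()
        assert tn.missing_connection(ktn, 1, 5) == [(3, 4)]


class TestFastestPath:
    def test_two_minima_one_ts(self):
        ktn = synthetic_network([-10.0, -9.0], [(-7.0, 1, 2)])
        seq, barrier = tn.fastest_path(ktn, 1, 2, 0.5)
        assert seq == [("min", 1), ("ts", 1), ("min", 2)]
        assert barrier == pytest.approx(3.0)

    def test_matches_exhaustive_enumeration(self):
        rngspec = [
            ([-10, -9.5, -9, -8.5, -8], [(-7, 1, 2), (-6, 2, 3), (-7.5, 3, 4),
                                         (-5, 4, 5), (-6.5, 1, 5), (-4, 2, 5)]),
            ([-10, -9, -8, -7], [(-6, 1, 2), (-5.5, 2, 3), (-5, 3, 4),
                                 (-4, 1, 4), (-3, 1, 3)]),
        ]
        for energies, ts in rngspec:
            ktn = synthetic_network(energies, ts)
            a, b = 1, len(energies)
            seq, _ = tn.fastest_path(ktn, a, b, 0.7)
            got = [i for kind, i in seq if kind == "min"]
            best_path, _ = enumerate_best_path(ktn, a, b, 0.7)
            assert got == best_path

    def test_barrier_nonnegative(self):
        ktn = synthetic_network([-10.0, -9.0, -8.0], [(-7.0, 1, 2), (-6.0, 2, 3)])
        _, barrier = tn.fastest_path(ktn, 1, 3, 0.4)
        assert barrier >= 0

    def test_disconnected_raises(self):
        ktn = synthetic_network([-10.0, -9.0, -5.0], [(-7.0, 1, 2)])
        with pytest.raises(ValueError):
            tn.fastest_path(ktn, 1, 3, 0.4)


class TestExpansionGuidedConnect:
    def test_anchor_endpoints_and_count(self, params, trefoil30_minimum):
        rng = np.random.default_rng(5)
        cfg = RingConfiguration(trefoil30_minimum.coords)
        other = sampling.perturb(cfg, 0.05, rng)
        other = RingConfiguration(sampling.minimize(other, params).coords)
        anchors = tn.expansion_guided_connect(cfg, other, params, m=4, rng=rng)
        assert len(anchors) == 4
        assert align(anchors[0], cfg).distance < 1e-3
        assert align(anchors[-1], other).distance < 1e-3

    def test_m2_returns_expanded_endpoints(self, params, trefoil30_minimum):
        rng = np.random.default_rng(6)
        cfg = RingConfiguration(trefoil30_minimum.coords)
        anchors = tn.expansion_guided_connect(cfg, cfg.copy(), params, m=2, rng=rng)
        assert len(anchors) == 2

    def test_anchors_share_knot_class(self, params, trefoil30_minimum):
        from knotscape import knot_analysis as ka

        rng = np.random.default_rng(7)
        cfg = RingConfiguration(trefoil30_minimum.coords)
        anchors = tn.expansion_guided_connect(cfg, cfg.copy(), params, m=3, rng=rng)
        for a in anchors:
            kc = ka.classify_knot(a, params, rng, n_rotations=200)
            assert kc.label == "3_1"

    def test_knot_class_mismatch_rejected(self, params, trefoil30_minimum):
        from knotscape.io_cli import make_circle

        rng = np.random.default_rng(8)
        cfg = RingConfiguration(trefoil30_minimum.coords)
        circle = RingConfiguration(
            sampling.minimize(make_circle(30), params).coords
        )
        with pytest.raises(ValueError):
            tn.expansion_guided_connect(cfg, circle, params, rng=rng)


class TestConnectMinima:
    def test_network_single_component_and_invariants(self, n12_ktn):
        g = n12_ktn.graph()
        assert nx.number_connected_components(g) == 1
        for ts in n12_ktn.transition_states.values():
            ea = n12_ktn.minima[ts.min_a].energy
            eb = n12_ktn.minima[ts.min_b].energy
            assert ts.energy >= max(ea, eb) - 1e-9

    def test_reachability_symmetric(self, n12_ktn):
        g = n12_ktn.graph()
        ids = list(n12_ktn.minima)
        for a in ids:
            for b in ids:
                assert nx.has_path(g, a, b) == nx.has_path(g, b, a)
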