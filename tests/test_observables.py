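import numpy as np
import pytest

from knotscape import observables as obs
from knotscape.sampling import MinimumRecord

from .conftest import random_connected_network, synthetic_network
from .oracles import hitting_times_linear_solve


def mk_min(mid, energy, logprod=6.0, weight=20.0, n_beads=10):
    return MinimumRecord(
        id=mid, energy=energy, coords=np.zeros((n_beads, 3)),
        log_prod_pos_eig=logprod, weight=weight,
    )


class TestOccupations:
    def test_single_minimum(self):
        r = obs.occupations([mk_min(1, -5.0)], 0.7)
        assert r.p[0] == 1.0 and r.g[0] == 0.0

    def test_two_identical_minima_split_evenly(self):
        r = obs.occupations([mk_min(1, -5.0), mk_min(2, -5.0)], 0.9)
        assert np.allclose(r.p, 0.5)
        assert np.allclose(r.g, 0.0)

    def test_boltzmann_ratio_equal_curvatures(self):
        for T in (0.3, 1.0, 2.5):
            r = obs.occupations([mk_min(1, 0.0), mk_min(2, 1.0)], T)
            assert r.p[1] / r.p[0] == pytest.approx(np.exp(-1.0 / T), rel=1e-12)

    def test_normalisation_and_gradient_sum(self):
        rng = np.random.default_rng(0)
        minima = [mk_min(i, rng.uniform(-10, -5), rng.uniform(4, 8))
                  for i in range(30)]
        for T in (0.1, 0.5, 2.0):
            r = obs.occupations(minima, T)
            assert abs(r.p.sum() - 1.0) < 1e-12
            assert abs(r.g.sum()) < 1e-12

    def test_gradient_matches_finite_difference(self):
        minima = [mk_min(1, -8.0, 5.0), mk_min(2, -7.0, 6.5), mk_min(3, -6.0, 4.5)]
        T, h = 0.8, 1e-6
        g = obs.occupations(minima, T).g
        fd = (obs.occupations(minima, T + h).p
              - obs.occupations(minima, T - h).p) / (2 * h)
        assert np.abs(g - fd).max() < 1e-6

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            obs.occupations([], 1.0)

    def test_epsilon_temperature_scaling_leaves_occupations_unchanged(self):
        # scaling all energies by s and T by s is an exact invariance
        minima = [mk_min(1, -8.0, 5.0), mk_min(2, -7.2, 6.0), mk_min(3, -6.1, 5.5)]
        s = 1.15
        scaled = [mk_min(m.id, s * m.energy, m.log_prod_pos_eig) for m in minima]
        p0 = obs.occupations(minima, 0.6).p
        p1 = obs.occupations(scaled, s * 0.6).p
        assert np.abs(p0 - p1).max() < 1e-12


class TestHeatCapacity:
    def test_single_minimum_is_kappa(self):
        series = obs.heat_capacity([mk_min(1, -5.0)], np.linspace(0.1, 3, 20))
        assert np.allclose(series.values, 3 * 10 - 6)

    def test_two_minimum_peak_matches_numerical_differentiation(self):
        minima = [mk_min(1, 0.0), mk_min(2, 1.0)]
        grid = np.linspace(0.1, 1.5, 400)
        series = obs.heat_capacity(minima, grid)
        kappa = 24
        # oracle: Cv_config = d<V>/dT by central differences
        h = 1e-5
        for T in (0.2, 0.4, 0.6):
            def vbar(t):
                r = obs.occupations(minima, t)
                return float(r.p @ np.array([0.0, 1.0]))

            cv_num = (vbar(T + h) - vbar(T - h)) / (2 * h)
            r = obs.occupations(minima, T)
            cv_ana = float(np.array([0.0, 1.0]) @ r.g)
            assert cv_ana == pytest.approx(cv_num, abs=1e-4)
        # peak position agreement between the two forms
        idx = np.argmax(series.values)
        gvals = [
            float(np.array([0.0, 1.0]) @ obs.occupations(minima, t).g)
            for t in grid
        ]
        assert idx == int(np.argmax(gvals))
        assert np.all(series.values >= kappa)

    def test_decomposition_identity_on_random_databases(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            minima = [
                mk_min(i, rng.uniform(-12, -6), rng.uniform(4, 9))
                for i in range(40)
            ]
            kappa = 24
            for T in (0.2, 0.7, 1.9):
                occ = obs.occupations(minima, T)
                v = np.array([m.energy for m in minima])
                g_form = kappa + float(v @ occ.g)
                series = obs.heat_capacity(minima, np.array([T]))
                assert g_form == pytest.approx(series.values[0], abs=1e-8)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            obs.heat_capacity([mk_min(1, -5.0)], np.array([-0.1, 0.5]))


class TestCvDecomposition:
    def test_single_minimum_empty_configurational_part(self):
        pos, neg, subset = obs.cv_decomposition([mk_min(1, -5.0)], 0.5)
        assert subset == []

    def test_two_minimum_sign_partition(self):
        pos, neg, subset = obs.cv_decomposition(
            [mk_min(1, 0.0), mk_min(2, 1.0)], 0.4
        )
        assert len(pos) == 1 and len(neg) == 1
        assert set(subset) <= {1, 2} and subset

    def test_subset_reproduces_fraction(self):
        rng = np.random.default_rng(2)
        minima = [mk_min(i, rng.uniform(-12, -6), rng.uniform(4, 9))
                  for i in range(50)]
        T = 0.8
        occ = obs.occupations(minima, T)
        v = np.array([m.energy for m in minima])
        contrib = dict(zip([m.id for m in minima], v * occ.g))
        total = sum(contrib.values())
        _, _, subset = obs.cv_decomposition(minima, T, fraction=0.99)
        assert sum(contrib[i] for i in subset) >= 0.99 * total


class TestTstRates:
    def test_detailed_balance(self):
        ktn = random_connected_network(12, seed=3)
        T = 0.6
        rm = obs.tst_rates(ktn, T)
        occ = obs.occupations(ktn.minima.values(), T)
        peq = dict(zip([m.id for m in ktn.minima.values()], occ.p))
        for (s, d), k in rm.rate.items():
            back = rm.rate[(d, s)]
            assert k * peq[s] == pytest.approx(back * peq[d], rel=1e-10)

    def test_rates_increase_with_temperature(self):
        ktn = synthetic_network([-10.0, -9.0], [(-7.0, 1, 2)])
        ks = [obs.tst_rates(ktn, T).rate[(1, 2)] for T in (0.3, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_symmetric_double_well(self):
        ktn = synthetic_network([-10.0, -10.0], [(-7.0, 1, 2)])
        # force equal curvatures
        lp = 6.0
        for m in ktn.minima.values():
            m.log_prod_pos_eig = lp
        rm = obs.tst_rates(ktn, 0.7)
        assert rm.rate[(1, 2)] == pytest.approx(rm.rate[(2, 1)], rel=1e-12)

    def test_ts_below_endpoint_rejected(self):
        ktn = synthetic_network([-10.0, -5.0], [(-7.0, 1, 2)])
        with pytest.raises(ValueError):
            obs.tst_rates(ktn, 0.5)

    def test_multi_edge_rates_sum(self):
        one = synthetic_network([-10.0, -9.0], [(-7.0, 1, 2)], seed=5)
        two = synthetic_network([-10.0, -9.0], [(-7.0, 1, 2), (-7.0, 1, 2)], seed=5)
        for ktn in (one, two):
            for ts in ktn.transition_states.values():
                ts.log_prod_pos_eig = 6.0
        k1 = obs.tst_rates(one, 0.5).rate[(1, 2)]
        k2 = obs.tst_rates(two, 0.5).rate[(1, 2)]
        assert k2 == pytest.approx(2 * k1, rel=1e-12)


class TestGraphTransformMFPT:
    def test_two_state_closed_form(self):
        ktn = synthetic_network([-10.0, -9.0], [(-7.0, 1, 2)])
        T = 0.5
        rm = obs.tst_rates(ktn, T)
        mfpt = obs.mfpt_graph_transform(ktn, 1, T)
        assert mfpt[2] == pytest.approx(1.0 / rm.rate[(2, 1)], rel=1e-12)

    @pytest.mark.parametrize("n,seed", [(10, 1), (25, 2), (50, 3)])
    def test_matches_dense_linear_solve(self, n, seed):
        ktn = random_connected_network(n, seed=seed)
        T = 0.8
        target = min(ktn.minima, key=lambda i: ktn.minima[i].energy)
        gt = obs.mfpt_graph_transform(ktn, target, T)
        lin = hitting_times_linear_solve(ktn, target, T)
        for m, v in gt.items():
            assert v == pytest.approx(lin[m], rel=1e-8)

    def test_elimination_order_invariance(self):
        ktn = random_connected_network(15, seed=7)
        T = 0.6
        rm = obs.tst_rates(ktn, T)
        target = 1
        source = 15
        vals = []
        for order_seed in range(4):
            rng = np.random.default_rng(order_seed)
            order = [i for i in rm.ids if i not in (source, target)]
            rng.shuffle(order)
            p, tau = obs._branching(rm)
            for x in order:
                p, tau = obs._gt_eliminate(p, tau, x)
            vals.append(tau[source] / p[(source, target)])
        assert max(vals) - min(vals) < 1e-10 * max(vals)

    def test_disconnected_source_raises(self):
        ktn = synthetic_network([-10.0, -9.0, -5.0], [(-7.0, 1, 2)])
        with pytest.raises(ValueError):
            obs.mfpt_graph_transform(ktn, 1, 0.5)

    def test_deep_trap_numerically_stable(self):
        # escape barrier of 30 energy units at T = 0.05 (rate ~ e^-600):
        # elimination must not lose the tiny branching probabilities
        ktn = synthetic_network([-50.0, -49.0, -48.0],
                                [(-19.0, 2, 1), (-45.0, 2, 3)])
        mfpt = obs.mfpt_graph_transform(ktn, 1, 0.05)
        assert np.isfinite(mfpt[2]) and mfpt[2] > 1e200
        assert np.isfinite(mfpt[3]) and mfpt[3] >= mfpt[2]


class TestFptDistribution:
    def test_two_state_single_exponential(self):
        ktn = synthetic_network([-10.0, -9.0], [(-7.0, 1, 2)])
        T = 0.5
        rm = obs.tst_rates(ktn, T)
        f = obs.fpt_distribution(ktn, 2, 1, T)
        assert len(f.rates) == 1
        assert f.rates[0] == pytest.approx(rm.rate[(2, 1)], rel=1e-10)
        assert f.amplitudes[0] == pytest.approx(1.0, abs=1e-10)
        # unimodal P(ln theta) with mean 1/k
        assert f.mean() == pytest.approx(1.0 / rm.rate[(2, 1)], rel=1e-10)
        grid = f.default_log_grid(200)
        dens = f.log_density(grid)
        peak = np.argmax(dens)
        assert 0 < peak < len(grid) - 1

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_density_normalised_and_mean_matches_gt(self, seed):
        ktn = random_connected_network(20, seed=seed)
        T = 0.9
        target = min(ktn.minima, key=lambda i: ktn.minima[i].energy)
        source = max(ktn.minima, key=lambda i: ktn.minima[i].energy)
        f = obs.fpt_distribution(ktn, source, target, T)
        gt = obs.mfpt_graph_transform(ktn, target, T)[source]
        assert f.amplitudes.sum() == pytest.approx(1.0, abs=1e-6)
        assert f.mean() == pytest.approx(gt, rel=1e-4)
        # numerical quadrature of p(theta)
        th = np.logspace(
            np.log10(1.0 / f.rates.max()) - 4,
            np.log10(1.0 / f.rates.min()) + 4, 4000,
        )
        integral = np.trapezoid(f.density(th), th)
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_three_state_trap_two_peaks_at_analytic_rates(self):
        # target 1 -- source 2 -- deep trap 3: from the source the walk
        # either relaxes directly (fast peak) or falls into the trap and
        # escapes slowly (slow peak); the transient 2x2 generator is
        # analytically diagonalisable
        ktn = synthetic_network(
            [-10.0, -9.0, -12.0],
            [(-8.5, 1, 2), (-8.8, 2, 3)],
        )
        for m in ktn.minima.values():
            m.log_prod_pos_eig = 6.0
        for ts in ktn.transition_states.values():
            ts.log_prod_pos_eig = 6.0
        T = 0.35
        rm = obs.tst_rates(ktn, T)
        k21 = rm.rate[(2, 1)]
        k23 = rm.rate[(2, 3)]
        k32 = rm.rate[(3, 2)]
        m = np.array([[-(k21 + k23), k32], [k23, -k32]])
        lam = np.linalg.eigvals(m)
        analytic = np.sort(-lam.real)
        f = obs.fpt_distribution(ktn, 2, 1, T)
        assert np.allclose(np.sort(f.rates), analytic, rtol=1e-8)
        grid = f.default_log_grid(600)
        dens = f.log_density(grid)
        # two resolved maxima in P(ln theta)
        maxima = [
            i for i in range(1, len(grid) - 1)
            if dens[i] > dens[i - 1] and dens[i] > dens[i + 1]
            and dens[i] > 1e-3 * dens.max()
        ]
        assert len(maxima) == 2
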