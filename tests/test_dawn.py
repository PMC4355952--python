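"""HMRF risk scoring: network estimation, Ising sampling, fitting, FDR calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chd8net.dawn import (
    IsingParams,
    call_risk_genes,
    estimate_network_lasso,
    fit_hmrf,
    p_to_z,
    pseudolikelihood_grad,
    select_lambda_powerlaw,
    simulate_ising,
)
from chd8net.dawn import test_d as d_boot_test  # avoid pytest collection
from chd8net.simulate import SimulationConfig, gen_graph

FAST_FIT = dict(max_iter=25, n_burn=25, n_samples=12)


def chain_net(n):
    return gen_graph(SimulationConfig(seed=0, graph_model="chain"), n)


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestPToZ:
    def test_half_is_zero(self):
        assert p_to_z(np.array([0.5]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantile(self):
        assert p_to_z(np.array([0.025]))[0] == pytest.approx(1.95996, abs=1e-4)

    def test_monotone(self, rng):
        p = np.sort(rng.uniform(0.001, 0.999, 50))
        z = p_to_z(p)
        assert np.all(np.diff(z) < 0)

    def test_boundary_clamped(self):
        z = p_to_z(np.array([0.0, 1.0]))
        assert np.isfinite(z).all() and z[0] > 6 and z[1] < -6

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p_to_z(np.array([-0.1]))


def expr_frame(data):
    return pd.DataFrame(data, index=[f"g{i}" for i in range(data.shape[0])])


class TestNetworkLasso:
    def test_large_lambda_empty(self, rng):
        expr = expr_frame(rng.standard_normal((20, 30)))
        net = estimate_network_lasso(expr, lam=10.0)
        assert net.n_edges == 0

    def test_null_false_edge_rate(self, rng):
        expr = expr_frame(rng.standard_normal((30, 50)))
        net = estimate_network_lasso(expr, lam=0.45)
        possible = 30 * 29 / 2
        assert net.n_edges / possible < 0.10

    def test_chain_recovery(self, rng):
        # Gaussian chain graphical model: partial correlation 0.45 on the chain
        n, p, rho = 400, 25, 0.45
        x = np.zeros((p, n))
        x[0] = rng.standard_normal(n)
        for i in range(1, p):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        net = estimate_network_lasso(expr_frame(x), lam=0.12)
        adj = net.adjacency.toarray()
        true_edges = {(i, i + 1) for i in range(p - 1)}
        found = {(i, j) for i, j in zip(*np.nonzero(adj)) if i < j}
        recovered = len(true_edges & found) / len(true_edges)
        assert recovered >= 0.8

    def test_symmetric_zero_diagonal(self, rng):
        expr = expr_frame(rng.standard_normal((15, 40)))
        net = estimate_network_lasso(expr, lam=0.2)
        adj = net.adjacency.toarray()
        assert np.array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)

    def test_key_node_restriction(self, rng):
        expr = expr_frame(rng.standard_normal((20, 40)))
        net = estimate_network_lasso(expr, lam=0.2, key_nodes=["g0", "g1"],
                                     corr_cutoff=0.99)
        # nodes outside the restriction never gain edges
        deg = net.degrees()
        allowed = {0, 1}
        for i in np.flatnonzero(deg):
            assert i in allowed

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            estimate_network_lasso(expr_frame(rng.standard_normal((5, 2))), 0.1)


class TestLambdaSelection:
    def test_single_element_grid(self, rng):
        expr = expr_frame(rng.standard_normal((10, 20)))
        assert select_lambda_powerlaw(expr, [0.3]) == 0.3

    def test_selected_r2_is_grid_max(self, rng):
        # scale-free-ish data: hub structure
        n, p = 300, 30
        hub = rng.standard_normal(n)
        x = np.vstack([hub] + [0.6 * hub + 0.8 * rng.standard_normal(n)
                               for _ in range(10)]
                      + [rng.standard_normal(n) for _ in range(p - 11)])
        expr = expr_frame(x)
        grid = [0.15, 0.3, 0.5]
        lam = select_lambda_powerlaw(expr, grid)

        def r2_of(l):
            net = estimate_network_lasso(expr, l)
            deg = net.degrees()
            deg = deg[deg >= 1]
            v, c = np.unique(deg, return_counts=True)
            if len(v) < 2:
                return None
            r = np.corrcoef(np.log(v.astype(float)), np.log(c.astype(float)))[0, 1]
            return 0.0 if np.isnan(r) else r * r

        scores = {l: r2_of(l) for l in grid}
        valid = {l: s for l, s in scores.items() if s is not None}
        assert valid[lam] == max(valid.values())

    def test_all_empty_networks_error(self, rng):
        expr = expr_frame(rng.standard_normal((8, 20)))
        with pytest.raises(ValueError, match="grid"):
            select_lambda_powerlaw(expr, [5.0, 10.0])


class TestSimulateIsing:
    def test_zero_coupling_logistic_marginal(self, rng):
        n = 2_000
        net = chain_net(n)
        params = IsingParams(b=-1.0, eta=0.0, d=0.0)
        I = simulate_ising(params, net, np.zeros(n), rng, n_sweeps=200)
        expect = logistic(-1.0)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(I.mean() - expect) < 4 * se

    def test_empty_edges_two_marginals(self, rng):
        import scipy.sparse as sp

        from chd8net.dawn import SparseNetwork

        n = 4_000
        net = SparseNetwork(genes=[f"g{i}" for i in range(n)],
                            adjacency=sp.csr_matrix((n, n), dtype=np.int8),
                            lam=0.0)
        H = np.zeros(n)
        H[: n // 2] = 1.0
        params = IsingParams(b=-1.5, eta=0.7, d=1.0)
        I = simulate_ising(params, net, H, rng, n_sweeps=150)
        p0, p1 = logistic(-1.5), logistic(-0.5)
        assert abs(I[H == 0].mean() - p0) < 4 * np.sqrt(p0 * (1 - p0) / (n / 2))
        assert abs(I[H == 1].mean() - p1) < 4 * np.sqrt(p1 * (1 - p1) / (n / 2))

    def test_chi2_goodness_of_fit_zero_coupling(self, rng):
        n = 10_000
        net = chain_net(n)
        params = IsingParams(b=-2.0, eta=0.0, d=0.0)
        I = simulate_ising(params, net, np.zeros(n), rng, n_sweeps=120)
        expect = logistic(-2.0) * n
        chi2 = (I.sum() - expect) ** 2 / expect \
            + ((n - I.sum()) - (n - expect)) ** 2 / (n - expect)
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_strong_binding_effect_saturates(self, rng):
        n = 500
        net = chain_net(n)
        H = np.ones(n)
        params = IsingParams(b=-2.0, eta=0.0, d=10.0)
        I = simulate_ising(params, net, H, rng, n_sweeps=100)
        assert I.mean() > 0.99

    def test_invalid_sweeps(self, rng):
        with pytest.raises(ValueError):
            simulate_ising(IsingParams(b=0, eta=0), chain_net(10),
                           np.zeros(10), rng, n_sweeps=0)


def simulate_dataset(n, net, params, H, rng):
    I = simulate_ising(params, net, H, rng)
    z = rng.standard_normal(n)
    z[I == 1] = params.mu + params.sigma * z[I == 1]
    return z, I


class TestFitHMRF:
    def test_parameter_recovery_small(self, rng):
        n = 400
        net = chain_net(n)
        true = IsingParams(b=-2.0, eta=0.5, d=1.5, mu=2.0, sigma=1.0)
        H = (rng.random(n) < 0.5).astype(float)
        ds = []
        for _ in range(6):
            z, _ = simulate_dataset(n, net, true, H, rng)
            fit = fit_hmrf(z, net, H=H, model="M1", rng=rng, max_iter=60)
            ds.append(fit.params.d)
        assert abs(np.mean(ds) - true.d) < 0.4

    def test_all_zero_H_rejected(self, rng):
        n = 50
        net = chain_net(n)
        with pytest.raises(ValueError, match="M0"):
            fit_hmrf(rng.standard_normal(n), net, H=np.zeros(n), model="M1",
                     rng=rng)

    def test_null_z_no_signal(self, rng):
        n = 300
        net = chain_net(n)
        z = rng.standard_normal(n)
        fit = fit_hmrf(z, net, model="M0", rng=rng, **FAST_FIT)
        # either the fit degenerates (no risk mass) or mu collapses near 0
        assert fit.degenerate or fit.params.mu < 0.8 or fit.posterior.mean() < 0.1

    def test_d_clamped_nonnegative(self, rng):
        n = 300
        net = chain_net(n)
        true = IsingParams(b=-1.5, eta=0.4, d=0.0, mu=2.0, sigma=1.0)
        # H anticorrelated with risk: unconstrained d would go negative
        z, I = simulate_dataset(n, net, true, np.zeros(n), rng)
        H = (I == 0).astype(float)
        fit = fit_hmrf(z, net, H=H, model="M1", rng=rng, **FAST_FIT)
        assert fit.params.d >= 0.0

    def test_null_d_releases_to_zero(self, rng):
        n = 300
        net = chain_net(n)
        true = IsingParams(b=-1.5, eta=0.4, d=0.0, mu=2.2, sigma=1.0)
        H = (rng.random(n) < 0.5).astype(float)
        ds = []
        for _ in range(8):
            z, _ = simulate_dataset(n, net, true, np.zeros(n), rng)
            fit = fit_hmrf(z, net, H=H, model="M1", rng=rng, **FAST_FIT)
            ds.append(fit.params.d)
        assert np.median(np.abs(ds)) < 0.25

    def test_pseudolikelihood_gradient_zero(self, rng):
        n = 300
        net = chain_net(n)
        true = IsingParams(b=-1.5, eta=0.5, d=1.5, mu=2.0, sigma=1.0)
        H = (rng.random(n) < 0.5).astype(float)
        z, _ = simulate_dataset(n, net, true, H, rng)
        fit = fit_hmrf(z, net, H=H, model="M1", rng=rng, **FAST_FIT)
        if fit.params.d > 0:  # unconstrained interior solution
            g = pseudolikelihood_grad(fit.params, net, H, fit.imputed_states)
            assert np.max(np.abs(g)) < 1e-3

    def test_m0_ignores_H(self, rng):
        n = 200
        net = chain_net(n)
        z = np.concatenate([rng.standard_normal(n - 40),
                            2.5 + rng.standard_normal(40)])
        fit = fit_hmrf(z, net, model="M0", rng=rng, **FAST_FIT)
        assert fit.params.d == 0.0


class TestTestD:
    def test_observed_zero_gives_p_one(self, rng):
        n = 200
        net = chain_net(n)
        true = IsingParams(b=-1.5, eta=0.4, d=0.0, mu=2.2, sigma=1.0)
        z, I = simulate_dataset(n, net, true, np.zeros(n), rng)
        H = (I == 0).astype(float)  # anti-association clamps d_obs to 0
        res = d_boot_test(z, net, H, n_boot=20, rng=rng, fit_kwargs=FAST_FIT)
        if res["d_obs"] == 0.0:
            assert res["p_value"] == 1.0

    def test_power_with_planted_effect(self, rng):
        n = 300
        net = chain_net(n)
        true = IsingParams(b=-2.0, eta=0.5, d=2.0, mu=2.2, sigma=1.0)
        H = (rng.random(n) < 0.5).astype(float)
        hits = 0
        for _ in range(5):
            z, _ = simulate_dataset(n, net, true, H, rng)
            res = d_boot_test(z, net, H, n_boot=40, rng=rng, fit_kwargs=FAST_FIT)
            hits += res["p_value"] < 0.05
        assert hits >= 3


class TestCallRiskGenes:
    def test_all_ones(self):
        out = call_risk_genes(np.ones(5))
        assert out["risk_flag"].all()

    def test_all_zeros(self):
        out = call_risk_genes(np.zeros(5))
        assert not out["risk_flag"].any()

    def test_hand_computed_prefix(self):
        out = call_risk_genes(np.array([0.99, 0.98, 0.5]), fdr=0.05)
        assert out["risk_flag"].tolist() == [True, True, False]
        assert out["q_value"].iloc[1] == pytest.approx(0.015)
        assert out["q_value"].iloc[2] == pytest.approx(0.17666667)

    def test_q_monotone_along_ranking(self, rng):
        post = rng.uniform(0, 1, 100)
        out = call_risk_genes(post)
        q_sorted = out.sort_values("posterior", ascending=False)["q_value"]
        assert np.all(np.diff(q_sorted.to_numpy()) >= -1e-12)

    def test_series_index_preserved(self):
        s = pd.Series([0.9, 0.1], index=["a", "b"])
        out = call_risk_genes(s)
        assert set(out.index) == {"a", "b"}

    def test_invalid_posterior(self):
        with pytest.raises(ValueError):
            call_risk_genes(np.array([1.2]))
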