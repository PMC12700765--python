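import numpy as np
import pytest

from netnonind import generate_pa_network
from netnonind.networks import CommunityPartition
from netnonind.estimators import build_dyads, fit_community_re, fit_dyadic, fit_ols

from _oracles import dense_dyadic_profile, enumerate_dyads


class TestCommunityRandomEffects:
    def _random_partition(self, n, k, rng):
        labels = np.repeat(np.arange(k), n // k)
        rng.shuffle(labels)
        return CommunityPartition(labels=labels, n_communities=k)

    def test_zero_community_variance_tracks_ols(self):
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(200):
            x = rng.standard_normal(60)
            y = 0.2 * x + rng.standard_normal(60)
            part = self._random_partition(60, 6, rng)
            diffs.append(fit_community_re(y, x, part).slope - fit_ols(y, x).slope)
        assert abs(np.mean(diffs)) < 0.01
        assert np.std(diffs) < 0.05

    def test_calibrated_under_true_community_structure(self):
        # strong community intercepts in y, X independent of community:
        # rejection rate stays within binomial error of alpha
        rng = np.random.default_rng(2)
        labels = np.repeat(np.arange(10), 10)
        part = CommunityPartition(labels=labels, n_communities=10)
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            u = rng.standard_normal(10)[labels]
            y = u + rng.standard_normal(100)
            x = rng.standard_normal(100)
            rejections += fit_community_re(y, x, part).p_value < 0.05
        rate = rejections / n_reps
        halfwidth = 3 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < halfwidth

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(np.arange(10), 10)
        part = CommunityPartition(labels=labels, n_communities=10)
        vc, rv = [], []
        for _ in range(200):
            u = rng.standard_normal(10)[labels]
            x = rng.standard_normal(100)
            y = 0.5 * x + u + rng.standard_normal(100)
            fit = fit_community_re(y, x, part)
            vc.append(fit.extras["community_var"])
            rv.append(fit.extras["residual_var"])
        assert np.mean(vc) == pytest.approx(1.0, rel=0.3)
        assert np.mean(rv) == pytest.approx(1.0, rel=0.3)

    def test_single_community_falls_back_to_ols(self, rng):
        part = CommunityPartition(labels=np.zeros(30, dtype=int), n_communities=1)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="single community"):
            fit = fit_community_re(y, x, part)
        assert "single_community" in fit.flags
        assert fit.slope == fit_ols(y, x).slope


class TestDyadTable:
    def test_three_nodes_three_rows(self, path3, rng):
        dt = build_dyads(rng.standard_normal(3), rng.standard_normal(3), path3)
        assert dt.n_dyads == 3

    def test_identical_traits_give_zero_distances(self, path3):
        dt = build_dyads(np.ones(3), np.full(3, 2.0), path3)
        assert np.all(dt.y_dist == 0) and np.all(dt.x_dist == 0)

    def test_matches_double_loop_enumeration(self, rng):
        net = generate_pa_network(20, 1, seed=9)
        y = rng.standard_normal(20)
        x = rng.standard_normal(20)
        dt = build_dyads(y, x, net)
        oracle = enumerate_dyads(y, x, net.adjacency)
        got = list(zip(dt.node_a, dt.node_b, dt.y_dist, dt.x_dist, dt.z))
        assert len(got) == len(oracle)
        for (i, j, dy, dx, z), (oi, oj, ody, odx, oz) in zip(
            sorted(got), sorted(oracle)
        ):
            assert (i, j) == (oi, oj)
            assert dy == pytest.approx(ody) and dx == pytest.approx(odx)
            assert z == oz

    def test_tie_indicator_matches_edges(self, tree20, rng):
        dt = build_dyads(rng.standard_normal(20), rng.standard_normal(20), tree20)
        tied = {(a, b) for a, b, z in zip(dt.node_a, dt.node_b, dt.z) if z == 1}
        assert tied == tree20.edges


class TestDyadicRegression:
    def test_constant_outcome_distance_gives_zero_slope(self, path3):
        dt = build_dyads(np.zeros(3), np.array([0.0, 1.0, 3.0]), path3)
        fit = fit_dyadic(dt)
        assert fit.slope == 0.0
        assert "degenerate" in fit.flags

    def test_profile_matches_dense_covariance_oracle(self, rng):
        from netnonind.estimators.mixed import dyadic_negloglik, dyadic_profile

        net = generate_pa_network(10, 1, seed=4)
        y = rng.standard_normal(10)
        x = rng.standard_normal(10)
        dt = build_dyads(y, x, net)
        m = dt.n_dyads
        # the Woodbury profile must agree with an explicit dense-covariance
        # computation at every variance ratio
        for gamma in (0.0, 0.3, 1.7):
            beta_o, q_o, logdet_o = dense_dyadic_profile(dt, gamma)
            beta, _, q, logdet = dyadic_profile(dt, gamma)
            assert np.allclose(beta, beta_o, atol=1e-9)
            assert q == pytest.approx(q_o, rel=1e-9)
            assert logdet == pytest.approx(logdet_o, rel=1e-9)
            nll_dense = 0.5 * (m * np.log(2 * np.pi * q_o / m) + logdet_o + m)
            assert dyadic_negloglik(dt, gamma) == pytest.approx(nll_dense, rel=1e-9)

    def test_zero_node_variance_matches_dyad_ols(self):
        rng = np.random.default_rng(5)
        diffs = []
        for seed in range(200):
            net = generate_pa_network(15, 1, seed=seed)
            x = rng.standard_normal(15)
            y = 0.3 * x + rng.standard_normal(15)
            dt = build_dyads(y, x, net)
            fit = fit_dyadic(dt)
            F = np.column_stack([np.ones(dt.n_dyads), dt.x_dist, dt.z])
            beta = np.linalg.lstsq(F, dt.y_dist, rcond=None)[0]
            diffs.append(fit.slope - beta[1])
        # gamma-hat >= 0 fluctuates on null data, so allow a small wobble
        assert abs(np.mean(diffs)) < 0.03

    def test_slope_recovery_short(self):
        # fuller recovery study lives in the acceptance suite
        rng = np.random.default_rng(6)
        slopes = []
        for seed in range(40):
            net = generate_pa_network(30, 1, seed=seed)
            x = rng.standard_normal(30)
            dt = build_dyads(np.zeros(30), x, net)
            u = rng.standard_normal(30)
            y_dist = 0.5 * dt.x_dist + u[dt.node_a] + u[dt.node_b] + rng.standard_normal(dt.n_dyads)
            dt2 = type(dt)(node_a=dt.node_a, node_b=dt.node_b, y_dist=y_dist,
                           x_dist=dt.x_dist, z=dt.z, n_nodes=30)
            slopes.append(fit_dyadic(dt2).slope)
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.1)
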