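"""DomiRank (closed form, dynamics, sigma selection) and classical centralities."""

import numpy as np
import pytest
from scipy import stats

from dominet.centrality import (
    DomiRankParams,
    classical_centralities,
    domirank_dynamics,
    domirank_solve,
    select_sigma,
    sigma_feasible_interval,
)
from dominet.robustness import lcc_area, targeted_attack_curve

from conftest import binary_net, random_connected_net


class TestDomiRankSolve:
    def test_complete_k4_symmetric_value(self, complete_k4):
        # symmetry: gamma (1 + 3 sigma) = 3 sigma -> gamma = 0.6 / 1.6 = 0.375
        gamma = domirank_solve(complete_k4, DomiRankParams(sigma=0.2))
        np.testing.assert_allclose(gamma, 0.375, atol=1e-12)

    def test_star_hand_solution(self, star_k14):
        # hub + 1.6 leaf = 1.6; leaf + 0.4 hub = 0.4 -> hub 8/3, leaf -2/3
        gamma = domirank_solve(star_k14, DomiRankParams(sigma=0.4))
        assert gamma[0] == pytest.approx(8 / 3, abs=1e-12)
        np.testing.assert_allclose(gamma[1:], -2 / 3, atol=1e-12)

    def test_edgeless_graph_gives_zero(self):
        net = binary_net(np.zeros((4, 4)))
        np.testing.assert_array_equal(domirank_solve(net, DomiRankParams(sigma=0.3)), 0.0)

    def test_linear_system_residual_small(self):
        rng = np.random.default_rng(0)
        net = random_connected_net(rng, 30)
        feas = sigma_feasible_interval(net)
        sigma = 0.7 * feas.upper_bound
        gamma = domirank_solve(net, DomiRankParams(sigma=sigma))
        A = net.A.astype(float)
        resid = (sigma * A + np.eye(30)) @ gamma - sigma * A.sum(axis=1)
        assert np.max(np.abs(resid)) < 1e-8

    def test_sigma_outside_interval_rejected(self, star_k14):
        # lambda_N = -2 -> upper bound 0.5
        with pytest.raises(ValueError, match="feasible interval"):
            domirank_solve(star_k14, DomiRankParams(sigma=0.6))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DomiRankParams(sigma=-0.1)

    @pytest.mark.parametrize("seed,n", [(1, 10), (2, 25), (3, 50)])
    def test_closed_form_matches_forward_dynamics(self, seed, n):
        """Steady state of the competition-relaxation ODE equals the solve."""
        rng = np.random.default_rng(seed)
        net = random_connected_net(rng, n)
        feas = sigma_feasible_interval(net)
        for frac in (0.2, 0.8):
            params = DomiRankParams(sigma=frac * feas.upper_bound)
            exact = domirank_solve(net, params)
            integrated = domirank_dynamics(net, params)
            np.testing.assert_allclose(integrated, exact, atol=1e-6)

    def test_sigma_to_zero_limit_recovers_degree(self):
        """Gamma/(sigma theta) -> A 1, so tiny sigma reproduces degree."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            net = random_connected_net(rng, 40)
            feas = sigma_feasible_interval(net)
            sigma = 1e-4 * feas.upper_bound
            gamma = domirank_solve(net, DomiRankParams(sigma=sigma))
            degree = net.A.sum(axis=1)
            np.testing.assert_allclose(gamma / sigma, degree, atol=0.05)
            # ranking agrees wherever degrees are untied
            rho = stats.spearmanr(gamma, degree).statistic
            assert rho > 0.98

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        net = random_connected_net(rng, 20)
        feas = sigma_feasible_interval(net)
        params = DomiRankParams(sigma=0.5 * feas.upper_bound)
        gamma = domirank_solve(net, params)
        perm = rng.permutation(20)
        net_p = binary_net(net.A[np.ix_(perm, perm)])
        gamma_p = domirank_solve(net_p, params)
        np.testing.assert_allclose(gamma_p, gamma[perm], atol=1e-10)


class TestSigmaFeasibility:
    @pytest.mark.parametrize("n", [3, 4, 7])
    def test_complete_graph_interval(self, n):
        # spectrum of K_n: {n-1, -1 x (n-1)} -> interval (0, 1)
        net = binary_net(np.ones((n, n)) - np.eye(n))
        feas = sigma_feasible_interval(net)
        assert feas.lambda_N == pytest.approx(-1.0, abs=1e-10)
        assert feas.upper_bound == pytest.approx(1.0, abs=1e-10)

    def test_star_interval(self, star_k14):
        # star K_{1,m}: extreme eigenvalues +/- sqrt(m) -> upper bound 1/2
        feas = sigma_feasible_interval(star_k14)
        assert feas.lambda_N == pytest.approx(-2.0, abs=1e-10)
        assert feas.upper_bound == pytest.approx(0.5, abs=1e-10)

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            sigma_feasible_interval(binary_net(np.zeros((3, 3))))

    def test_candidates_exclude_endpoints_evenly_spaced(self, complete_k5):
        feas = sigma_feasible_interval(complete_k5, n_candidates=100)
        assert len(feas.candidates) == 100
        assert feas.candidates[0] > 0
        assert feas.candidates[-1] < feas.upper_bound
        np.testing.assert_allclose(np.diff(feas.candidates), feas.candidates[0], atol=1e-12)


class TestSelectSigma:
    def test_single_candidate_returned(self, complete_k5):
        sigma, cands, areas = select_sigma(complete_k5, n_candidates=1)
        assert sigma == cands[0]
        assert len(areas) == 1

    def test_selected_sigma_attains_minimum_area(self):
        """Independent recomputation of every candidate's attack area."""
        rng = np.random.default_rng(21)
        net = random_connected_net(rng, 30)
        sigma, cands, areas = select_sigma(net, n_candidates=25)
        recomputed = []
        for sig in cands:
            gamma = domirank_solve(net, DomiRankParams(sigma=float(sig)))
            recomputed.append(lcc_area(targeted_attack_curve(net, gamma)))
        np.testing.assert_allclose(areas, recomputed, atol=1e-12)
        assert areas[list(cands).index(sigma)] == min(areas)

    def test_deterministic(self):
        rng = np.random.default_rng(22)
        net = random_connected_net(rng, 25)
        first = select_sigma(net, n_candidates=10)
        second = select_sigma(net, n_candidates=10)
        assert first[0] == second[0]
        np.testing.assert_array_equal(first[2], second[2])

    def test_solve_succeeds_across_entire_scan(self):
        rng = np.random.default_rng(23)
        net = random_connected_net(rng, 20)
        _, cands, areas = select_sigma(net, n_candidates=50)
        assert np.all(np.isfinite(areas))  # every (sigma A + I) solve succeeded


class TestClassicalCentralities:
    def test_complete_k5_degree_and_betweenness(self, complete_k5):
        vals = classical_centralities(complete_k5)
        np.testing.assert_allclose(vals["Degree"], 4)
        np.testing.assert_allclose(vals["Betweenness"], 0, atol=1e-12)

    def test_star_hub_betweenness(self, star_k14):
        vals = classical_centralities(star_k14)
        assert vals["Betweenness"][0] == pytest.approx(1.0)
        np.testing.assert_allclose(vals["Betweenness"][1:], 0, atol=1e-12)

    def test_path3_closeness(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        vals = classical_centralities(binary_net(A))
        assert vals["Closeness"][1] == pytest.approx(1.0)
        assert vals["Closeness"][0] == pytest.approx(2 / 3)
        assert vals["Closeness"][2] == pytest.approx(2 / 3)

    def test_strength_sums_retained_weights(self):
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        W = np.array([[0, 0.5, 1.5], [0.5, 0, 0], [1.5, 0, 0]])
        vals = classical_centralities(binary_net(A, weights=W), metrics=("Strength",))
        np.testing.assert_allclose(vals["Strength"], [2.0, 0.5, 1.5])

    def test_eigenvector_nonnegative_unit_norm(self):
        rng = np.random.default_rng(31)
        net = random_connected_net(rng, 15)
        vec = classical_centralities(net, metrics=("Eigenvector",))["Eigenvector"]
        assert np.all(vec >= 0)
        assert np.linalg.norm(vec) == pytest.approx(1.0)

    def test_all_seven_metrics_present(self, complete_k4):
        vals = classical_centralities(complete_k4)
        assert set(vals) == {
            "Betweenness", "Closeness", "Degree", "Eigenvector",
            "Harmonic", "PageRank", "Strength",
        }
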