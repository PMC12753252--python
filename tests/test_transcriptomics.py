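"""PLS association, permutation/bootstrap inference and enrichment."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from dominet.cohort import generate_gene_expression
from dominet.transcriptomics import (
    hypergeom_enrich,
    pls1_explained_x,
    pls_bootstrap,
    pls_fit,
    pls_permutation,
    rank_top_genes,
    read_gmt,
)


def planted_data(seed=0, n_regions=60, n_genes=80, n_signal=20, weight=0.8):
    rng = np.random.default_rng(seed)
    response = rng.standard_normal(n_regions)
    genes, mask = generate_gene_expression(
        n_regions, n_genes, signal_map=response, n_signal_genes=n_signal,
        signal_weight=weight, noise_sd=0.5, seed=seed,
    )
    return response, genes, mask


class TestPlsFit:
    def test_single_gene_response_perfect_correlation(self):
        """Response equal to one gene (others orthogonal to it): PLS1 r = 1."""
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((30, 5))
        raw -= raw.mean(axis=0)  # center first so QR columns stay centered
        q, _ = np.linalg.qr(raw)  # orthogonal columns
        genes = pd.DataFrame(q, columns=list("abcde"))
        response = genes["c"].to_numpy().copy()
        res = pls_fit(response, genes)
        assert abs(res.component1_response_r) == pytest.approx(1.0, abs=1e-8)

    def test_explained_shares_valid_and_cumulative_monotone(self):
        for seed in range(50):
            r2 = np.random.default_rng(seed)
            genes = r2.standard_normal((25, 15))
            y = r2.standard_normal(25)
            res = pls_fit(y, genes, n_components=5)
            for share in (res.x_variance_explained, res.y_variance_explained):
                assert np.all(share >= -1e-10) and np.all(share <= 1 + 1e-10)
                assert share.sum() <= 1 + 1e-8
            assert np.all(np.diff(np.cumsum(res.y_variance_explained)) >= -1e-12)

    def test_planted_association_beats_permutation_null(self):
        response, genes, _ = planted_data()
        p = pls_permutation(response, genes, B=200, seed=0)
        assert p < 0.05

    def test_sign_convention_scores_positively_correlated(self):
        response, genes, _ = planted_data(seed=3)
        res = pls_fit(response, genes)
        assert res.component1_response_r >= 0

    def test_explained_share_invariant_to_gene_order(self):
        response, genes, _ = planted_data(seed=4)
        rng = np.random.default_rng(4)
        shuffled = genes.iloc[:, rng.permutation(genes.shape[1])]
        a = pls_fit(response, genes).x_variance_explained[0]
        b = pls_fit(response, shuffled).x_variance_explained[0]
        assert a == pytest.approx(b, rel=1e-10)

    def test_fast_pls1_statistic_matches_sklearn(self):
        """The closed-form PLS1 explained-variance equals a full model fit."""
        response, genes, _ = planted_data(seed=5)
        X = genes.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        fast = pls1_explained_x(response, Xs)
        full = pls_fit(response, genes, n_components=1).x_variance_explained[0]
        assert fast == pytest.approx(full, rel=1e-8)

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="constant"):
            pls_fit(np.ones(20), rng.standard_normal((20, 5)))

    def test_too_few_regions_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="10 regions"):
            pls_fit(rng.standard_normal(6), rng.standard_normal((6, 5)))


class TestPlsPermutation:
    def test_perfect_signal_attains_minimum_p(self):
        response, genes, _ = planted_data(weight=3.0, seed=8)
        B = 99
        p = pls_permutation(response, genes, B=B, seed=1)
        assert p == pytest.approx(1 / (B + 1))

    def test_exhaustive_enumeration_small_n(self):
        """Exact p over all 720 orderings matches brute-force recomputation."""
        rng = np.random.default_rng(9)
        y = rng.standard_normal(6)
        X = rng.standard_normal((6, 4))
        p_exact = pls_permutation(y, X, exact=True)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        obs = pls1_explained_x(y, Xs)
        count = sum(
            pls1_explained_x(y[list(perm)], Xs) >= obs - 1e-12
            for perm in permutations(range(6))
        )
        assert p_exact == pytest.approx(count / 720)
        assert p_exact >= 1 / 720

    def test_null_pvalues_uniform(self):
        """Calibration: under no association p is uniform across replicates."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            y = rng.standard_normal(20)
            X = rng.standard_normal((20, 15))
            ps.append(pls_permutation(y, X, B=99, seed=seed))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPlsBootstrap:
    def test_positive_se_on_noisy_data(self):
        response, genes, _ = planted_data(seed=10)
        boot = pls_bootstrap(response, genes, B=200, seed=0)
        assert (boot["boot_se"] > 0).all()

    def test_signal_genes_more_stable_than_noise(self):
        response, genes, mask = planted_data(seed=11, weight=1.5)
        boot = pls_bootstrap(response, genes, B=300, seed=0)
        z = np.abs(boot["stability_z"].to_numpy())
        assert z[mask].mean() > z[~mask].mean()

    def test_doubling_b_converges(self):
        response, genes, _ = planted_data(seed=12)
        se1 = pls_bootstrap(response, genes, B=400, seed=0)["boot_se"].to_numpy()
        se2 = pls_bootstrap(response, genes, B=800, seed=1)["boot_se"].to_numpy()
        assert np.median(np.abs(se1 - se2) / se1) < 0.25


class TestRankTopGenes:
    def test_exact_k_returned(self):
        response, genes, _ = planted_data(seed=13, n_genes=120)
        res = pls_fit(response, genes)
        top = rank_top_genes(res, k=50)
        assert len(top) == 50

    def test_full_ranking_sorted_by_weight_magnitude(self):
        response, genes, _ = planted_data(seed=14)
        res = pls_fit(response, genes)
        ranked = rank_top_genes(res, k=len(res.gene_names))
        w = dict(zip(res.gene_names, np.abs(res.weights[:, 0])))
        mags = [w[g] for g in ranked]
        assert all(a >= b - 1e-12 for a, b in zip(mags, mags[1:]))

    def test_invariant_to_gene_column_order(self):
        response, genes, _ = planted_data(seed=15)
        rng = np.random.default_rng(15)
        shuffled = genes.iloc[:, rng.permutation(genes.shape[1])]
        a = rank_top_genes(pls_fit(response, genes), k=20)
        b = rank_top_genes(pls_fit(response, shuffled), k=20)
        assert a == b

    def test_k_too_large_rejected(self):
        response, genes, _ = planted_data(seed=16)
        with pytest.raises(ValueError, match="exceeds"):
            rank_top_genes(pls_fit(response, genes), k=10_000)


class TestHypergeomEnrich:
    def test_hand_worked_overlap(self):
        background = [f"g{i}" for i in range(10)]
        out = hypergeom_enrich(
            background[:4], {"setA": background[:5]}, background
        )
        assert out.loc[0, "p"] == pytest.approx(1 / 42)

    def test_zero_overlap_p_one(self):
        background = [f"g{i}" for i in range(10)]
        out = hypergeom_enrich(background[:3], {"setA": background[5:]}, background)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_one_sided_fisher_exact(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(20, 60))
        background = [f"g{i}" for i in range(M)]
        hits = list(rng.choice(background, size=rng.integers(5, 15), replace=False))
        members = list(rng.choice(background, size=rng.integers(5, 20), replace=False))
        out = hypergeom_enrich(hits, {"s": members}, background)
        k = len(set(hits) & set(members))
        table = [
            [k, len(hits) - k],
            [len(members) - k, M - len(hits) - len(members) + k],
        ]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        assert out.loc[0, "p"] == pytest.approx(p_fisher, rel=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            hypergeom_enrich([], {"s": []}, [])

    def test_gene_list_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeom_enrich(["x"], {"s": ["a"]}, ["a", "b"])


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
    sets = read_gmt(path)
    assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g4"}}
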