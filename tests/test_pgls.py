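"""Trees, covariances, PGLS models and AICc weights."""

import numpy as np
import pytest

import ctpc
from ctpc.pgls import PhylogenyError, _gls_profile, _lambda_cov, phylo_cov


class TestNewickIO:
    def test_two_tip_tree(self):
        tree = ctpc.read_newick("(A:1,B:1);")
        leaves = list(tree.leaf_node_iter())
        assert sorted(l.taxon.label for l in leaves) == ["A", "B"]
        assert all(l.edge.length == 1.0 for l in leaves)

    def test_roundtrip_preserves_distances(self):
        tree = ctpc.yule_tree(50, seed=9)
        back = ctpc.read_newick(ctpc.write_newick(tree))
        d1 = ctpc.DistanceMatrix.from_tree(tree)
        d2 = ctpc.DistanceMatrix.from_tree(back)
        assert d1.labels == d2.labels
        assert np.abs(d1.matrix - d2.matrix).max() < 1e-9

    def test_unlabeled_tip_rejected(self):
        with pytest.raises(PhylogenyError):
            ctpc.read_newick("(:1,B:1);")

    def test_malformed_string_rejected(self):
        with pytest.raises(PhylogenyError):
            ctpc.read_newick("((A:1,B:1;")


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        # d12=4, d13=6, d23=8 -> pendant lengths a=1, b=3, c=5 (as path lengths)
        dm = ctpc.DistanceMatrix(["A", "B", "C"],
                                 np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0.0]]))
        tree = ctpc.nj_tree(dm)
        out = ctpc.DistanceMatrix.from_tree(tree)
        assert np.allclose(out.matrix, dm.matrix)

    @pytest.mark.parametrize("newick", [
        "((A:1,B:2):1,(C:3,D:4):2);",
        "(((A:1,B:1.5):0.5,C:2):1,(D:0.7,E:1.2):2.3);",
    ])
    def test_additive_matrix_recovered_exactly(self, newick):
        source = ctpc.read_newick(newick)
        dm = ctpc.DistanceMatrix.from_tree(source)
        rebuilt = ctpc.nj_tree(dm)
        out = ctpc.DistanceMatrix.from_tree(rebuilt)
        assert out.labels == dm.labels
        assert np.abs(out.matrix - dm.matrix).max() < 1e-9

    def test_ultrametric_matrix_reproduced(self):
        tree = ctpc.yule_tree(8, seed=4)
        dm = ctpc.DistanceMatrix.from_tree(tree)
        out = ctpc.DistanceMatrix.from_tree(ctpc.nj_tree(dm))
        assert np.abs(out.matrix - dm.matrix).max() < 1e-9

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhylogenyError):
            ctpc.DistanceMatrix(["A", "B", "C"],
                                np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0.0]]))


class TestPhyloCov:
    def test_lambda_zero_is_diagonal_of_depths(self):
        tree = ctpc.yule_tree(6, seed=1)
        C, labels = phylo_cov(tree, 0.0)
        assert np.allclose(C, np.diag(np.diag(C)))
        assert np.allclose(np.diag(C), 1.0)  # unit-depth ultrametric tree

    def test_lambda_half_scales_offdiagonals(self):
        tree = ctpc.yule_tree(6, seed=1)
        C1, _ = phylo_cov(tree, 1.0)
        Ch, _ = phylo_cov(tree, 0.5)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(Ch[off], 0.5 * C1[off])
        assert np.allclose(np.diag(Ch), np.diag(C1))

    def test_missing_species_listed(self):
        tree = ctpc.yule_tree(4, seed=0, labels=list("ABCD"))
        with pytest.raises(PhylogenyError, match="X"):
            phylo_cov(tree, 1.0, species=["A", "X"])


class TestPGLS:
    @staticmethod
    def dataset(seed=0, n=16, lam=1.0, beta=2.0, sigma2=0.5):
        return ctpc.simulate_tree_and_traits(
            n, beta_habitat=beta, sigma2_bm=sigma2, lambda_true=lam, seed=seed)

    def test_star_equals_ols(self):
        tree, tab, _ = self.dataset(seed=5)
        fit = ctpc.pgls_fit(tab, tree, model="star")
        X = np.column_stack([np.ones(len(tab)), tab["habitat"].astype(float)])
        beta_ols = np.linalg.lstsq(X, tab["value"].to_numpy(), rcond=None)[0]
        assert np.abs(fit.beta - beta_ols).max() < 1e-8

    def test_noise_free_habitat_effect_exact(self):
        tree, tab, _ = self.dataset(seed=2, sigma2=0.0, beta=3.5)
        for model in ("star", "brownian"):
            fit = ctpc.pgls_fit(tab, tree, model=model)
            assert fit.beta[1] == pytest.approx(3.5, abs=1e-8)

    def test_pagel_loglik_nests_endpoints(self):
        for seed in range(10):
            tree, tab, _ = self.dataset(seed=seed, lam=float(seed % 2))
            fits = {m: ctpc.pgls_fit(tab, tree, model=m)
                    for m in ("star", "brownian", "pagel")}
            assert fits["pagel"].logLik >= fits["star"].logLik - 1e-6
            assert fits["pagel"].logLik >= fits["brownian"].logLik - 1e-6

    def test_gls_equals_ols_on_whitened_data(self):
        tree, tab, _ = self.dataset(seed=8)
        fit = ctpc.pgls_fit(tab, tree, model="brownian")
        C, _ = phylo_cov(tree, 1.0, species=list(tab["species"]))
        L = np.linalg.cholesky(C)
        Linv = np.linalg.inv(L)
        X = np.column_stack([np.ones(len(tab)), tab["habitat"].astype(float)])
        y = tab["value"].to_numpy()
        beta_white = np.linalg.lstsq(Linv @ X, Linv @ y, rcond=None)[0]
        assert np.abs(fit.beta - beta_white).max() < 1e-8

    def test_lambda_recovery_under_brownian_truth(self):
        lams = []
        for s in range(10):
            tree, tab, _ = self.dataset(seed=s, n=64, lam=1.0, beta=0.5)
            lams.append(ctpc.pgls_fit(tab, tree, model="pagel").lam)
        assert np.median(lams) >= 0.8

    def test_type_one_error_near_alpha(self):
        tree = ctpc.yule_tree(16, seed=7)
        rej = 0
        n_reps = 400
        for rep in range(n_reps):
            _, tab, _ = ctpc.simulate_tree_and_traits(
                16, beta_habitat=0.0, sigma2_bm=1.0, lambda_true=0.0,
                seed=20_000 + rep, tree=tree)
            rej += ctpc.pgls_fit(tab, tree, model="star").p[1] < 0.05
        assert rej / n_reps == pytest.approx(0.05, abs=0.025)

    def test_duplicate_species_rejected(self):
        import pandas as pd
        tree, tab, _ = self.dataset(seed=1)
        doubled = pd.concat([tab, tab.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            ctpc.pgls_fit(doubled, tree, model="star")


class TestModelComparison:
    @staticmethod
    def fits(seed=3):
        tree, tab, _ = ctpc.simulate_tree_and_traits(
            12, beta_habitat=1.0, sigma2_bm=0.5, lambda_true=1.0, seed=seed)
        return [ctpc.pgls_fit(tab, tree, model=m)
                for m in ("star", "brownian", "pagel")]

    def test_weights_sum_to_one(self):
        table = ctpc.compare_models(self.fits())
        assert table["wAICc"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_for_delta_two(self):
        w = ctpc.akaike_weights([10.0, 12.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-9)
        assert w.round(3).tolist() == [0.731, 0.269]

    def test_equal_aicc_gives_equal_weights(self):
        w = ctpc.akaike_weights([5.0, 5.0])
        assert np.allclose(w, 0.5)

    def test_weights_invariant_to_constant_shift(self):
        a = np.array([3.0, 4.5, 9.0])
        assert np.allclose(ctpc.akaike_weights(a), ctpc.akaike_weights(a + 100.0))

    def test_differing_data_rejected(self):
        f1 = self.fits(seed=3)
        f2 = self.fits(seed=4)
        with pytest.raises(ValueError):
            ctpc.compare_models([f1[0], f2[1]])


class TestGLSInternals:
    def test_profiled_loglik_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        n = 10
        A = rng.normal(size=(n, n))
        C = A @ A.T + n * np.eye(n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        beta, ll, *_ = _gls_profile(C, X, y)
        resid = y - X @ beta
        Cinv = np.linalg.inv(C)
        s2 = resid @ Cinv @ resid / n
        ll_direct = -0.5 * (n * np.log(2 * np.pi * s2)
                            + np.linalg.slogdet(C)[1] + n)
        assert ll == pytest.approx(ll_direct, abs=1e-8)

    def test_lambda_cov_keeps_diagonal(self):
        tree = ctpc.yule_tree(5, seed=0)
        C1, _ = phylo_cov(tree, 1.0)
        C = _lambda_cov(C1, 0.3)
        assert np.allclose(np.diag(C), np.diag(C1))
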