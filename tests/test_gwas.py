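import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxekit import encoding, gwas, simulate
from gxekit.cli import run_gwas
from gxekit.data_io import PhenotypeTable


def _gls_oracle(y, X_full, V):
    """Dense GLS with explicit V inverse; per-model residual scale."""
    Vi = np.linalg.inv(V)
    A = X_full.T @ Vi @ X_full
    beta = np.linalg.solve(A, X_full.T @ Vi @ y)
    r = y - X_full @ beta
    df = len(y) - X_full.shape[1]
    s2 = float(r @ Vi @ r) / df
    cov = s2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


class TestKinship:
    def test_identical_individuals_share_diagonal(self, rng):
        X = rng.integers(0, 3, size=(10, 40)).astype(float)
        X[3] = X[7]
        K = gwas.compute_kinship(X).K
        np.testing.assert_allclose(K[3, 7], K[3, 3], atol=1e-12)
        np.testing.assert_allclose(K[3, 3], K[7, 7], atol=1e-12)

    def test_matches_centered_crossproduct_oracle(self, rng):
        X = rng.integers(0, 3, size=(15, 60)).astype(float)
        Z = X - X.mean(axis=0)
        c = (Z**2).mean(axis=0).sum()
        np.testing.assert_allclose(gwas.compute_kinship(X).K, Z @ Z.T / c, atol=1e-10)

    def test_mean_diagonal_one_and_symmetry(self, rng):
        X = rng.integers(0, 3, size=(30, 100)).astype(float)
        K = gwas.compute_kinship(X).K
        np.testing.assert_allclose(np.diag(K).mean(), 1.0, atol=1e-10)
        np.testing.assert_allclose(K, K.T, atol=1e-10)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_gbye_rows_of_same_individual_related(self, small_geno):
        """Env-1 and env-2 copies of one individual are more related than average."""
        X = encoding.expand_genotypes(small_geno, 2)
        K = gwas.compute_kinship(X.values).K
        n = small_geno.n
        self_pairs = np.array([K[i, n + i] for i in range(n)])
        off = K[np.triu_indices_from(K, k=1)]
        assert self_pairs.mean() > off.mean()

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            gwas.compute_kinship(np.ones((5, 4)))


class TestPCs:
    def test_shapes_and_orthogonality(self, small_geno):
        X = encoding.expand_genotypes(small_geno, 2).values.astype(float)
        P = gwas.compute_pcs(X, 3)
        assert P.shape == (X.shape[0], 3)
        G = P.T @ P
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(40, 25))
        Z = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Z.T @ Z)
        order = np.argsort(w)[::-1]
        scores = Z @ V[:, order[:3]]
        P = gwas.compute_pcs(X, 3)
        for j in range(3):
            s = np.sign(scores[:, j] @ P[:, j])
            np.testing.assert_allclose(P[:, j], s * scores[:, j], atol=1e-8)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            gwas.compute_pcs(rng.normal(size=(5, 10)), 5)


class TestNullReml:
    def test_null_trait_estimates_small_genetic_fraction(self, medium_geno):
        K = gwas.compute_kinship(medium_geno.values).K
        ratios = []
        for s in range(10):
            y = np.random.default_rng(s).standard_normal(medium_geno.n)
            vc = gwas.fit_null_reml(y, np.ones((medium_geno.n, 1)), K)
            ratios.append(vc.sigma2_g / max(vc.sigma2_e, 1e-12))
        assert np.mean(ratios) < 0.25

    def test_strong_signal_small_delta(self, medium_geno):
        deltas = []
        for s in range(8):
            sim = simulate.simulate(medium_geno, nqtn=50, h2=0.9, r=0.5, seed=40 + s)
            y = sim.phenotypes.values[:, 0]
            K = gwas.compute_kinship(medium_geno.values).K
            deltas.append(gwas.fit_null_reml(y, np.ones((len(y), 1)), K).delta)
        assert np.median(deltas) < 0.6

    def test_returned_delta_is_local_optimum(self, small_geno, rng):
        K = gwas.compute_kinship(small_geno.values).K
        y = rng.standard_normal(small_geno.n) + K @ rng.standard_normal(small_geno.n)
        X = np.ones((small_geno.n, 1))
        vc = gwas.fit_null_reml(y, X, K)
        d, U = np.linalg.eigh(K)
        d = np.maximum(d, gwas.EIG_FLOOR)
        yt, Xt = U.T @ y, U.T @ X
        _, ld = np.linalg.slogdet(X.T @ X)
        at = -gwas._reml_neg_loglik(np.log(vc.delta), yt, Xt, d, ld)
        lo = -gwas._reml_neg_loglik(np.log(vc.delta / 2), yt, Xt, d, ld)
        hi = -gwas._reml_neg_loglik(np.log(vc.delta * 2), yt, Xt, d, ld)
        assert at >= lo - 1e-9 and at >= hi - 1e-9


class TestMlmScan:
    def test_zero_kinship_reduces_to_ols(self, rng):
        """With sigma2_g = 0 the scan equals OLS t-tests (statsmodels oracle)."""
        import statsmodels.api as sm

        n, m = 60, 8
        M = rng.integers(0, 3, size=(n, m)).astype(float)
        C = rng.normal(size=(n, 2))
        y = rng.normal(size=n) + M[:, 0] * 0.5
        vc = gwas.VarianceComponents(0.0, 1.0, np.inf, 0.0)
        res = gwas.mlm_scan(y, M, covariates=C, K=np.eye(n), vc=vc)
        for j in range(m):
            X = sm.add_constant(np.column_stack([C, M[:, j]]))
            fit = sm.OLS(y, X).fit()
            np.testing.assert_allclose(res.loc[j, "beta"], fit.params[-1], atol=1e-8)
            np.testing.assert_allclose(res.loc[j, "p"], fit.pvalues[-1], atol=1e-8)

    def test_matches_dense_gls_oracle(self, rng):
        n, m = 50, 5
        M = rng.integers(0, 3, size=(n, m)).astype(float)
        base = rng.normal(size=(n, 30))
        K = gwas.compute_kinship(base).K
        C = rng.normal(size=(n, 2))
        y = M[:, 1] * 0.6 + rng.multivariate_normal(np.zeros(n), 0.5 * K + np.eye(n))
        X0 = np.column_stack([np.ones(n), C])
        vc = gwas.fit_null_reml(y, X0, K)
        res = gwas.mlm_scan(y, M, covariates=C, K=K, vc=vc)
        d, U = np.linalg.eigh(K)
        d = np.maximum(d, gwas.EIG_FLOOR)
        V = (U * d) @ U.T + vc.delta * np.eye(n)  # proportional to the true V
        for j in range(m):
            Xf = np.column_stack([X0, M[:, j]])
            beta, se, t, p = _gls_oracle(y, Xf, V)
            np.testing.assert_allclose(res.loc[j, "beta"], beta[-1], atol=1e-6)
            np.testing.assert_allclose(res.loc[j, "se"], se[-1], rtol=1e-6)
            np.testing.assert_allclose(res.loc[j, "p"], p[-1], rtol=1e-5)

    def test_monomorphic_marker_skipped(self, rng):
        n = 30
        M = np.column_stack([np.full(n, 2.0), rng.integers(0, 3, n).astype(float)])
        res = gwas.mlm_scan(rng.normal(size=n), M)
        assert bool(res.loc[0, "skipped"]) and res.loc[0, "p"] == 1.0
        assert not bool(res.loc[1, "skipped"])

    def test_permutation_invariance(self, small_geno, rng):
        sim = simulate.simulate(small_geno, nqtn=5, h2=0.7, r=0.5, seed=21)
        y = encoding.mean_phenotype(sim.phenotypes)
        M = small_geno.values.astype(float)
        K = gwas.compute_kinship(M).K
        C = gwas.compute_pcs(M, 2)
        res = gwas.mlm_scan(y, M, covariates=C, K=K)
        perm = rng.permutation(len(y))
        res_p = gwas.mlm_scan(y[perm], M[perm], covariates=C[perm], K=K[np.ix_(perm, perm)])
        np.testing.assert_allclose(res["p"], res_p["p"], atol=1e-10)

    def test_p3d_close_to_exact(self, medium_geno):
        """P3D -log10 p within 0.2 of per-marker REML for >=95% of markers."""
        sim = simulate.simulate(medium_geno, nqtn=10, h2=0.5, r=0.5, seed=31)
        y = encoding.mean_phenotype(sim.phenotypes)
        M = medium_geno.values[:, :100].astype(float)
        K = gwas.compute_kinship(medium_geno.values).K
        res_p3d = gwas.mlm_scan(y, M, K=K, p3d=True)
        res_ex = gwas.mlm_scan(y, M, K=K, p3d=False)
        ok = ~(res_p3d["skipped"] | res_ex["skipped"])
        gap = np.abs(-np.log10(res_p3d.loc[ok, "p"]) + np.log10(res_ex.loc[ok, "p"]))
        assert (gap <= 0.2).mean() >= 0.95

    def test_interactive_tests_not_anticonservative_without_gxe(self, medium_geno):
        """r=1 (no interaction signal, independent noise): the interactive
        false-positive rate stays at or below nominal."""
        pvals = []
        for s in range(20):
            sim = simulate.simulate(medium_geno, nqtn=10, h2=0.5, r=1.0, seed=1000 + s)
            res = run_gwas(medium_geno, sim.phenotypes, mode="gbye", n_pcs=0)
            inter = res[res["effect_class"] != "additive"]
            pvals.extend(inter.loc[~inter["skipped"], "p"])
        pvals = np.asarray(pvals)
        se = np.sqrt(0.05 * 0.95 / len(pvals))
        assert (pvals < 0.05).mean() <= 0.05 + 2 * se
        # and p-values are spread, not degenerate
        assert 0.2 < np.median(pvals) < 0.8

    def test_interactive_contrast_degenerate_with_shared_residuals(self, small_geno):
        """Literally identical environments (shared residual draws) make the
        interaction contrast noiseless: interactive p-values pile up near 1."""
        rng = np.random.default_rng(55)
        q = simulate.sample_qtn(small_geno, 5, seed=rng)
        eff = simulate.sample_effects(5, 2, r=1.0, seed=rng)
        g = small_geno.values[:, q].astype(float) @ eff
        shared = rng.standard_normal(small_geno.n) * np.sqrt(g[:, 0].var(ddof=1))
        Y = PhenotypeTable(g + shared[:, None], ["env1", "env2"], small_geno.individual_ids)
        res = run_gwas(small_geno, Y, mode="gbye", n_pcs=0)
        inter = res[(res["effect_class"] != "additive") & ~res["skipped"]]
        assert inter["p"].median() > 0.5


class TestCollapse:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["marker_id", "effect_class", "p"]).assign(
            beta=0.0, se=1.0, t=0.0, df=10, skipped=False
        )

    def test_min_mode_records_winning_class(self):
        res = self._results([("m1", "additive", 0.01), ("m1", "interactive:env2", 0.50)])
        out = gwas.collapse_pvalues(res, "min")
        assert len(out) == 1
        assert out.loc[0, "p"] == 0.01 and out.loc[0, "effect_class"] == "additive"

    def test_bonferroni_min(self):
        res = self._results([("m1", "additive", 0.01), ("m1", "interactive:env2", 0.50)])
        out = gwas.collapse_pvalues(res, "bonf-min")
        np.testing.assert_allclose(out.loc[0, "p"], 0.02)

    def test_bonferroni_capped_at_one(self):
        res = self._results([("m1", "additive", 0.9), ("m1", "interactive:env2", 0.9)])
        out = gwas.collapse_pvalues(res, "bonf-min")
        assert out.loc[0, "p"] == 1.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            gwas.collapse_pvalues(self._results([("m1", "additive", 0.5)]), "median")
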