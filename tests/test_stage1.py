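"""Stage-1 pooling methods and homogeneity tests."""

import numpy as np
import pytest
from scipy import optimize

from masem import (
    SIGMA,
    StudySet,
    corr_to_vec,
    homogeneity_ba1,
    olkin_siotani_acov,
    pool_mgls,
    pool_tssem,
    pool_unir,
    pool_uniz,
    vec_to_corr,
)
from masem.model import PAIR_INDICES


def _studyset_from_vecs(ns, vecs, labels=None):
    return StudySet(
        sizes=list(ns), matrices=[vec_to_corr(v) for v in vecs], labels=labels or []
    )


def _perturbed(base, delta, element=0):
    v = np.array(base, dtype=float)
    v[element] += delta
    return v


BASE = corr_to_vec(SIGMA)


class TestUnivariatePooling:
    def test_unir_weighted_mean_hand_value(self):
        vecs = [np.full(6, 0.5), np.full(6, 0.7)]
        res = pool_unir(_studyset_from_vecs([100, 300], vecs))
        assert np.allclose(res.pooled, (0.5 * 100 + 0.7 * 300) / 400)

    def test_uniz_closed_form_hand_value(self):
        vecs = [np.full(6, 0.0), np.full(6, 0.6)]
        res = pool_uniz(_studyset_from_vecs([103, 103], vecs))
        assert np.allclose(res.pooled, np.tanh(np.arctanh(0.6) / 2.0))
        assert res.pooled[0] == pytest.approx(1.0 / 3.0, abs=1e-6)

    @pytest.mark.parametrize("pool", [pool_unir, pool_uniz])
    def test_identical_studies_recovered(self, pool):
        res = pool(_studyset_from_vecs([50, 80, 120], [BASE] * 3))
        assert np.allclose(res.pooled, BASE, atol=1e-12)
        assert res.per_element_stat.max() < 1e-20
        assert not res.reject

    def test_equal_sizes_give_unweighted_mean(self):
        vecs = [BASE, _perturbed(BASE, 0.1), _perturbed(BASE, -0.1)]
        res = pool_unir(_studyset_from_vecs([100, 100, 100], vecs))
        assert np.allclose(res.pooled, np.mean(vecs, axis=0))

    @pytest.mark.parametrize("pool", [pool_unir, pool_uniz])
    def test_pooled_between_study_extremes(self, pool):
        vecs = [np.full(6, 0.2), np.full(6, 0.5), np.full(6, 0.8)]
        res = pool(_studyset_from_vecs([30, 90, 60], vecs))
        assert np.all(res.pooled >= 0.2 - 1e-12) and np.all(res.pooled <= 0.8 + 1e-12)


class TestBA1:
    def test_z_scale_hand_value(self):
        """k=2, n=103 each, one element's z-values (0, 0.4) => Q = 8 on 1 df."""
        vecs = [BASE.copy(), BASE.copy()]
        vecs[0][3] = np.tanh(0.0)
        vecs[1][3] = np.tanh(0.4)
        q, p, _ = homogeneity_ba1(_studyset_from_vecs([103, 103], vecs), scale="z")
        assert q[3] == pytest.approx(100 * 0.2**2 * 2, abs=1e-10)
        np.testing.assert_allclose(np.delete(q, 3), 0.0, atol=1e-20)

    def test_rejects_only_below_bonferroni_level(self):
        from scipy import stats

        vecs = [BASE, _perturbed(BASE, 0.25)]
        studies = _studyset_from_vecs([200, 200], vecs)
        q, p, reject = homogeneity_ba1(studies, scale="z", alpha=0.05)
        assert reject == (p.min() < 0.05 / 6)
        assert np.all(q >= 0)
        assert np.allclose(p, stats.chi2.sf(q, df=1))

    def test_single_study_undefined(self):
        with pytest.raises(ValueError, match="2 studies"):
            homogeneity_ba1(_studyset_from_vecs([100], [BASE]))


class TestOlkinSiotani:
    def test_zero_correlations_give_identity_over_n(self):
        V = olkin_siotani_acov(np.zeros(6), 50)
        assert np.allclose(V, np.eye(6) / 50)

    def test_diagonal_closed_form(self):
        V = olkin_siotani_acov(BASE, 100)
        assert V[0, 0] == pytest.approx((1 - 0.65**2) ** 2 / 100, abs=1e-12)
        for i, (a, b) in enumerate(PAIR_INDICES):
            assert V[i, i] == pytest.approx((1 - SIGMA[a, b] ** 2) ** 2 / 100, rel=1e-10)

    def test_matches_monte_carlo_covariance(self, rng):
        """Brute-force oracle: empirical covariance of sample correlations."""
        n, reps = 500, 30_000
        L = np.linalg.cholesky(SIGMA)
        vecs = np.empty((reps, 6))
        rows = [p[0] for p in PAIR_INDICES]
        cols = [p[1] for p in PAIR_INDICES]
        for i in range(reps):
            X = rng.standard_normal((n, 4)) @ L.T
            R = np.corrcoef(X, rowvar=False)
            vecs[i] = R[rows, cols]
        emp = np.cov(vecs, rowvar=False)
        V = olkin_siotani_acov(BASE, n)
        # MC error on covariance entries of magnitude ~1/n
        assert np.abs(emp - V).max() < 4.0 / (n * np.sqrt(reps) / 10)

    def test_non_pd_rho_raises(self):
        with pytest.raises(ValueError, match="positive-definite"):
            olkin_siotani_acov(np.array([0.99, 0.99, 0.0, -0.99, 0.0, 0.0]), 100)


class TestMGLS:
    def test_identical_equal_studies(self):
        res = pool_mgls(_studyset_from_vecs([100, 100, 100], [BASE] * 3))
        assert np.allclose(res.pooled, BASE, atol=1e-10)
        assert res.stat == pytest.approx(0.0, abs=1e-16)
        assert res.df == 12

    def test_common_weights_reduce_to_unir(self, small_studyset):
        """With one plug-in weight matrix the GLS mean equals the n-weighted mean."""
        res = pool_mgls(small_studyset)
        unir = pool_unir(small_studyset)
        assert np.allclose(res.pooled, unir.pooled, atol=1e-10)

    def test_matches_stacked_regression_oracle(self, small_studyset):
        """Equal-n GLS equals solving the explicitly stacked normal equations."""
        ns = np.asarray(small_studyset.sizes, float)
        rs = np.stack([corr_to_vec(R) for R in small_studyset.matrices])
        rtilde = ns @ rs / ns.sum()
        V = olkin_siotani_acov(rtilde, 1.0)
        k = len(ns)
        X = np.tile(np.eye(6), (k, 1))
        Winv = np.kron(np.diag(1.0 / ns), V)
        beta = np.linalg.solve(X.T @ np.linalg.solve(Winv, X), X.T @ np.linalg.solve(Winv, rs.ravel()))
        res = pool_mgls(small_studyset)
        assert np.allclose(res.pooled, beta, atol=1e-10)

    def test_reordering_invariance(self, small_studyset):
        res = pool_mgls(small_studyset)
        perm = [3, 1, 4, 0, 2]
        shuffled = StudySet(
            sizes=[small_studyset.sizes[i] for i in perm],
            matrices=[small_studyset.matrices[i] for i in perm],
            labels=[small_studyset.labels[i] for i in perm],
        )
        res2 = pool_mgls(shuffled)
        assert res2.stat == pytest.approx(res.stat, rel=1e-10)
        assert np.allclose(res2.pooled, res.pooled, atol=1e-12)


class TestTSSEM:
    def test_identical_groups_perfect_fit(self, small_studyset):
        R = small_studyset.matrices[0]
        studies = StudySet(sizes=[80, 80, 80], matrices=[R.copy() for _ in range(3)])
        res = pool_tssem(studies, compute_acov=False)
        assert res.stat == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(res.pooled, corr_to_vec(R), atol=1e-5)

    def test_matches_multistart_oracle_k2(self):
        """LR statistic agrees with a generic derivative-free multi-start optimizer."""
        rng = np.random.default_rng(99)
        L = np.linalg.cholesky(SIGMA)
        mats, ns = [], [60, 140]
        for n in ns:
            X = rng.standard_normal((n, 4)) @ L.T
            mats.append(np.corrcoef(X, rowvar=False))
        studies = StudySet(sizes=ns, matrices=mats)
        res = pool_tssem(studies, compute_acov=False)

        S = np.stack(mats)
        w = np.asarray(ns, float) / sum(ns)
        logdetS = np.linalg.slogdet(S)[1]

        def fobj(x):
            rho, d = x[:6], np.exp(x[6:].reshape(2, 4))
            R = vec_to_corr(rho)
            try:
                np.linalg.cholesky(R)
            except np.linalg.LinAlgError:
                return 1e8
            f = 0.0
            for g in range(2):
                Sig = np.outer(d[g], d[g]) * R
                sgn, ld = np.linalg.slogdet(Sig)
                f += w[g] * (ld - logdetS[g] + np.trace(np.linalg.solve(Sig, S[g])) - 4)
            return f

        best = np.inf
        for s in range(20):
            r2 = np.random.default_rng(s)
            x0 = np.concatenate([corr_to_vec(SIGMA) + r2.normal(0, 0.05, 6), r2.normal(0, 0.1, 8)])
            out = optimize.minimize(fobj, x0, method="Nelder-Mead",
                                    options={"maxiter": 20000, "fatol": 1e-13, "xatol": 1e-9})
            best = min(best, out.fun)
        assert res.stat == pytest.approx(sum(ns) * best, abs=1e-4)

    def test_reordering_invariance(self, small_studyset):
        res = pool_tssem(small_studyset, compute_acov=False)
        perm = [4, 2, 0, 1, 3]
        shuffled = StudySet(
            sizes=[small_studyset.sizes[i] for i in perm],
            matrices=[small_studyset.matrices[i] for i in perm],
            labels=[small_studyset.labels[i] for i in perm],
        )
        res2 = pool_tssem(shuffled, compute_acov=False)
        assert res2.stat == pytest.approx(res.stat, abs=1e-6)

    def test_acov_is_symmetric_positive_definite(self, small_studyset):
        res = pool_tssem(small_studyset, compute_acov=True)
        assert res.converged
        assert np.allclose(res.acov, res.acov.T)
        assert np.linalg.eigvalsh(res.acov).min() > 0
        # pooled-correlation variances shrink like 1/N: same order as Olkin-Siotani
        V = olkin_siotani_acov(res.pooled, small_studyset.total_n)
        assert np.all(np.diag(res.acov) < 3 * np.diag(V))
        assert np.all(np.diag(res.acov) > np.diag(V) / 3)


def test_all_methods_consistent_at_large_n():
    """All four pooled estimates converge to the population vector."""
    from masem import SimCellConfig, simulate_meta

    cfg = SimCellConfig(k=5, nbar=10_000, design="E", seed=13, replications=1)
    studies = simulate_meta(cfg, 0)
    for pool in (pool_unir, pool_uniz, pool_mgls):
        assert np.abs(pool(studies).pooled - BASE).max() < 0.02
    assert np.abs(pool_tssem(studies, compute_acov=False).pooled - BASE).max() < 0.02
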