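"""Kinship, GLM/MLM scans, genomic control and the Spearman climate scan."""

import numpy as np
import pytest
from scipy import stats

from clinescan.association import (
    glm_scan,
    kinship_matrix,
    lambda_gc,
    mlm_scan,
    select_model,
    spearman_climate_scan,
)


class TestKinship:
    def test_single_snp_hand_value(self, toy_vt):
        vt = toy_vt(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(
            kinship_matrix(vt), [[1, -1], [-1, 1]], atol=1e-12
        )

    def test_duplicated_sample(self, toy_vt):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(5, 60)).astype(float)
        d[1] = d[0]
        k = kinship_matrix(toy_vt(d))
        assert k[0, 1] == pytest.approx(k[0, 0])
        assert k[0, 1] == pytest.approx(k[1, 1])

    def test_unrelated_samples_near_zero_offdiag(self, toy_vt):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 500), size=(40, 500)).astype(float)
        k = kinship_matrix(toy_vt(d))
        off = k[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 0.05
        evals = np.linalg.eigvalsh(k)
        assert evals.min() > -1e-8

    def test_monomorphic_only_errors(self, toy_vt):
        with pytest.raises(ValueError):
            kinship_matrix(toy_vt(np.zeros((4, 3))))


class TestGlmScan:
    def test_perfect_association(self, toy_vt):
        d = np.array([[0.0], [1.0], [2.0], [1.0], [0.0]])
        res = glm_scan(toy_vt(d), d[:, 0] * 3.0 + 1.0)
        assert res["r2"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] < 1e-10

    def test_hand_ols_r2(self, toy_vt):
        # y=[1,2,3,4], x=[0,1,1,2]: r = 3/sqrt(10), r2 = 0.9
        res = glm_scan(toy_vt(np.array([[0.0], [1.0], [1.0], [2.0]])),
                       np.array([1.0, 2.0, 3.0, 4.0]))
        assert res["r2"].iloc[0] == pytest.approx(0.9, abs=1e-12)

    def test_null_p_uniform(self, toy_vt):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.5, size=(400, 2000)).astype(float)
        y = rng.normal(size=400)
        res = glm_scan(toy_vt(d), y)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_r2_invariant_to_affine_and_flip(self, toy_vt):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, size=(50, 20)).astype(float)
        y = rng.normal(size=50)
        base = glm_scan(toy_vt(d), y)["r2"]
        scaled = glm_scan(toy_vt(2.0 - d), 5.0 - 3.0 * y)["r2"]
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_rank_deficient_covariates(self, toy_vt):
        d = np.array([[0.0], [1.0], [2.0], [1.0]])
        cov = np.ones((4, 2))
        with pytest.raises(ValueError):
            glm_scan(toy_vt(d), np.arange(4.0), cov)


class TestMlmScan:
    def test_identity_kinship_reduces_to_glm(self, toy_vt):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=(60, 100)).astype(float)
        y = rng.normal(size=60) + d[:, 0]
        vt = toy_vt(d)
        g = glm_scan(vt, y)
        m = mlm_scan(vt, y, None, np.eye(60))
        np.testing.assert_allclose(g["p"], m["p"], atol=1e-6)
        np.testing.assert_allclose(g["r2"], m["r2"], atol=1e-6)

    def test_structured_phenotype_deflated_by_K(self, toy_vt):
        # two demes with different allele frequencies and a deme-level
        # phenotype shift: plain GLM inflates, the mixed model does not
        rng = np.random.default_rng(5)
        n = 100
        freqs = np.vstack([rng.uniform(0.1, 0.9, 800), rng.uniform(0.1, 0.9, 800)])
        deme = np.repeat([0, 1], n // 2)
        d = rng.binomial(2, freqs[deme]).astype(float)
        y = deme * 2.0 + rng.normal(size=n)
        vt = toy_vt(d)
        lam_glm = lambda_gc(glm_scan(vt, y)["p"])
        lam_mlm = lambda_gc(mlm_scan(vt, y, None, kinship_matrix(vt))["p"])
        assert lam_mlm < lam_glm
        assert lam_glm > 1.2

    def test_variance_ratio_recovery(self, toy_vt):
        rng = np.random.default_rng(6)
        n, m = 300, 600
        d = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        vt = toy_vt(d)
        k = kinship_matrix(vt)
        lam, u = np.linalg.eigh(k)
        g = u @ (np.sqrt(np.clip(lam, 0, None)) * rng.normal(size=n))
        y = g + rng.normal(size=n)  # sigma2_g = sigma2_e = 1
        res = mlm_scan(vt, y, None, k)
        delta = res.attrs["delta"]  # sigma2_e / sigma2_g
        assert 0.5 < 1.0 / delta < 2.0


class TestLambdaGc:
    def test_definition_at_half(self):
        assert lambda_gc(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_null(self):
        rng = np.random.default_rng(7)
        assert 0.98 < lambda_gc(rng.uniform(size=100000)) < 1.02

    def test_inflated_chi2(self):
        rng = np.random.default_rng(8)
        chi2 = 1.5 * rng.chisquare(1, size=100000)
        p = stats.chi2.sf(chi2, 1)
        assert lambda_gc(p) == pytest.approx(1.5, rel=0.02)


class TestSelectModel:
    def test_most_parsimonious_in_window(self):
        lams = {"simple": 1.6, "PC2": 1.3, "PC5": 1.15, "PC2+K": 1.02}
        assert select_model(lams) == ("PC5", True)

    def test_all_in_window_prefers_simple(self):
        lams = {"simple": 1.0, "PC2": 1.0, "K": 1.0}
        assert select_model(lams) == ("simple", True)

    def test_fallback_nearest_with_warning(self):
        lams = {"simple": 1.9, "PC2": 1.5, "PC2+K": 1.31}
        with pytest.warns(UserWarning):
            tag, ok = select_model(lams)
        assert (tag, ok) == ("PC2+K", False)


class TestSpearmanScan:
    def test_monotone_dosage(self, toy_vt):
        d = np.array([[0.0], [1.0], [2.0]])
        res = spearman_climate_scan(toy_vt(d), np.array([1.0, 5.0, 9.0]))
        assert res["statistic"].iloc[0] == pytest.approx(1.0)
        assert res["r2"].iloc[0] == pytest.approx(1.0)

    def test_hand_rank_value(self, toy_vt):
        # x=[1,2,3] vs y=[3,1,2]: sum d^2 = 6 -> rho = -0.5
        d = np.array([[1.0], [2.0], [3.0]])
        res = spearman_climate_scan(toy_vt(d), np.array([3.0, 1.0, 2.0]))
        assert res["statistic"].iloc[0] == pytest.approx(-0.5)
        ref = stats.spearmanr(d[:, 0], [3.0, 1.0, 2.0])
        assert res["statistic"].iloc[0] == pytest.approx(ref.statistic)

    def test_matches_scipy_with_ties(self, toy_vt):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.4, size=(80, 30)).astype(float)
        clim = np.repeat(rng.normal(size=8), 10)
        res = spearman_climate_scan(toy_vt(d), clim)
        for j in (0, 7, 19):
            ref = stats.spearmanr(d[:, j], clim)
            assert res["statistic"].iloc[j] == pytest.approx(ref.statistic, abs=1e-12)
            assert res["p"].iloc[j] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_permutation_null_matches(self, toy_vt):
        rng = np.random.default_rng(10)
        d = rng.binomial(2, 0.5, size=(150, 800)).astype(float)
        clim = np.repeat(rng.normal(size=15), 10)
        obs = spearman_climate_scan(toy_vt(d), clim)["r2"]
        perm = spearman_climate_scan(toy_vt(d), rng.permutation(clim))["r2"]
        assert stats.ks_2samp(obs, perm).pvalue > 0.01

    def test_constant_climate_errors(self, toy_vt):
        with pytest.raises(ValueError):
            spearman_climate_scan(toy_vt(np.zeros((4, 2))), np.ones(4))
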