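"""Redundancy analysis: predictor pruning, constrained ordination, outliers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clinescan.io_binning import filter_variants
from clinescan.rda import fit_rda, rda_outliers, select_predictors


def _predictors(n, p, rng, names=None):
    x = rng.normal(size=(n, p))
    return pd.DataFrame(x, columns=names or [f"v{j}" for j in range(p)])


class TestSelectPredictors:
    def test_identical_variables_collapse(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        clim = pd.DataFrame({"x": a, "y": a})
        assert select_predictors(clim) == ["x"]

    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(1)
        clim = _predictors(200, 4, rng)
        assert select_predictors(clim) == list(clim.columns)

    def test_redundant_pair_pruned(self):
        rng = np.random.default_rng(2)
        a, b, c = rng.normal(size=(3, 100))
        clim = pd.DataFrame({"a": a, "b": b, "a2": a + 0.05 * rng.normal(size=100), "c": c})
        kept = select_predictors(clim, r_max=0.75)
        assert kept == ["a", "b", "c"]

    def test_priority_order_respected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=60)
        clim = pd.DataFrame({"x": a, "y": a})
        assert select_predictors(clim, priority=["y", "x"]) == ["y"]


class TestFitRda:
    def test_exact_linear_response(self, toy_vt):
        rng = np.random.default_rng(4)
        x = _predictors(40, 2, rng)
        b = rng.normal(size=(2, 15))
        y = (x.to_numpy() - x.to_numpy().mean(0)) @ b
        vt = toy_vt(y - y.min())  # dosage-like shift; centring removes it
        model = fit_rda(vt, x)
        assert model.constrained_fraction == pytest.approx(1.0, abs=1e-10)
        # locus scores equal PCA loadings of Y itself in the noise-free case
        yc = y - y.mean(axis=0)
        _, _, vh = np.linalg.svd(yc / np.sqrt(39), full_matrices=False)
        for a in range(2):
            ref, got = vh[a], model.locus_scores[:, a]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8

    def test_orthogonal_predictors_no_variance(self, toy_vt):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(200, 10))
        x = _predictors(200, 2, rng)
        model = fit_rda(toy_vt(y), x)
        assert model.constrained_fraction < 0.05
        assert model.eigenvalues.sum() <= (y - y.mean(0)).var(axis=0, ddof=1).sum()

    def test_toy_matches_hand_svd(self, toy_vt):
        y = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 2.0], [2.0, 1.0, 0.0], [1.0, 2.0, 2.0]])
        x = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        model = fit_rda(toy_vt(y), x)
        xs = (x.to_numpy() - 2.5) / np.std(x.to_numpy(), ddof=1)
        yc = y - y.mean(axis=0)
        fitted = xs @ np.linalg.lstsq(xs, yc, rcond=None)[0]
        u, s, vh = np.linalg.svd(fitted / np.sqrt(3), full_matrices=False)
        assert model.eigenvalues[0] == pytest.approx(s[0] ** 2, abs=1e-10)
        got, ref = model.locus_scores[:, 0], vh[0]
        assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-10

    def test_projection_idempotence(self, toy_vt):
        rng = np.random.default_rng(6)
        y = rng.binomial(2, 0.4, size=(60, 40)).astype(float)
        x = _predictors(60, 3, rng)
        model = fit_rda(toy_vt(y), x)
        xs = model.predictors.to_numpy()
        h = xs @ np.linalg.solve(xs.T @ xs, xs.T)
        fitted = h @ (y - y.mean(0))
        assert np.abs(fitted - h @ fitted).max() < 1e-8

    def test_locus_scores_reproduce_gram_eigendecomposition(self, toy_vt):
        rng = np.random.default_rng(7)
        y = rng.binomial(2, 0.5, size=(50, 30)).astype(float)
        x = _predictors(50, 3, rng)
        model = fit_rda(toy_vt(y), x)
        xs = model.predictors.to_numpy()
        fitted = xs @ np.linalg.lstsq(xs, y - y.mean(0), rcond=None)[0]
        evals, evecs = np.linalg.eigh(fitted.T @ fitted / 49)
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(model.eigenvalues, evals[order][:3], atol=1e-8)
        for a in range(3):
            ref, got = evecs[:, order[a]], model.locus_scores[:, a]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8

    def test_collinear_predictors_rejected(self, toy_vt):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(30, 5))
        a = rng.normal(size=30)
        x = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError):
            fit_rda(toy_vt(y), x)


class TestRdaOutliers:
    def _model_with_injected_outlier(self, rng, extreme_snp=7):
        n, m = 80, 60
        x = _predictors(n, 2, rng)
        y = rng.normal(size=(n, m)) * 0.5
        y[:, extreme_snp] += 4.0 * x.to_numpy()[:, 0]  # strong loading on axis 1
        vt_like = y - y.min()
        return x, vt_like

    def test_injected_extreme_snp_flagged(self, toy_vt):
        rng = np.random.default_rng(9)
        x, y = self._model_with_injected_outlier(rng)
        vt = toy_vt(y)
        model = fit_rda(vt, x)
        out = rda_outliers(model, vt, n_axes=2)
        assert "s7" in set(out["snp_id"])
        flagged_axis1 = out[out["axis"] == 1]["snp_id"].tolist()
        assert flagged_axis1 == ["s7"]

    def test_infinite_sd_mult_yields_nothing(self, toy_vt):
        rng = np.random.default_rng(10)
        x, y = self._model_with_injected_outlier(rng)
        vt = toy_vt(y)
        model = fit_rda(vt, x)
        assert rda_outliers(model, vt, n_axes=2, sd_mult=np.inf).empty

    def test_predictor_assignment_by_max_correlation(self, toy_vt):
        rng = np.random.default_rng(11)
        x = _predictors(100, 2, rng, names=["hot", "wet"])
        y = rng.normal(size=(100, 20)) * 0.3
        y[:, 4] = x["wet"].to_numpy()  # dosage literally equals a predictor
        vt = toy_vt(y - y.min())
        model = fit_rda(vt, x)
        out = rda_outliers(model, vt, n_axes=2)
        row = out[out["snp_id"] == "s4"].iloc[0]
        assert row["predictor"] == "wet"
        assert abs(row["r"]) == pytest.approx(1.0, abs=1e-9)

    def test_too_many_axes_rejected(self, toy_vt):
        rng = np.random.default_rng(12)
        x = _predictors(30, 2, rng)
        vt = toy_vt(rng.normal(size=(30, 10)))
        model = fit_rda(vt, x)
        with pytest.raises(ValueError):
            rda_outliers(model, vt, n_axes=5)


def test_clinal_snps_enriched_among_outliers(small_study):
    """Causal (climate-clinal) SNPs are overrepresented among RDA locus-score
    outliers relative to neutral SNPs."""
    study = small_study
    lat = study.samples[study.samples["transect"] == "lat"]
    vt = filter_variants(study.variants.subset_samples(lat["clone"].tolist()))
    clim = study.climate.set_index("provenance").loc[lat["provenance"]]
    kept = select_predictors(clim[["MAT", "MAP", "TD", "PAS", "EMT"]])
    model = fit_rda(vt, clim[kept].reset_index(drop=True))
    out = rda_outliers(model, vt, n_axes=min(3, model.n_axes))
    causal = {s for s, _ in study.truth.causal_snps["lat"]}
    flagged = set(out["snp_id"])
    present_causal = causal & set(vt.snp_id)
    tab = np.array(
        [
            [len(present_causal & flagged), len(present_causal - flagged)],
            [len(flagged - causal), vt.n_snps - len(present_causal) - len(flagged - causal)],
        ]
    )
    odds, p = stats.fisher_exact(tab, alternative="greater")
    assert odds > 1
    assert p < 0.05
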