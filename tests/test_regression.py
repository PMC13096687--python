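"""Logistic / phylogenetic regression, partial R2, AIC comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from slp_biogeo.regression import (compare_models, fit_logistic, fit_phyloglm,
                                   fit_phylolm, lr_test, partial_r2lik,
                                   partial_r2_table)
from slp_biogeo.tree import read_newick


class TestFitLogistic:
    def test_balanced_intercept(self):
        y = np.array([0, 1] * 20)
        f = fit_logistic(y)
        assert f.beta[0] == pytest.approx(0.0, abs=1e-6)

    def test_quarter_intercept(self):
        y = np.array([1, 0, 0, 0] * 25)
        f = fit_logistic(y)
        assert f.beta[0] == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_separation_unpenalized_flags(self):
        x = np.arange(10, dtype=float)
        y = (x > 4).astype(float)
        f = fit_logistic(y, x[:, None], firth=False)
        assert not f.converged

    def test_separation_firth_converges(self):
        x = np.arange(10, dtype=float)
        y = (x > 4).astype(float)
        f = fit_logistic(y, x[:, None], firth="auto")
        assert f.converged
        assert f.method == "logistic-firth"
        assert np.all(np.isfinite(f.beta)) and np.all(np.isfinite(f.se))

    def test_constant_response_error(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10))


class TestStarTreeEquivalence:
    """With no shared history the phylogenetic fits must reduce to their
    non-phylogenetic counterparts."""

    def test_phyloglm_matches_logistic(self, star100):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 2))
        y = (rng.random(100) < expit(0.3 + X @ [1.0, -0.5])).astype(float)
        ref = fit_logistic(y, X, firth=True)
        fit = fit_phyloglm(y, X, star100, penalized=True)
        np.testing.assert_allclose(fit.beta, ref.beta, rtol=1e-3)
        ref0 = fit_logistic(y, X, firth=False)
        fit0 = fit_phyloglm(y, X, star100, penalized=False)
        np.testing.assert_allclose(fit0.beta, ref0.beta, rtol=1e-3)
        assert fit0.logLik == pytest.approx(ref0.logLik, abs=1e-3)

    def test_phylolm_matches_ols(self, star100):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 2))
        y = 1.0 + X @ [2.0, -1.0] + rng.standard_normal(100)
        fit = fit_phylolm(y, X, star100)
        ols = np.linalg.lstsq(np.column_stack([np.ones(100), X]), y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, rtol=1e-3)


class TestPhyloLMOracle:
    """Frozen reference values from an independent Brownian GLS fit
    (ape::corBrownian + nlme::gls, method='ML') on an 8-tip fixture."""

    NEWICK = ("((A:1,(B:0.5,C:0.5):0.5):2,"
              "((D:1.5,E:1.5):0.5,(F:1,(G:0.4,H:0.4):0.6):1):1);")
    X = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1, 0.0, -0.5])
    Y = np.array([1.0, 0.2, 0.8, 3.1, 0.5, 2.0, 1.2, 0.3])
    REF_BETA = (0.9987189851, 0.7817512625)
    REF_LOGLIK = -4.6153361950
    REF_SIGMA2_CORR = 0.3207118567   # on the unit-diagonal correlation scale
    REF_SE = (0.3778921267, 0.1466375235)  # with n-p denominator

    def test_matches_reference(self):
        tree = read_newick(self.NEWICK, from_string=True)
        order = {lab: i for i, lab in
                 enumerate(["A", "B", "C", "D", "E", "F", "G", "H"])}
        sel = [order[lab] for lab in tree.tip_labels]
        fit = fit_phylolm(self.Y[sel], self.X[sel][:, None], tree)
        np.testing.assert_allclose(fit.beta, self.REF_BETA, rtol=1e-8)
        assert fit.logLik == pytest.approx(self.REF_LOGLIK, abs=1e-8)
        # reference scales the Brownian covariance to unit diagonal
        # (tree height 3) and uses an n-p denominator for the coef vcov
        assert fit.sigma2 * tree.height == pytest.approx(self.REF_SIGMA2_CORR,
                                                         rel=1e-8)
        n, p = 8, 2
        np.testing.assert_allclose(fit.se * np.sqrt(n / (n - p)), self.REF_SE,
                                   rtol=1e-8)


class TestPhyloGLM:
    def test_detects_signal_and_nests(self, bench300):
        ds = bench300.dataset
        firth = fit_phyloglm(ds.trait, ds.design, ds.phylogeny)
        assert firth.alpha > 0
        assert not firth.alpha_at_bound  # strong simulated signal
        assert np.all((firth.p >= 0) & (firth.p <= 1))
        # likelihood nesting holds for the unpenalised ML fits
        full = fit_phyloglm(ds.trait, ds.design, ds.phylogeny, penalized=False)
        reduced = fit_phyloglm(ds.trait, ds.design.drop(columns=["richness"]),
                               ds.phylogeny, penalized=False)
        assert full.logLik >= reduced.logLik - 1e-6
        plain = fit_logistic(ds.trait, ds.design)
        assert full.logLik >= plain.logLik

    def test_constant_predictor_error(self, bench300):
        ds = bench300.dataset
        X = ds.design.copy()
        X["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_phyloglm(ds.trait, X, ds.phylogeny)

    def test_partial_r2_table_structure(self, bench300):
        ds = bench300.dataset
        table = partial_r2_table(ds.trait, ds.design, ds.phylogeny)
        assert set(table.index) == {"tropical", "hotspot", "richness", "phylogeny"}
        assert ((table["r2lik"] > -1e-9) & (table["r2lik"] < 1)).all()
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
        # simulated with phylogenetic signal: the phylogeny component is real
        assert table.loc["phylogeny", "r2lik"] > 0
        assert table.loc["phylogeny", "p"] < 0.05


class TestPartialR2:
    def test_equal_likelihoods(self):
        assert partial_r2lik(-100.0, -100.0, 50) == 0.0

    def test_closed_form(self):
        assert partial_r2lik(-98.0, -100.0, 100) == pytest.approx(
            1 - np.exp(-0.04), rel=1e-12)
        assert partial_r2lik(-98.0, -100.0, 100) == pytest.approx(0.03921, abs=1e-5)

    def test_bad_n(self):
        with pytest.raises(ValueError):
            partial_r2lik(-1.0, -2.0, 0)

    def test_warns_on_inversion(self):
        with pytest.warns(UserWarning):
            partial_r2lik(-101.0, -100.0, 50)

    def test_monotone_in_delta(self):
        vals = [partial_r2lik(-100.0 + d, -100.0, 80) for d in (0.5, 1, 2, 4)]
        assert vals == sorted(vals)
        assert all(0 <= v < 1 for v in vals)

    def test_lr_pvalue(self):
        assert lr_test(-100.0, -100.0) == 1.0
        assert 0 < lr_test(-95.0, -100.0) < 0.01


class TestCompareModels:
    class Fake:
        def __init__(self, ll, k, n=100):
            self.logLik, self.n_params, self.n = ll, k, n

    def test_equal_aic(self):
        out = compare_models([self.Fake(-100, 3), self.Fake(-100, 3)])
        np.testing.assert_allclose(out["akaike_weight"], [0.5, 0.5])

    def test_delta_two(self):
        out = compare_models([self.Fake(-100, 3), self.Fake(-101, 3)])
        np.testing.assert_allclose(out["akaike_weight"],
                                   [1 / (1 + np.exp(-1)), np.exp(-1) / (1 + np.exp(-1))],
                                   rtol=1e-12)
        assert out["akaike_weight"].iloc[0] == pytest.approx(0.731, abs=1e-3)
        assert out["delta_aic"].min() == 0

    def test_weights_sum_to_one(self):
        out = compare_models([self.Fake(-100, 3), self.Fake(-104, 5),
                              self.Fake(-99, 7)])
        assert out["akaike_weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="different"):
            compare_models([self.Fake(-100, 3, n=100), self.Fake(-100, 3, n=90)])
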