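"""Tests of the six classifiers: uniform API, structural invariants,
full-rank collapses onto plain IRLS, and method-specific closed forms."""

import numpy as np
import pytest
from scipy import linalg
from sklearn.base import clone

from lspls.estimators import (
    ALL_METHODS,
    ClinicalGLM,
    IRLSPLS,
    LSPCR,
    LSPLSIRLS,
    RLSPLS,
    RPLS,
    fit_glm,
    fit_ir_lspls,
    fit_ls_pcr,
    fit_lspls_irls,
    fit_r_lspls,
    fit_r_pls,
    predict,
)
from lspls.glm import irls
from lspls.pls import lspls_fit, orthogonalize


def _augment(D):
    return np.column_stack([np.ones(len(D)), D])


def _fit_all(D, X, y):
    return {
        "GLM": fit_glm(y, D),
        "R-PLS": fit_r_pls(y, X, 2, 1.0),
        "LS-PCR": fit_ls_pcr(y, D, X, 2),
        "LS-PLS-IRLS": fit_lspls_irls(y, D, X, 2),
        "IR-LS-PLS": fit_ir_lspls(y, D, X, 2),
        "R-LS-PLS": fit_r_lspls(y, D, X, 2, 1.0),
    }


class TestUniformInterface:
    def test_all_methods_registered(self):
        assert set(ALL_METHODS) == {
            "GLM", "R-PLS", "LS-PCR", "LS-PLS-IRLS", "IR-LS-PLS", "R-LS-PLS"
        }

    def test_fitted_attributes_and_prediction_shapes(self, small_logistic_data):
        D, X, y = small_logistic_data
        for name, model in _fit_all(D, X, y).items():
            assert model.method == name
            assert isinstance(model.converged_, bool) or model.converged_ in (0, 1)
            assert model.n_iter_ >= 1
            assert np.isscalar(model.intercept_)
            pi, yhat = predict(model, D, X)
            assert pi.shape == yhat.shape == y.shape
            assert np.all((pi > 0) & (pi < 1))
            assert set(np.unique(yhat)) <= {0, 1}

    def test_training_row_probability_consistency(self, small_logistic_data):
        # predict on the training rows reproduces the in-sample probabilities
        D, X, y = small_logistic_data
        for name, model in _fit_all(D, X, y).items():
            pi1, _ = predict(model, D, X)
            pi2, _ = predict(model, D.copy(), X.copy())
            np.testing.assert_allclose(pi1, pi2, atol=1e-8, err_msg=name)

    def test_genomic_coef_is_loadings_times_reduced_coef(self, small_logistic_data):
        D, X, y = small_logistic_data
        models = _fit_all(D, X, y)
        for name in ("R-PLS", "R-LS-PLS", "IR-LS-PLS"):
            m = models[name]
            np.testing.assert_allclose(
                m.coef_genomic_, m.loadings_ @ m._lspls.gamma_T, atol=1e-12,
                err_msg=name,
            )
        m = models["LS-PLS-IRLS"]
        gamma_T = m._state.gamma[1 + D.shape[1]:]
        np.testing.assert_allclose(m.coef_genomic_, m.loadings_ @ gamma_T,
                                   atol=1e-12)

    def test_sklearn_clone_and_get_params(self):
        est = RLSPLS(n_clinical=3, kappa=2, lam=0.5)
        cl = clone(est)
        assert cl.get_params() == est.get_params()

    def test_strict_half_threshold(self, small_logistic_data):
        D, X, y = small_logistic_data
        model = fit_glm(y, D)
        model.intercept_ = 0.0
        model.coef_clinical_ = np.zeros(D.shape[1])
        _, yhat = predict(model, D, X)
        assert np.all(yhat == 0)  # pi exactly 0.5 everywhere -> class 0

    def test_single_class_rejected(self, small_logistic_data):
        D, X, _ = small_logistic_data
        with pytest.raises(ValueError, match="single class"):
            fit_glm(np.ones(len(D)), D)

    def test_feature_count_mismatch_rejected(self, small_logistic_data):
        D, X, y = small_logistic_data
        model = fit_r_lspls(y, D, X, 2, 1.0)
        with pytest.raises(ValueError, match="features"):
            model.decision_function(np.hstack([D, X])[:, :-1])


class TestFullRankCollapses:
    """With maximal kappa and lambda -> 0 every compression-based method
    reduces to plain IRLS on its expanded design."""

    def test_lspls_irls_collapse(self, small_logistic_data):
        D, X, y = small_logistic_data
        Dt = _augment(D)
        Xo = orthogonalize(X, Dt)
        ref = irls(y.astype(float), np.hstack([D, Xo]))
        eta_ref = np.hstack([Dt, Xo]) @ ref.gamma
        model = fit_lspls_irls(y, D, X, X.shape[1], lam=0.0)
        np.testing.assert_allclose(
            model.decision_function(np.hstack([D, X])), eta_ref, atol=1e-5
        )

    def test_r_lspls_collapse(self, small_logistic_data):
        D, X, y = small_logistic_data
        Dt = _augment(D)
        Xo = orthogonalize(X, Dt)
        ref = irls(y.astype(float), np.hstack([D, Xo]))
        model = fit_r_lspls(y, D, X, X.shape[1], lam=1e-8)
        np.testing.assert_allclose(
            model.decision_function(np.hstack([D, X])),
            np.hstack([Dt, Xo]) @ ref.gamma, atol=1e-5,
        )

    def test_ir_lspls_fixed_point_collapse(self, small_logistic_data):
        D, X, y = small_logistic_data
        Dt = _augment(D)
        Xo = orthogonalize(X, Dt)
        ref = irls(y.astype(float), np.hstack([D, Xo]))
        model = fit_ir_lspls(y, D, X, X.shape[1], max_iter=200)
        assert model.converged_
        np.testing.assert_allclose(
            model.decision_function(np.hstack([D, X])),
            np.hstack([Dt, Xo]) @ ref.gamma, atol=1e-5,
        )

    def test_ls_pcr_collapse(self, small_logistic_data):
        D, X, y = small_logistic_data
        Xc = X - X.mean(axis=0)
        ref = irls(y.astype(float), np.hstack([D, Xc]))
        model = fit_ls_pcr(y, D, X, X.shape[1], lam=0.0)
        np.testing.assert_allclose(
            model.decision_function(np.hstack([D, X])),
            np.hstack([_augment(D), Xc]) @ ref.gamma, atol=1e-5,
        )


class TestMethodSpecifics:
    def test_ir_lspls_first_iterate_closed_form(self, small_logistic_data):
        # from gamma = 0 the working weights are exactly 0.25 and the
        # pseudo-response is 4(y - 1/2): one outer iteration is one LS-PLS
        D, X, y = small_logistic_data
        model = IRLSPLS(n_clinical=D.shape[1], kappa=2, max_iter=1)
        model.fit(np.hstack([D, X]), y)
        ref = lspls_fit(4.0 * (y - 0.5), D, X, 2,
                        sample_weight=np.full(len(y), 0.25))
        np.testing.assert_allclose(model.coef_clinical_, ref.gamma_Dtilde[1:],
                                   atol=1e-10)
        np.testing.assert_allclose(model.coef_genomic_, ref.gamma_X, atol=1e-10)

    def test_r_pls_constant_weight_collapse(self, rng):
        # under enormous shrinkage step 1 of the genomic-only method returns
        # an intercept-only fit, so the working weights are constant and the
        # weighted PLS of step 2 equals the unweighted PLS of the
        # pseudo-response (constant weights cancel out of every regression)
        n, p = 60, 8
        X = rng.standard_normal((n, p))
        y = (rng.random(n) < 0.5).astype(int)
        model = fit_r_pls(y, X, 2, lam=1e10)
        from lspls.glm import rirls_reduced
        st = rirls_reduced(y.astype(float), X[:, :0], X, 1e10)
        assert st.w.max() - st.w.min() < 1e-6
        unweighted = lspls_fit(st.z, X[:, :0], X, 2)
        np.testing.assert_allclose(model.coef_genomic_, unweighted.gamma_X,
                                   atol=1e-4)
        np.testing.assert_allclose(model.intercept_, unweighted.gamma_Dtilde[0],
                                   atol=1e-4)

    def test_r_pls_mirrors_r_lspls_with_empty_clinical(self, rng):
        n, p = 50, 7
        X = rng.standard_normal((n, p))
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        m = fit_r_pls(y, X, 2, 1.0)
        assert m.coef_clinical_.size == 0
        pi, yhat = predict(m, np.zeros((n, 0)), X)
        assert pi.shape == (n,)

    def test_ls_pcr_score_is_dominant_variance_direction(self, rng):
        # one genomic direction carries most variance; kappa=1 must pick it
        n, p = 100, 10
        base = rng.standard_normal((n, p)) * 0.1
        v = rng.standard_normal(p)
        v /= linalg.norm(v)
        scores = rng.standard_normal(n) * 5.0
        X = base + np.outer(scores, v)
        D = rng.standard_normal((n, 1))
        y = (rng.random(n) < 0.5).astype(int)
        model = fit_ls_pcr(y, D, X, 1)
        Xc = X - X.mean(axis=0)
        lead = np.linalg.eigh(Xc.T @ Xc)[1][:, -1]
        cos = abs(model.loadings_[:, 0] @ lead)
        assert cos > 1 - 1e-6

    def test_null_genomic_signal_recovers_clinical_glm(self, rng):
        # strong clinical effect, pure-noise genomic block: the combined fit's
        # clinical coefficients stay within 2 SE of the clinical-only GLM
        sm = pytest.importorskip("statsmodels.api")
        n, q, p = 300, 2, 20
        D = rng.standard_normal((n, q))
        X = rng.standard_normal((n, p))
        eta = 0.2 + D @ np.array([1.5, -1.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        model = fit_lspls_irls(y, D, X, 2)
        ref = sm.Logit(y, _augment(D)).fit(disp=0)
        se = ref.bse
        assert np.all(np.abs(model.coef_clinical_ - ref.params[1:]) < 2 * se[1:])
        assert np.abs(model.coef_genomic_).max() < 0.5

    def test_glm_wrapper_on_clinical_alone(self, small_logistic_data):
        D, X, y = small_logistic_data
        model = fit_glm(y, D)
        ref = irls(y.astype(float), D)
        np.testing.assert_allclose(
            np.concatenate([[model.intercept_], model.coef_clinical_]),
            ref.gamma, atol=1e-12,
        )


class TestFitPath:
    """The shared-stage fit_path shortcut must agree with independent refits."""

    @pytest.mark.parametrize("cls,kwargs", [
        (RLSPLS, {"lam": 0.5}),
        (RPLS, {"lam": 0.5}),
        (LSPLSIRLS, {"lam": 0.0}),
        (LSPCR, {"lam": 0.0}),
    ])
    def test_fit_path_matches_individual_fits(self, small_logistic_data, cls, kwargs):
        D, X, y = small_logistic_data
        q = 0 if cls is RPLS else D.shape[1]
        XD = X if cls is RPLS else np.hstack([D, X])
        est = cls(n_clinical=q if cls is not RPLS else 0, **kwargs)
        models = est.fit_path(XD, y, [1, 2, 3], lam=kwargs.get("lam"))
        for k in (1, 2, 3):
            solo = cls(n_clinical=est.n_clinical, kappa=k, **kwargs).fit(XD, y)
            np.testing.assert_allclose(
                models[k].decision_function(XD), solo.decision_function(XD),
                atol=1e-8, err_msg=f"{cls.__name__} kappa={k}",
            )
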