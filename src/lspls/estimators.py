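"""Classifiers for combined clinical + genomic binary prediction.

Every estimator follows the scikit-learn API (``fit``, ``predict``,
``predict_proba``, ``decision_function``, ``get_params``/``set_params``) and
operates on a single feature matrix whose first ``n_clinical`` columns are the
low-dimensional clinical covariates and whose remaining columns are the
high-dimensional genomic block.  The clinical block always enters the model at
full resolution; the genomic block is compressed (PLS or PCA scores) or
ridge-regularized.

The six methods:

=================  ============================================================
``ClinicalGLM``    logistic regression on the clinical block alone (baseline)
``RPLS``           ridge-IRLS pseudo-response followed by weighted PLS on the
                   genomic block alone (baseline)
``LSPCR``          principal-component scores of the genomic block joined with
                   the clinical block in an IRLS fit (baseline)
``LSPLSIRLS``      LS-PLS on the 0/1 response to build scores, then (ridge-)
                   IRLS on clinical + scores
``IRLSPLS``        IRLS outer loop whose weighted least-squares solve is
                   replaced by a weighted LS-PLS fit each iteration
``RLSPLS``         ridge-IRLS on the full clinico-genomic design to build a
                   continuous pseudo-response, then one weighted LS-PLS fit
=================  ============================================================

Module-level ``fit_*`` helpers mirror the estimators for callers who hold the
clinical matrix ``D`` and genomic matrix ``X`` separately.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted

from .glm import IRLSState, _sigmoid, irls, rirls, rirls_reduced
from .pls import LSPLSFit, lspls_fit, truncate_pls


def _truncate_lspls(fit: LSPLSFit, kappa: int) -> LSPLSFit:
    """Nested smaller-``kappa`` LS-PLS fit extracted from a larger one.

    Valid because PLS1 components are nested and the scores are orthogonal to
    each other and to the clinical design, so the step-4 coefficients of the
    leading components do not change when trailing components are dropped.
    """
    pls_k = truncate_pls(fit.pls, kappa)
    gamma_T = fit.gamma_T[:kappa]
    return LSPLSFit(
        gamma_Dtilde=fit.gamma_Dtilde, gamma_X=pls_k.V @ gamma_T,
        gamma_T=gamma_T, V=pls_k.V, T=fit.T[:, :kappa], proj_C=fit.proj_C,
        kappa=kappa, n_effective=pls_k.n_effective, pls=pls_k,
    )


class BaseClinicoGenomicClassifier(ClassifierMixin, BaseEstimator):
    """Shared plumbing: column splitting, validation, probability mapping."""

    method: str = ""

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = self.n_clinical or 0
        return X[:, :q], X[:, q:]

    def _validate_fit_inputs(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0, 1))):
            raise ValueError("y must be coded 0/1")
        if classes.size < 2:
            raise ValueError("y contains a single class")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return X, y.astype(float)

    def fit(self, X, y):
        X, y = self._validate_fit_inputs(X, y)
        D, G = self._split(X)
        self._fit(D, G, y)
        return self

    # subclasses implement _fit(D, G, y) and _decision(D, G)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        D, G = self._split(X)
        return self._decision(D, G)

    def predict_proba(self, X) -> np.ndarray:
        pi = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - pi, pi])

    def predict(self, X) -> np.ndarray:
        # strict threshold: a tie at pi = 0.5 is assigned to class 0
        pi = self.predict_proba(X)[:, 1]
        return self.classes_[(pi > 0.5).astype(int)]

    def fit_path(self, X, y, kappas, lam=None):
        """Fit one model per ``kappa`` at fixed ridge parameter ``lam``.

        Returns ``{kappa: fitted estimator}``.  The base implementation just
        refits; subclasses override it to share the expensive stage across
        the component grid.
        """
        models = {}
        for k in kappas:
            est = clone(self)
            params = {}
            if "kappa" in est.get_params():
                params["kappa"] = int(k)
            if lam is not None and "lam" in est.get_params():
                params["lam"] = float(lam)
            est.set_params(**params)
            models[int(k)] = est.fit(X, y)
        return models


class ClinicalGLM(BaseClinicoGenomicClassifier):
    """Logistic regression on the clinical covariates alone (IRLS).

    With ``n_clinical=None`` every column of ``X`` is treated as clinical;
    otherwise only the first ``n_clinical`` columns are used and the genomic
    block is ignored.
    """

    method = "GLM"

    def __init__(self, n_clinical=None, tol=1e-6, max_iter=100):
        self.n_clinical = n_clinical
        self.tol = tol
        self.max_iter = max_iter

    def _split(self, X):
        if self.n_clinical is None:
            return X, X[:, :0]
        return super()._split(X)

    def _fit(self, D, G, y):
        state = irls(y, D, tol=self.tol, max_iter=self.max_iter)
        self.intercept_ = float(state.gamma[0])
        self.coef_clinical_ = state.gamma[1:]
        self.coef_genomic_ = np.zeros(G.shape[1])
        self.loadings_ = None
        self.converged_ = state.converged
        self.n_iter_ = state.n_iter
        self._state = state

    def _decision(self, D, G):
        return self.intercept_ + D @ self.coef_clinical_


class RPLS(BaseClinicoGenomicClassifier):
    """Ridge-PLS on the genomic block alone.

    Step 1 runs ridge-IRLS of ``y`` on the genomic block (intercept
    unpenalized) to produce the pseudo-response ``z`` and working weights
    ``W`` at convergence; step 2 runs a weighted PLS of ``W^{1/2} z`` on the
    weighted intercept-augmented genomic block — i.e. LS-PLS with an empty
    clinical design.
    """

    method = "R-PLS"

    def __init__(self, n_clinical=0, kappa=1, lam=1.0, tol=1e-6, max_iter=100):
        self.n_clinical = n_clinical
        self.kappa = kappa
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def _fit(self, D, G, y, _state: IRLSState | None = None):
        if _state is None:
            _state = rirls_reduced(
                y, G[:, :0], G, self.lam, tol=self.tol, max_iter=self.max_iter
            )
        fit = lspls_fit(_state.z, G[:, :0], G, self.kappa, sample_weight=_state.w)
        self._assign(fit, _state, G.shape[1])

    def _assign(self, fit: LSPLSFit, state: IRLSState, p: int):
        self.intercept_ = float(fit.gamma_Dtilde[0])
        self.coef_clinical_ = np.zeros(0)
        self.coef_genomic_ = fit.gamma_X
        self.loadings_ = fit.V
        self.converged_ = state.converged
        self.n_iter_ = state.n_iter
        self._lspls = fit

    def _decision(self, D, G):
        return self._lspls.linear_predictor(G[:, :0], G)

    def fit_path(self, X, y, kappas, lam=None):
        lam = self.lam if lam is None else float(lam)
        X, y = self._validate_fit_inputs(X, y)
        D, G = self._split(X)
        state = rirls_reduced(y, G[:, :0], G, lam, tol=self.tol, max_iter=self.max_iter)
        kmax = int(max(kappas))
        ref = clone(self).set_params(kappa=kmax, lam=lam)
        ref._validate_fit_inputs(X, y)
        ref._fit(D, G, y, _state=state)
        models = {kmax: ref}
        for k in kappas:
            k = int(k)
            if k in models:
                continue
            est = clone(self).set_params(kappa=k, lam=lam)
            est._validate_fit_inputs(X, y)
            est._assign(_truncate_lspls(ref._lspls, k), state, G.shape[1])
            models[k] = est
        return models


class RLSPLS(BaseClinicoGenomicClassifier):
    """Ridge LS-PLS: pseudo-response from ridge-IRLS on the full design,
    then one weighted LS-PLS fit.

    Step 1 runs ridge-IRLS of ``y`` on ``[D X]`` with the ridge penalty on
    the genomic coefficients only (the clinical block and the intercept are
    left unpenalized), yielding the pseudo-response ``z`` and the working
    weights ``W`` at convergence.  Step 2 fits
    ``LS-PLS(W^{1/2} z, W^{1/2} D, W^{1/2} X, kappa)``.  Step 2 is a direct
    (non-iterative) solve, so the procedure converges whenever step 1 does —
    and step 1 maximizes a strictly concave penalized likelihood for any
    ``lam > 0``.
    """

    method = "R-LS-PLS"

    def __init__(self, n_clinical=0, kappa=1, lam=1.0, tol=1e-6, max_iter=100):
        self.n_clinical = n_clinical
        self.kappa = kappa
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def _fit(self, D, G, y, _state: IRLSState | None = None):
        if _state is None:
            _state = rirls_reduced(
                y, D, G, self.lam, tol=self.tol, max_iter=self.max_iter
            )
        fit = lspls_fit(_state.z, D, G, self.kappa, sample_weight=_state.w)
        self._assign(fit, _state)

    def _assign(self, fit: LSPLSFit, state: IRLSState):
        self.intercept_ = float(fit.gamma_Dtilde[0])
        self.coef_clinical_ = fit.gamma_Dtilde[1:]
        self.coef_genomic_ = fit.gamma_X
        self.loadings_ = fit.V
        self.converged_ = state.converged
        self.n_iter_ = state.n_iter
        self._lspls = fit

    def _decision(self, D, G):
        return self._lspls.linear_predictor(D, G)

    def fit_path(self, X, y, kappas, lam=None):
        lam = self.lam if lam is None else float(lam)
        X, y = self._validate_fit_inputs(X, y)
        D, G = self._split(X)
        state = rirls_reduced(y, D, G, lam, tol=self.tol, max_iter=self.max_iter)
        kmax = int(max(kappas))
        ref = clone(self).set_params(kappa=kmax, lam=lam)
        ref._validate_fit_inputs(X, y)
        ref._fit(D, G, y, _state=state)
        models = {kmax: ref}
        for k in kappas:
            k = int(k)
            if k in models:
                continue
            est = clone(self).set_params(kappa=k, lam=lam)
            est._validate_fit_inputs(X, y)
            est._assign(_truncate_lspls(ref._lspls, k), state)
            models[k] = est
        return models


class LSPLSIRLS(BaseClinicoGenomicClassifier):
    """LS-PLS scores from the 0/1 response, then (ridge-)IRLS on
    clinical + scores.

    Step 1 applies the Gaussian LS-PLS procedure to the binary response
    treated as numeric, retaining the loading matrix ``V`` and the scores
    ``T`` built from the orthogonalized genomic block.  Step 2 fits a
    logistic regression of ``y`` on ``[D T]``; with the default ``lam=0``
    this is plain IRLS, and the convergence flag reports whether that IRLS
    run met its stopping rule (maximum likelihood can fail to exist under
    separation).  Genomic coefficients are recovered as ``V @ gamma_T``.
    """

    method = "LS-PLS-IRLS"

    def __init__(self, n_clinical=0, kappa=1, lam=0.0, tol=1e-6, max_iter=100):
        self.n_clinical = n_clinical
        self.kappa = kappa
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def _fit(self, D, G, y, _step1: LSPLSFit | None = None):
        if _step1 is None:
            _step1 = lspls_fit(y, D, G, self.kappa)
        elif _step1.kappa != self.kappa:
            _step1 = _truncate_lspls(_step1, self.kappa)
        T = _step1.T
        state = rirls(
            y, np.hstack([D, T]), lam=self.lam, tol=self.tol,
            max_iter=self.max_iter,
        )
        q = D.shape[1]
        gamma_T = state.gamma[1 + q:]
        self.intercept_ = float(state.gamma[0])
        self.coef_clinical_ = state.gamma[1: 1 + q]
        self.coef_genomic_ = _step1.V @ gamma_T
        self.loadings_ = _step1.V
        self.converged_ = state.converged
        self.n_iter_ = state.n_iter
        self._proj_C = _step1.proj_C
        self._state = state

    def _decision(self, D, G):
        Dt = np.hstack([np.ones((D.shape[0], 1)), D])
        gamma_Dt = np.concatenate([[self.intercept_], self.coef_clinical_])
        return Dt @ gamma_Dt + (G - Dt @ self._proj_C) @ self.coef_genomic_

    def fit_path(self, X, y, kappas, lam=None):
        lam = self.lam if lam is None else float(lam)
        X, y = self._validate_fit_inputs(X, y)
        D, G = self._split(X)
        step1 = lspls_fit(y, D, G, int(max(kappas)))
        models = {}
        for k in kappas:
            est = clone(self).set_params(kappa=int(k), lam=lam)
            est._validate_fit_inputs(X, y)
            est._fit(D, G, y, _step1=step1)
            models[int(k)] = est
        return models


class IRLSPLS(BaseClinicoGenomicClassifier):
    """Iteratively reweighted LS-PLS.

    An IRLS-type outer loop in which the weighted least-squares solve of each
    iteration is replaced by a weighted LS-PLS fit:
    ``LS-PLS(W^{1/2} z, W^{1/2} D, W^{1/2} X, kappa)``, after which the
    pseudo-response is rebuilt from the fitted linear predictor.  Because the
    compression changes with the weights at every step, no objective function
    is being maximized and convergence is not guaranteed; the loop stops on a
    small relative coefficient change, on detected oscillation (comparison
    with the iterate two steps back), on divergence, or at ``max_iter``, and
    ``converged_`` reports honestly which of these happened.
    """

    method = "IR-LS-PLS"

    def __init__(self, n_clinical=0, kappa=1, tol=1e-6, max_iter=50):
        self.n_clinical = n_clinical
        self.kappa = kappa
        self.tol = tol
        self.max_iter = max_iter

    def _fit(self, D, G, y):
        from .glm import PI_CLIP

        n = y.shape[0]
        eta = np.zeros(n)
        prev = None
        prev2 = None
        fit = None
        converged = False
        n_iter = 0
        for _ in range(self.max_iter):
            pi = np.clip(_sigmoid(eta), PI_CLIP, 1.0 - PI_CLIP)
            w = pi * (1.0 - pi)
            z = eta + (y - pi) / w
            fit = lspls_fit(z, D, G, self.kappa, sample_weight=w)
            g = np.concatenate([fit.gamma_Dtilde, fit.gamma_X])
            eta = fit.linear_predictor(D, G)
            n_iter += 1
            if not np.all(np.isfinite(g)) or linalg.norm(g) > 1e8:
                converged = False
                break
            if prev is not None:
                delta = linalg.norm(g - prev) / max(1.0, linalg.norm(g))
                if delta < self.tol:
                    converged = True
                    prev2, prev = prev, g
                    break
                if prev2 is not None:
                    osc = linalg.norm(g - prev2) / max(1.0, linalg.norm(g))
                    if osc < self.tol:
                        # two-cycle: iterates alternate without settling
                        converged = False
                        prev2, prev = prev, g
                        break
            prev2, prev = prev, g

        self.intercept_ = float(fit.gamma_Dtilde[0])
        self.coef_clinical_ = fit.gamma_Dtilde[1:]
        self.coef_genomic_ = fit.gamma_X
        self.loadings_ = fit.V
        self.converged_ = converged
        self.n_iter_ = n_iter
        self._lspls = fit

    def _decision(self, D, G):
        return self._lspls.linear_predictor(D, G)


class LSPCR(BaseClinicoGenomicClassifier):
    """Principal-component scores of the genomic block + clinical block,
    fitted by (ridge-)IRLS.

    The scores are the leading ``kappa`` principal components of the
    column-centered genomic matrix — chosen without reference to the
    response — so directions of large genomic variance dominate regardless
    of their predictive value.  Default ``lam=0`` is plain IRLS.
    """

    method = "LS-PCR"

    def __init__(self, n_clinical=0, kappa=1, lam=0.0, tol=1e-6, max_iter=100):
        self.n_clinical = n_clinical
        self.kappa = kappa
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def _fit(self, D, G, y, _svd=None):
        if _svd is None:
            center = G.mean(axis=0)
            Us, s, Vt = linalg.svd(G - center, full_matrices=False)
        else:
            center, Us, s, Vt = _svd
        k = self.kappa
        if k > np.sum(s > 1e-10 * (s[0] if s.size else 1.0)):
            raise ValueError(
                f"kappa={k} exceeds the rank of the centered genomic block"
            )
        T = Us[:, :k] * s[:k]
        state = rirls(
            y, np.hstack([D, T]), lam=self.lam, tol=self.tol,
            max_iter=self.max_iter,
        )
        q = D.shape[1]
        gamma_T = state.gamma[1 + q:]
        self.intercept_ = float(state.gamma[0])
        self.coef_clinical_ = state.gamma[1: 1 + q]
        self.coef_genomic_ = Vt[:k].T @ gamma_T
        self.loadings_ = Vt[:k].T
        self.converged_ = state.converged
        self.n_iter_ = state.n_iter
        self._x_center = center
        self._state = state

    def _decision(self, D, G):
        return (
            self.intercept_
            + D @ self.coef_clinical_
            + (G - self._x_center) @ self.coef_genomic_
        )

    def fit_path(self, X, y, kappas, lam=None):
        lam = self.lam if lam is None else float(lam)
        X, y = self._validate_fit_inputs(X, y)
        D, G = self._split(X)
        center = G.mean(axis=0)
        svd = (center, *linalg.svd(G - center, full_matrices=False))
        models = {}
        for k in kappas:
            est = clone(self).set_params(kappa=int(k), lam=lam)
            est._validate_fit_inputs(X, y)
            est._fit(D, G, y, _svd=svd)
            models[int(k)] = est
        return models


# ---------------------------------------------------------------------------
# functional wrappers over the estimators, for callers holding D and X apart

def _stack(D, X):
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    X = np.asarray(X, dtype=float)
    return np.hstack([D, X]), D.shape[1]


def fit_glm(Y, D) -> ClinicalGLM:
    """Clinical-only logistic baseline."""
    D = np.asarray(D, dtype=float)
    return ClinicalGLM(n_clinical=None).fit(D, Y)


def fit_r_pls(Y, X, kappa, lam) -> RPLS:
    """Genomic-only ridge-PLS baseline."""
    return RPLS(n_clinical=0, kappa=kappa, lam=lam).fit(np.asarray(X, float), Y)


def fit_ls_pcr(Y, D, X, kappa, lam=0.0) -> LSPCR:
    XD, q = _stack(D, X)
    return LSPCR(n_clinical=q, kappa=kappa, lam=lam).fit(XD, Y)


def fit_lspls_irls(Y, D, X, kappa, lam=0.0) -> LSPLSIRLS:
    XD, q = _stack(D, X)
    return LSPLSIRLS(n_clinical=q, kappa=kappa, lam=lam).fit(XD, Y)


def fit_ir_lspls(Y, D, X, kappa, tol=1e-6, max_iter=50) -> IRLSPLS:
    XD, q = _stack(D, X)
    return IRLSPLS(n_clinical=q, kappa=kappa, tol=tol, max_iter=max_iter).fit(XD, Y)


def fit_r_lspls(Y, D, X, kappa, lam) -> RLSPLS:
    XD, q = _stack(D, X)
    return RLSPLS(n_clinical=q, kappa=kappa, lam=lam).fit(XD, Y)


def predict(model, D_new, X_new):
    """Probabilities and 0/1 labels for new samples held as (D, X) pairs."""
    D_new = np.asarray(D_new, dtype=float)
    if D_new.ndim == 1:
        D_new = D_new[:, None]
    X_new = np.asarray(X_new, dtype=float)
    if isinstance(model, ClinicalGLM) and model.n_clinical is None:
        XD = D_new
    elif isinstance(model, RPLS) and model.n_clinical == 0:
        XD = X_new
    else:
        XD = np.hstack([D_new, X_new])
    pi = model.predict_proba(XD)[:, 1]
    return pi, (pi > 0.5).astype(int)


ALL_METHODS = {
    cls.method: cls
    for cls in (ClinicalGLM, RPLS, LSPCR, LSPLSIRLS, IRLSPLS, RLSPLS)
}
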