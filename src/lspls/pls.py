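"""Partial least squares core.

This module implements the three linear-algebra primitives shared by every
classifier in the package:

* :func:`orthogonalize` — projection of a high-dimensional block onto the
  orthogonal complement of the column space of a low-dimensional design;
* :func:`pls_fit` — univariate-response PLS (PLS1) with orthogonal-scores
  deflation (NIPALS-equivalent);
* :func:`lspls_fit` — the combined least-squares / PLS regression in which the
  clinical design enters by ordinary least squares while the genomic block,
  orthogonalized against it, is compressed to ``kappa`` latent components.

All fits operate on plain numpy arrays; the estimator layer wraps them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

#: relative singular-value cutoff for rank decisions
RANK_RTOL = 1e-10


class SingularDesignError(ValueError):
    """Raised when a design matrix that must be full column rank is not."""


def _check_full_column_rank(M: np.ndarray, name: str = "design") -> None:
    """Raise :class:`SingularDesignError` naming the dependent columns."""
    if M.size == 0:
        return
    # pivoted QR exposes which columns fall beyond the numerical rank
    _, R, piv = linalg.qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0:
        return
    rank = int(np.sum(diag > RANK_RTOL * diag[0]))
    if rank < M.shape[1]:
        bad = sorted(piv[rank:].tolist())
        raise SingularDesignError(
            f"{name} matrix is rank deficient (rank {rank} < {M.shape[1]} "
            f"columns); offending columns: {bad}"
        )


def orthogonalize(X: np.ndarray, Dtilde: np.ndarray) -> np.ndarray:
    """Project the columns of ``X`` onto the orthogonal complement of ``Dtilde``.

    Returns ``X_orth = (I - Dtilde (Dtilde^T Dtilde)^{-1} Dtilde^T) X``,
    the column-wise least-squares residuals of ``X`` regressed on ``Dtilde``.
    When ``Dtilde`` contains the intercept column this also centers ``X``.

    Parameters
    ----------
    X : (n, p) array
    Dtilde : (n, q+1) array, full column rank

    Raises
    ------
    SingularDesignError
        If ``Dtilde`` is rank deficient.
    """
    X = np.asarray(X, dtype=float)
    Dtilde = np.asarray(Dtilde, dtype=float)
    if X.shape[0] != Dtilde.shape[0]:
        raise ValueError("X and Dtilde must have the same number of rows")
    _check_full_column_rank(Dtilde, name="clinical design")
    if Dtilde.shape[1] == 0:
        return X.copy()
    Q, _ = linalg.qr(Dtilde, mode="economic")
    return X - Q @ (Q.T @ X)


@dataclass
class PLSFit:
    """Result of a PLS1 regression.

    Attributes
    ----------
    V : (p, kappa) ndarray
        Rotation ("loading") matrix with ``T = (X - x_center) @ V``.
    T : (n, kappa) ndarray
        Orthogonal score matrix.
    gamma_T : (kappa,) ndarray
        Reduced-space regression coefficients of the (centered) response on T.
    x_center : (p,) ndarray
        Column means removed from X before fitting (zeros if ``center=False``).
    y_center : float
        Mean removed from the response (0.0 if ``center=False``).
    kappa : int
        Number of components requested.
    n_effective : int
        Number of non-degenerate components actually extracted (trailing
        components are zero when the response covariance is exhausted).
    """

    V: np.ndarray
    T: np.ndarray
    gamma_T: np.ndarray
    x_center: np.ndarray
    y_center: float
    kappa: int
    n_effective: int
    weights_W: np.ndarray = field(repr=False, default=None)
    loadings_P: np.ndarray = field(repr=False, default=None)

    def fitted_values(self) -> np.ndarray:
        return self.y_center + self.T @ self.gamma_T

    def coef_(self) -> np.ndarray:
        """Coefficients on the original predictor scale, ``V @ gamma_T``."""
        return self.V @ self.gamma_T


def pls_fit(z: np.ndarray, X: np.ndarray, kappa: int, *, center: bool = True) -> PLSFit:
    """Univariate-response PLS with orthogonal-scores deflation.

    Each weight vector maximizes covariance between the deflated predictor
    block and the response; scores are mutually orthogonal.  With
    ``kappa == rank(X)`` the fitted values coincide with ordinary least
    squares.  A response with no remaining covariance against the predictors
    (e.g. a constant ``z``) yields zero trailing components rather than an
    error, so the fit degrades gracefully to the mean.

    Parameters
    ----------
    z : (n,) response
    X : (n, p) predictors
    kappa : number of components, ``1 <= kappa <= rank(centered X)``
    center : subtract column means of X and the mean of z first.  Callers that
        have already orthogonalized X against a design containing the
        intercept should pass ``center=False``.
    """
    z = np.asarray(z, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if z.shape[0] != n:
        raise ValueError("z and X must have the same number of rows")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite values in PLS inputs")
    kappa = int(kappa)
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if kappa > min(n, p):
        raise ValueError(f"kappa={kappa} exceeds min(n, p)={min(n, p)}")

    if center:
        x_center = X.mean(axis=0)
        y_center = float(z.mean())
    else:
        x_center = np.zeros(p)
        y_center = 0.0
    Xc = X - x_center
    zc = z - y_center

    x_scale = linalg.norm(Xc) or 1.0
    z_scale = linalg.norm(zc)

    W = np.zeros((p, kappa))
    P = np.zeros((p, kappa))
    T = np.zeros((n, kappa))
    Xk = Xc.copy()
    n_eff = kappa
    for k in range(kappa):
        w = Xk.T @ zc
        nw = linalg.norm(w)
        if nw <= RANK_RTOL * max(x_scale * z_scale, 1.0):
            # no covariance left: rank exhausted vs degenerate response
            if linalg.norm(Xk) > np.sqrt(RANK_RTOL) * x_scale and z_scale > 0:
                n_eff = k
                break
            if linalg.norm(Xk) <= np.sqrt(RANK_RTOL) * x_scale:
                raise ValueError(
                    f"kappa={kappa} exceeds the rank of the centered predictor "
                    f"matrix (exhausted after {k} components)"
                )
            n_eff = k
            break
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt <= (RANK_RTOL * x_scale) ** 2:
            raise ValueError(
                f"kappa={kappa} exceeds the rank of the centered predictor "
                f"matrix (degenerate score at component {k + 1})"
            )
        pk = Xk.T @ t / tt
        Xk -= np.outer(t, pk)
        W[:, k], P[:, k], T[:, k] = w, pk, t

    gamma_T = np.zeros(kappa)
    V = np.zeros((p, kappa))
    if n_eff > 0:
        # rotation so that T = Xc @ V  (Manne relation)
        V[:, :n_eff] = W[:, :n_eff] @ linalg.inv(P[:, :n_eff].T @ W[:, :n_eff])
        tt = np.einsum("ij,ij->j", T[:, :n_eff], T[:, :n_eff])
        gamma_T[:n_eff] = (T[:, :n_eff].T @ zc) / tt
    return PLSFit(
        V=V, T=T, gamma_T=gamma_T, x_center=x_center, y_center=y_center,
        kappa=kappa, n_effective=n_eff, weights_W=W, loadings_P=P,
    )


def truncate_pls(fit: PLSFit, kappa: int) -> PLSFit:
    """Return the ``kappa``-component fit nested inside a larger PLS1 fit.

    PLS1 components are nested: the first ``kappa`` weight/loading vectors of
    a larger fit are exactly those of the smaller fit, so only the rotation
    and the reduced-space coefficients need recomputing.
    """
    if kappa > fit.kappa:
        raise ValueError("cannot truncate to more components than fitted")
    n_eff = min(kappa, fit.n_effective)
    p = fit.V.shape[0]
    V = np.zeros((p, kappa))
    gamma_T = np.zeros(kappa)
    T = fit.T[:, :kappa].copy()
    if n_eff > 0:
        W, P = fit.weights_W[:, :n_eff], fit.loadings_P[:, :n_eff]
        V[:, :n_eff] = W @ linalg.inv(P.T @ W)
    # gamma_T of leading components is unchanged (scores are orthogonal)
    gamma_T[:n_eff] = fit.gamma_T[:n_eff]
    return PLSFit(
        V=V, T=T, gamma_T=gamma_T, x_center=fit.x_center,
        y_center=fit.y_center, kappa=kappa, n_effective=n_eff,
        weights_W=fit.weights_W[:, :kappa], loadings_P=fit.loadings_P[:, :kappa],
    )


@dataclass
class LSPLSFit:
    """Combined least-squares / PLS fit.

    The clinical design ``Dtilde = [1 D]`` enters by (weighted) OLS; the
    genomic block, orthogonalized against ``Dtilde``, is compressed by PLS1.
    ``proj_C`` holds ``(Dtilde^T W Dtilde)^{-1} Dtilde^T W X`` — the weighted
    projection coefficients needed to orthogonalize a new sample's genomic
    vector consistently with the training fit.
    """

    gamma_Dtilde: np.ndarray  # (q+1,) intercept first
    gamma_X: np.ndarray       # (p,)
    gamma_T: np.ndarray       # (kappa,)
    V: np.ndarray             # (p, kappa)
    T: np.ndarray             # (n, kappa) scores on the (weighted) X_orth
    proj_C: np.ndarray        # (q+1, p)
    kappa: int
    n_effective: int
    pls: PLSFit = field(repr=False, default=None)

    def linear_predictor(self, D_new: np.ndarray, X_new: np.ndarray) -> np.ndarray:
        return lspls_linear_predictor(self, D_new, X_new)


def _augment(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    return np.hstack([np.ones((n, 1)), D])


def lspls_fit(
    y: np.ndarray,
    D: np.ndarray,
    X: np.ndarray,
    kappa: int,
    sample_weight: np.ndarray | None = None,
) -> LSPLSFit:
    """Fit the orthogonalized (non-iterative) LS-PLS regression.

    Steps: (1) OLS of ``y`` on ``Dtilde = [1 D]``; (2) orthogonalize ``X``
    against ``Dtilde``; (3) PLS1 of the step-1 residuals on the orthogonalized
    block with ``kappa`` components; (4) OLS of ``y`` on ``[Dtilde T]``; the
    genomic coefficients are ``gamma_X = V @ gamma_T``.  Because the score
    space is orthogonal to the clinical design, the clinical coefficients of
    steps (1) and (4) agree, which is what removes the need to iterate.

    ``sample_weight`` (non-negative, typically IRLS weights) turns every
    regression above into its weighted counterpart: the augmented design —
    including the intercept column — the genomic block and the response are
    all multiplied row-wise by ``sqrt(sample_weight)`` first.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    if D.shape[0] != n or X.shape[0] != n:
        raise ValueError("y, D and X must have the same number of rows")
    Dt = _augment(D)
    if sample_weight is not None:
        sw = np.sqrt(np.asarray(sample_weight, dtype=float).ravel())
        if sw.shape[0] != n:
            raise ValueError("sample_weight length mismatch")
        Dt_w = Dt * sw[:, None]
        X_w = X * sw[:, None]
        y_w = y * sw
    else:
        Dt_w, X_w, y_w = Dt, X, y

    _check_full_column_rank(Dt_w, name="augmented clinical design")

    # step 1: clinical-only (weighted) OLS and residuals
    gamma_init, *_ = linalg.lstsq(Dt_w, y_w)
    r = y_w - Dt_w @ gamma_init

    # step 2: orthogonalize the genomic block on the clinical design
    X_orth = orthogonalize(X_w, Dt_w)

    # step 3: PLS1 of the residuals on X_orth; the orthogonalization already
    # removed the (weighted) intercept direction, so no further centering
    pls = pls_fit(r, X_orth, kappa, center=False)
    T = pls.T

    # step 4: joint OLS of y on [Dtilde T]; orthogonality makes this separable
    A = np.hstack([Dt_w, T])
    coef, *_ = linalg.lstsq(A, y_w)
    gamma_Dt = coef[: Dt.shape[1]]
    gamma_T = coef[Dt.shape[1]:]
    gamma_X = pls.V @ gamma_T

    # projection coefficients for scoring new samples
    C = linalg.lstsq(Dt_w, X_w)[0]

    return LSPLSFit(
        gamma_Dtilde=gamma_Dt, gamma_X=gamma_X, gamma_T=gamma_T, V=pls.V,
        T=T, proj_C=C, kappa=kappa, n_effective=pls.n_effective, pls=pls,
    )


def lspls_linear_predictor(
    fit: LSPLSFit, D_new: np.ndarray, X_new: np.ndarray
) -> np.ndarray:
    """Linear predictor for new samples.

    ``eta_0 = d0~^T gamma_Dtilde + (x0^T - d0~^T C) gamma_X`` with
    ``C = (Dtilde^T W Dtilde)^{-1} Dtilde^T W X`` from training; applied to a
    training row it reproduces that row's in-sample fitted predictor.
    """
    D_new = np.atleast_2d(np.asarray(D_new, dtype=float))
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    q = fit.gamma_Dtilde.shape[0] - 1
    if D_new.shape[1] != q:
        raise ValueError(f"expected {q} clinical columns, got {D_new.shape[1]}")
    if X_new.shape[1] != fit.gamma_X.shape[0]:
        raise ValueError(
            f"expected {fit.gamma_X.shape[0]} genomic columns, got {X_new.shape[1]}"
        )
    Dt0 = _augment(D_new)
    return Dt0 @ fit.gamma_Dtilde + (X_new - Dt0 @ fit.proj_C) @ fit.gamma_X
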