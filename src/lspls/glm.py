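"""Logistic regression engines: IRLS and ridge-penalized IRLS (RIRLS).

The iteratively reweighted least squares algorithm maximizes the logistic
log-likelihood; its ridge variant maximizes the penalized likelihood
``l*(gamma) = l(gamma) - 0.5 * lambda * ||gamma_pen||^2`` where the intercept
(and, optionally, further coordinates) is left unpenalized.  Both return, in
addition to the coefficients, the pseudo-response ``z`` and the diagonal
working weights ``W`` at the final iterate — the quantities the LS-PLS
extensions feed into a weighted PLS step.

For designs with far more penalized columns than samples,
:func:`rirls_reduced` solves the identical problem in the row space of the
penalized block (thin SVD), which is exact for a pure ridge penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

PI_CLIP = 1e-10          # probability clipping before forming W^{-1}
DIVERGENCE_NORM = 1e8    # ||gamma|| beyond which ML is declared nonexistent


@dataclass
class IRLSState:
    """Final state of an (R)IRLS run.

    Attributes
    ----------
    gamma : (m+1,) coefficients, intercept first.
    z : (n,) pseudo-response at the final iterate.
    w : (n,) diagonal working weights ``pi * (1 - pi)``.
    converged : whether the relative-change stopping rule was met.
    n_iter : accepted Newton/step-halving updates performed.
    final_loglik : log-likelihood (penalized when ``lam > 0``) at ``gamma``.
    lam : ridge parameter used.
    """

    gamma: np.ndarray
    z: np.ndarray
    w: np.ndarray
    converged: bool
    n_iter: int
    final_loglik: float
    lam: float


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def log_likelihood(gamma: np.ndarray, y: np.ndarray, Utilde: np.ndarray) -> float:
    """Logistic log-likelihood ``sum_i { y_i eta_i - ln(1 + exp(eta_i)) }``.

    Computed with ``logaddexp`` so large linear predictors do not overflow.
    ``Utilde`` must already contain the intercept column.
    """
    eta = np.asarray(Utilde, dtype=float) @ np.asarray(gamma, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _validate_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("response must be coded 0/1")
    if vals.size < 2:
        raise ValueError("response contains a single class; cannot fit")
    return y


def rirls(
    y: np.ndarray,
    U: np.ndarray,
    lam: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    penalty_mask: np.ndarray | None = None,
) -> IRLSState:
    """Ridge-penalized IRLS for logistic regression.

    Iterates the pseudo-response / weighted-ridge update
    ``gamma <- (U~^T W U~ + lam * I~)^{-1} U~^T W z`` where ``U~ = [1 U]`` and
    ``I~`` is diagonal with zeros on the unpenalized coordinates (by default
    only the intercept).  ``lam = 0`` degrades to plain maximum-likelihood
    IRLS.  Non-existence of the ML estimate (separation) is reported through
    ``converged=False`` with a divergence guard, never an exception.

    Parameters
    ----------
    penalty_mask : optional boolean array of length ``m+1`` over the
        intercept-augmented coefficients; ``True`` marks penalized
        coordinates.  Default: everything but the intercept.
    """
    y = _validate_binary(y)
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    if not np.all(np.isfinite(U)):
        raise ValueError("non-finite values in the design matrix")
    n, m = U.shape
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Ut = np.hstack([np.ones((n, 1)), U])
    if penalty_mask is None:
        penalty_mask = np.ones(m + 1, dtype=bool)
        penalty_mask[0] = False
    else:
        penalty_mask = np.asarray(penalty_mask, dtype=bool).ravel()
        if penalty_mask.shape[0] != m + 1:
            raise ValueError("penalty_mask must have length m+1")
    pen_diag = lam * penalty_mask.astype(float)

    def objective(g: np.ndarray) -> float:
        return log_likelihood(g, y, Ut) - 0.5 * float(pen_diag @ (g * g))

    gamma = np.zeros(m + 1)
    obj = objective(gamma)
    converged = False
    n_iter = 0
    while n_iter < max_iter:
        eta = Ut @ gamma
        pi = np.clip(_sigmoid(eta), PI_CLIP, 1.0 - PI_CLIP)
        w = pi * (1.0 - pi)
        z = eta + (y - pi) / w
        A = Ut.T @ (Ut * w[:, None])
        A[np.diag_indices_from(A)] += pen_diag
        b = Ut.T @ (w * z)
        try:
            gamma_new = linalg.solve(A, b, assume_a="pos")
        except linalg.LinAlgError:
            converged = False
            break
        n_iter += 1
        # step halving keeps the (penalized) likelihood non-decreasing
        obj_new = objective(gamma_new)
        halvings = 0
        while (not np.isfinite(obj_new) or obj_new < obj - 1e-12) and halvings < 10:
            gamma_new = 0.5 * (gamma + gamma_new)
            obj_new = objective(gamma_new)
            halvings += 1
            n_iter += 1
        if not np.isfinite(obj_new) or linalg.norm(gamma_new) > DIVERGENCE_NORM:
            gamma = gamma_new if np.all(np.isfinite(gamma_new)) else gamma
            converged = False
            break
        delta = linalg.norm(gamma_new - gamma) / max(1.0, linalg.norm(gamma_new))
        gamma, obj = gamma_new, obj_new
        if delta < tol:
            converged = True
            break

    eta = Ut @ gamma
    pi = np.clip(_sigmoid(eta), PI_CLIP, 1.0 - PI_CLIP)
    w = pi * (1.0 - pi)
    z = eta + (y - pi) / w
    return IRLSState(
        gamma=gamma, z=z, w=w, converged=converged, n_iter=n_iter,
        final_loglik=obj, lam=float(lam),
    )


def irls(
    y: np.ndarray, U: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> IRLSState:
    """Maximum-likelihood logistic regression of ``y`` on ``[1 U]`` via IRLS."""
    return rirls(y, U, lam=0.0, tol=tol, max_iter=max_iter)


def rirls_reduced(
    y: np.ndarray,
    D: np.ndarray,
    X: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> IRLSState:
    """RIRLS on ``[D X]`` with the ridge penalty on the ``X`` block only.

    Equivalent to ``rirls(y, [D X], lam, penalty_mask=[0, 0_q, 1_p])`` but
    solved in the row space of ``X``: with a pure ridge penalty the optimal
    genomic coefficient vector lies in ``rowspace(X)``, so substituting the
    thin SVD ``X = U_s S V_s^T`` and ``gamma_X = V_s beta`` gives an exact
    ``rank(X)``-dimensional reformulation — the only tractable route when
    ``p >> n``.  Intercept and clinical coefficients are unpenalized.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    X = np.asarray(X, dtype=float)
    q = D.shape[1]
    Us, s, Vt = linalg.svd(X, full_matrices=False)
    keep = s > RANK_SVD_RTOL * (s[0] if s.size else 1.0)
    Us, s, Vt = Us[:, keep], s[keep], Vt[keep]
    U_red = np.hstack([D, Us * s])
    mask = np.zeros(1 + q + s.size, dtype=bool)
    mask[1 + q:] = True
    state = rirls(y, U_red, lam=lam, tol=tol, max_iter=max_iter, penalty_mask=mask)
    beta = state.gamma[1 + q:]
    gamma_full = np.concatenate([state.gamma[: 1 + q], Vt.T @ beta])
    return IRLSState(
        gamma=gamma_full, z=state.z, w=state.w, converged=state.converged,
        n_iter=state.n_iter, final_loglik=state.final_loglik, lam=state.lam,
    )


RANK_SVD_RTOL = 1e-12


def predict_class(gamma: np.ndarray, u0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probability and label for feature vector(s) ``u0`` (no intercept).

    ``pi = h([1 u0^T] gamma)``; the label is 1 iff ``pi > 0.5`` (strict, so a
    tie at 0.5 yields class 0).
    """
    u0 = np.atleast_2d(np.asarray(u0, dtype=float))
    gamma = np.asarray(gamma, dtype=float).ravel()
    if u0.shape[1] != gamma.shape[0] - 1:
        raise ValueError(
            f"expected {gamma.shape[0] - 1} features, got {u0.shape[1]}"
        )
    eta = gamma[0] + u0 @ gamma[1:]
    pi = _sigmoid(eta)
    return pi, (pi > 0.5).astype(int)
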