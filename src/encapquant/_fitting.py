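"""Batched nonlinear least squares used by the EELS quantification chain.

Every pixel of a spectrum image needs the same three small fits (a
Gaussian zero-loss peak, two candidate background models), so the
solvers here operate on stacks of spectra at once: closed-form
log-space initialisation through shared pseudo-inverses, followed by a
few damped Gauss-Newton iterations with per-pixel accept/reject.  A
single spectrum is just a stack of one.
"""

from __future__ import annotations

import numpy as np

_MAX_EXP = 700.0  # exp argument clip; rejected steps are discarded anyway


def _rss(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.sum((y - pred) ** 2, axis=-1)


def gauss_newton(
    predict_jac,
    y: np.ndarray,
    theta0: np.ndarray,
    n_iter: int = 30,
    ridge: float = 1e-12,
    step_tol: float = 1e-12,
) -> np.ndarray:
    """Batched Gauss-Newton with per-pixel monotone acceptance.

    Parameters
    ----------
    predict_jac : callable
        ``theta (npix, p) -> (pred (npix, nch), jac (npix, nch, p))``.
    y : (npix, nch) array
        Data.
    theta0 : (npix, p) array
        Initial parameters.

    Returns
    -------
    (npix, p) array
        Per-pixel parameters with the lowest residual encountered;
        steps that do not reduce the residual are rejected, so the
        result is never worse than the initialisation.
    """
    theta = theta0.astype(float).copy()
    pred, _ = predict_jac(theta)
    best_rss = _rss(pred, y)
    best = theta.copy()
    for _ in range(n_iter):
        pred, jac = predict_jac(theta)
        r = y - pred
        jtj = np.einsum("nij,nik->njk", jac, jac)
        jtr = np.einsum("nij,ni->nj", jac, r)
        # Marquardt-style damping: inflate each diagonal element
        # relatively, so badly scaled parameters are not swamped.
        p = theta.shape[1]
        diag = np.einsum("njj->nj", jtj)
        jtj = jtj + np.eye(p)[None, :, :] * (ridge * diag[:, None, :] + 1e-300)
        try:
            delta = np.linalg.solve(jtj, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        cand = theta + delta
        pred_c, _ = predict_jac(cand)
        rss_c = _rss(pred_c, y)
        improved = rss_c <= best_rss
        best[improved] = cand[improved]
        best_rss[improved] = rss_c[improved]
        # continue iterating from the candidate where it helped, from
        # a half step where it did not
        theta = np.where(improved[:, None], cand, theta + 0.5 * delta)
        scale = np.abs(theta) + 1e-300
        if np.max(np.abs(delta) / scale) < step_tol:
            break
    return best


def exp_poly_predict_jac(basis: np.ndarray):
    """Model ``exp(theta . basis)`` on a fixed basis (nch, p)."""

    def f(theta: np.ndarray):
        expo = np.clip(theta @ basis.T, -_MAX_EXP, _MAX_EXP)
        pred = np.exp(expo)
        jac = pred[:, :, None] * basis[None, :, :]
        return pred, jac

    return f


def gaussian_predict_jac(x: np.ndarray):
    """Gaussian model ``amp * exp(-(x-cen)^2 / (2 s^2))``, theta=(amp, cen, s)."""

    def f(theta: np.ndarray):
        amp = theta[:, 0:1]
        cen = theta[:, 1:2]
        s = theta[:, 2:3]
        z = (x[None, :] - cen) / s
        g = np.exp(-0.5 * z**2)
        pred = amp * g
        jac = np.stack(
            [g, pred * z / s, pred * z**2 / s],
            axis=2,
        )
        return pred, jac

    return f


def polyfit_batch(basis: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares ``y ~ basis @ coeffs`` for a stack of right-hand sides.

    Returns ``(coeffs (npix, p), rss (npix,))`` using one shared
    pseudo-inverse of the (nch, p) basis.
    """
    pinv = np.linalg.pinv(basis)
    coeffs = y @ pinv.T
    resid = y - coeffs @ basis.T
    return coeffs, np.sum(resid**2, axis=-1)
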