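"""Laplace approximation to a subject's marginal likelihood.

The engine is model-agnostic: it takes a callable ``nll2(eta)`` returning
-2 log p(y | eta) for one subject and the diagonal variances of the normal
random-effect prior, locates the conditional mode of the joint density by a
damped Newton iteration (finite-difference derivatives), and returns the
Laplace -2 log marginal likelihood

    h(eta_hat) - d*log(2*pi) + log det(H/2),      H = grad^2 h at the mode,

with ``h(eta) = nll2(eta) + eta' W^-1 eta + log det(2*pi*W)``.  Because the
curvature of the data term is kept exact (no interaction-dropping), this
behaves like FOCE with interaction for proportional-error models and is exact
whenever ``nll2`` is quadratic in eta (linear mixed models), which is how the
engine is verified.
"""
from __future__ import annotations

from typing import Callable

import numpy as np

PENALTY = 1e10


def _fd_grad_hess(f: Callable, x: np.ndarray, step: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Central finite-difference value, gradient and Hessian."""
    d = x.size
    f0 = f(x)
    g = np.zeros(d)
    H = np.zeros((d, d))
    fp = np.zeros(d)
    fm = np.zeros(d)
    for k in range(d):
        e = np.zeros(d)
        e[k] = step
        fp[k] = f(x + e)
        fm[k] = f(x - e)
        g[k] = (fp[k] - fm[k]) / (2 * step)
        H[k, k] = (fp[k] - 2 * f0 + fm[k]) / step**2
    for j in range(d):
        for k in range(j + 1, d):
            ej = np.zeros(d); ej[j] = step
            ek = np.zeros(d); ek[k] = step
            fpp = f(x + ej + ek)
            fmm = f(x - ej - ek)
            H[j, k] = H[k, j] = (fpp - fp[j] - fp[k] - fm[j] - fm[k] + fmm + 2 * f0) / (
                2 * step**2
            )
    return f0, g, H


def _make_pd(H: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Ridge the Hessian up to positive definiteness if needed."""
    try:
        w = np.linalg.eigvalsh(H)
    except np.linalg.LinAlgError:
        return np.eye(H.shape[0])
    if w.min() <= floor:
        H = H + (floor - w.min() + floor) * np.eye(H.shape[0])
    return H


def conditional_mode(
    h: Callable,
    eta0: np.ndarray,
    grad_tol: float = 1e-6,
    max_iter: int = 60,
    fd_step: float = 1e-4,
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Damped Newton minimisation of the joint -2 log density in eta.

    Returns (mode, h(mode), Hessian at mode, converged).  Non-finite h at the
    start falls back to the origin; non-finite trial points are rejected by
    the step-halving line search.
    """
    x = np.asarray(eta0, dtype=float).copy()
    if not np.isfinite(h(x)):
        x = np.zeros_like(x)
    f0, g, H = _fd_grad_hess(h, x, fd_step)
    converged = False
    for _ in range(max_iter):
        if not np.isfinite(f0):
            return x, PENALTY, np.eye(x.size), False
        if np.max(np.abs(g)) < grad_tol:
            converged = True
            break
        Hpd = _make_pd(H)
        try:
            step_dir = np.linalg.solve(Hpd, -g)
        except np.linalg.LinAlgError:
            step_dir = -g
        alpha = 1.0
        f_new = np.inf
        for _ in range(25):
            x_new = x + alpha * step_dir
            f_new = h(x_new)
            if np.isfinite(f_new) and f_new <= f0 + 1e-12 * abs(f0):
                break
            alpha *= 0.5
        if not np.isfinite(f_new) or f_new > f0:
            converged = np.max(np.abs(g)) < 1e-3  # flat region; accept if nearly stationary
            break
        if np.max(np.abs(alpha * step_dir)) < 1e-12:
            converged = True
            x = x_new
            f0, g, H = _fd_grad_hess(h, x, fd_step)
            break
        x = x_new
        f0, g, H = _fd_grad_hess(h, x, fd_step)
    return x, f0, H, converged


def laplace_m2ll(
    nll2: Callable,
    omega_var: np.ndarray,
    eta0: np.ndarray | None = None,
    grad_tol: float = 1e-6,
) -> tuple[float, np.ndarray, bool]:
    """-2 log marginal likelihood of one subject by the Laplace approximation.

    ``omega_var`` holds the (strictly positive) prior variances of the active
    random effects.  A zero-dimensional prior reduces to ``nll2([])`` exactly.
    Returns (ofv_i, eta_hat, ok); a parameter region where the model cannot be
    evaluated yields a large finite penalty with ``ok=False`` rather than an
    exception.
    """
    w = np.asarray(omega_var, dtype=float)
    d = w.size
    if d == 0:
        val = nll2(np.zeros(0))
        ok = bool(np.isfinite(val))
        return (float(val) if ok else PENALTY), np.zeros(0), ok
    if np.any(w <= 0):
        raise ValueError("laplace_m2ll requires strictly positive prior variances")
    prior_const = float(np.sum(np.log(2 * np.pi * w)))

    def h(eta):
        return nll2(eta) + float(np.sum(eta**2 / w)) + prior_const

    eta0 = np.zeros(d) if eta0 is None else np.asarray(eta0, dtype=float)
    eta_hat, h_val, H, ok = conditional_mode(h, eta0, grad_tol=grad_tol)
    if not np.isfinite(h_val):
        return PENALTY, np.zeros(d), False
    Hpd = _make_pd(H)
    sign, logdet = np.linalg.slogdet(Hpd / 2.0)
    if sign <= 0:
        return PENALTY, eta_hat, False
    ofv = h_val - d * np.log(2 * np.pi) + logdet
    return float(ofv), eta_hat, ok
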