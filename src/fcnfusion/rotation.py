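"""Oblimin (quartimin) rotation by gradient projection.

Implements the oblique gradient projection algorithm of Bernaards &
Jennrich for the oblimin family criterion

    f(L) = (1/4) * sum_i sum_{j != k} L_ij^2 L_ik^2        (gamma = 0)

applied to a 2-D latent position matrix to remove rotational ambiguity in
an interpretable way. Only the criterion and the projection loop are
implemented; nothing beyond what the rotation needs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["oblimin_criterion", "oblimin_rotate"]


def oblimin_criterion(L: np.ndarray, gamma: float = 0.0) -> tuple[float, np.ndarray]:
    """Criterion value and gradient dF/dL for the oblimin family."""
    L = np.asarray(L, dtype=float)
    p, m = L.shape
    L2 = L**2
    N = np.ones((m, m)) - np.eye(m)
    if gamma != 0.0:
        C = np.full((p, p), 1.0 / p)
        X = (np.eye(p) - gamma * C) @ L2 @ N
    else:
        X = L2 @ N
    f = float(np.sum(L2 * X) / 4.0)
    G = L * X
    return f, G


def oblimin_rotate(
    A: np.ndarray,
    gamma: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Oblique gradient-projection rotation minimizing the oblimin criterion.

    Returns ``(L, T, f)`` where ``L = A @ inv(T).T`` is the rotated matrix,
    ``T`` the rotation with unit-norm columns, and ``f`` the final
    criterion value (never above the criterion of ``A`` itself).
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    T = np.eye(m)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        ft, Tt = f, T
        for _inner in range(20):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            Tt = X @ np.diag(v)
            try:
                Ti = np.linalg.inv(Tt)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            Lt = A @ Ti.T
            ft, Gq = oblimin_criterion(Lt, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        if ft >= f:  # no descent found; converged
            break
        T, f, L = Tt, ft, Lt
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    return L, T, f
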