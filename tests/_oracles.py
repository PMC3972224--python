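"""Independent reference implementations used only as test oracles.

Deliberately written from the textbook formulas, without reusing any
code path from the package under test: a plain NIPALS PLS2 with
score deflation, plus the block-balancing standardization applied
before it. Slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np


def standardize_block(X: np.ndarray) -> np.ndarray:
    """Center, autoscale (ddof=1) and divide by sqrt(p * (n - 1)) so the
    block's total sum of squares is 1."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return Xs / np.sqrt(p * (n - 1))


def nipals_pls2(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = 1e-13,
    max_iter: int = 5000,
):
    """Two-block PLS2 via NIPALS with deflation of X and Y on the X
    score. Returns (T, W, P, C): scores, unit-norm weights, X loadings,
    Y regression loadings. Sign: largest-|.| weight entry positive.
    """
    X = np.asarray(X, dtype=float).copy()
    Y = np.asarray(Y, dtype=float).copy()
    n = X.shape[0]
    T = np.zeros((n, n_components))
    W = np.zeros((X.shape[1], n_components))
    P = np.zeros((X.shape[1], n_components))
    C = np.zeros((Y.shape[1], n_components))
    for h in range(n_components):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        for _ in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t
            q /= np.linalg.norm(q)
            u_new = Y @ q
            if np.linalg.norm(u_new - u) / np.linalg.norm(u_new) < tol:
                u = u_new
                break
            u = u_new
        if w[int(np.argmax(np.abs(w)))] < 0:
            w, t = -w, -t
        tt = float(t @ t)
        p = X.T @ t / tt
        c = Y.T @ t / tt
        X -= np.outer(t, p)
        Y -= np.outer(t, c)
        T[:, h] = t
        W[:, h] = w
        P[:, h] = p
        C[:, h] = c
    return T, W, P, C
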