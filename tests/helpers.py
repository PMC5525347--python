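"""Independent oracles and small utilities shared across the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def std_cols(X: np.ndarray) -> np.ndarray:
    """Population-convention columnwise z-score (x_j'x_j/n = 1)."""
    return (X - X.mean(axis=0)) / X.std(axis=0)


def orthonormal_design(n: int, p: int, seed: int = 0) -> np.ndarray:
    """Design with X'X/n exactly the identity (columns mean zero)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, p + 1))
    A[:, 0] = 1.0  # force orthogonality to the constant => columns mean 0
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:] * np.sqrt(n)


def soft_threshold(z: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def lasso_objective(X, y, beta, lam) -> float:
    n = X.shape[0]
    r = y - X @ beta
    return 0.5 * float(r @ r) / n + lam * float(np.abs(beta).sum())


def lasso_enumeration_oracle(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Exact Lasso solution by enumerating supports and sign patterns.

    For every support S and sign vector s on S, solve the stationarity
    system (X_S'X_S/n) b = X_S'y/n - lam*s and keep solutions whose signs
    match and whose inactive coordinates satisfy the subgradient bound.
    Feasible only for tiny p; exact up to linear-solve precision.
    """
    n, p = X.shape
    c = X.T @ y / n
    G = X.T @ X / n
    best, best_obj = np.zeros(p), lasso_objective(X, y, np.zeros(p), lam)
    if np.all(np.abs(c) <= lam + 1e-12):
        return best
    for k in range(1, p + 1):
        for S in combinations(range(p), k):
            S = list(S)
            GS = G[np.ix_(S, S)]
            for bits in range(2 ** k):
                s = np.array([1.0 if bits >> i & 1 else -1.0 for i in range(k)])
                try:
                    b = np.linalg.solve(GS, c[S] - lam * s)
                except np.linalg.LinAlgError:
                    continue
                if np.any(np.sign(b) != s):
                    continue
                beta = np.zeros(p)
                beta[S] = b
                grad = c - G @ beta
                inactive = np.setdiff1d(np.arange(p), S)
                if np.any(np.abs(grad[inactive]) > lam + 1e-10):
                    continue
                obj = lasso_objective(X, y, beta, lam)
                if obj < best_obj:
                    best, best_obj = beta, obj
    return best
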