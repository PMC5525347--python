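"""Lasso fitting engine: coordinate descent, sparsity-targeted bisection, cross-validation.

Objective convention
--------------------
All routines minimise

    (1 / (2n)) * ||y - X b||^2  +  lam * ||b||_1

with ``X`` standardized (each column mean 0, variance 1 with the 1/n
denominator, so that x_j' x_j / n = 1) and ``y`` centered.  The intercept is
handled by centering and is therefore identically zero in the fit.  On this
scale the penalty that yields a per-coefficient type-1-error rate alpha under
the global null is approximately z_{1-alpha/2} * sigma / sqrt(n); the
conversion to the unscaled objective ``(1/2)||y - Xb||^2 + lam'||b||_1`` is
``lam' = n * lam``.

Two cyclic coordinate-descent kernels are provided: a residual-updating one
(works directly on X, memory O(np)) and a Gram/covariance-updating one that
reuses a precomputed ``G = X'X/n`` across many fits with different responses —
the workhorse for permutation and bootstrap loops, where only ``c = X'y/n``
changes between fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

# Convergence: max absolute coefficient change per sweep must drop below
# CD_TOL; a fit that fails to do so within CD_MAX_SWEEPS raises.  The tight
# default is needed so that nonzero counts are resolved reliably near knots
# of the regularization path during bisection.
CD_TOL = 1e-7
CD_MAX_SWEEPS = 100_000

#: largest p for which the Gram (covariance-updating) strategy is used by
#: default; beyond this the p x p Gram matrix is not worth materialising.
GRAM_MAX_P = 4000


class ConvergenceError(RuntimeError):
    """Coordinate descent did not converge; carries the attained KKT violation."""

    def __init__(self, msg: str, kkt_violation: float):
        super().__init__(msg)
        self.kkt_violation = kkt_violation


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sweep_naive(X, r, beta, colnorm, lam, active_only):
    """One cyclic sweep with residual updating. Returns max |coef change|."""
    n, p = X.shape
    max_change = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        if colnorm[j] <= 0.0:
            continue
        rho = 0.0
        for i in range(n):
            rho += X[i, j] * r[i]
        rho = rho / n + colnorm[j] * bj
        if rho > lam:
            new = (rho - lam) / colnorm[j]
        elif rho < -lam:
            new = (rho + lam) / colnorm[j]
        else:
            new = 0.0
        d = new - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = new
            ad = abs(d)
            if ad > max_change:
                max_change = ad
    return max_change


@njit(cache=True)
def _cd_naive(X, r, beta, colnorm, lam, tol, max_sweeps):
    """Full coordinate descent with an active-set strategy.

    Alternates full sweeps with inner sweeps restricted to the current
    nonzero set.  Returns (sweeps_used, last_full_sweep_change).
    """
    sweeps = 0
    while sweeps < max_sweeps:
        change = _sweep_naive(X, r, beta, colnorm, lam, False)
        sweeps += 1
        if change < tol:
            return sweeps, change
        while sweeps < max_sweeps:
            change = _sweep_naive(X, r, beta, colnorm, lam, True)
            sweeps += 1
            if change < tol:
                break
    return sweeps, change


@njit(cache=True)
def _sweep_gram(G, c, q, beta, lam, active_only):
    """One cyclic sweep, covariance updating: q = G @ beta is maintained."""
    p = c.shape[0]
    max_change = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        gjj = G[j, j]
        if gjj <= 0.0:
            continue
        rho = c[j] - q[j] + gjj * bj
        if rho > lam:
            new = (rho - lam) / gjj
        elif rho < -lam:
            new = (rho + lam) / gjj
        else:
            new = 0.0
        d = new - bj
        if d != 0.0:
            for k in range(p):
                q[k] += G[k, j] * d
            beta[j] = new
            ad = abs(d)
            if ad > max_change:
                max_change = ad
    return max_change


@njit(cache=True)
def _cd_gram(G, c, q, beta, lam, tol, max_sweeps):
    sweeps = 0
    while sweeps < max_sweeps:
        change = _sweep_gram(G, c, q, beta, lam, False)
        sweeps += 1
        if change < tol:
            return sweeps, change
        while sweeps < max_sweeps:
            change = _sweep_gram(G, c, q, beta, lam, True)
            sweeps += 1
            if change < tol:
                break
    return sweeps, change


# ---------------------------------------------------------------------------
# public types
# ---------------------------------------------------------------------------


@dataclass
class LassoFit:
    """A Lasso solution at a fixed penalty on the 1/n-scaled objective."""

    lam: float
    beta: np.ndarray
    intercept: float
    n_nonzero: int
    residuals: np.ndarray
    objective: float
    n_sweeps: int = 0
    kkt_violation: float = float("nan")

    @property
    def nonzero_idx(self) -> np.ndarray:
        return np.flatnonzero(self.beta)

    def to_frame(self, snp_ids=None):
        import pandas as pd

        p = self.beta.shape[0]
        ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(p)]
        return pd.DataFrame(
            {"snp_id": ids, "beta": self.beta, "nonzero": self.beta != 0.0}
        )


@dataclass
class CvResult:
    """10-fold cross-validation over a descending lambda grid."""

    lambda_grid: np.ndarray
    cv_error: np.ndarray
    lambda_selected: float
    fold_seed: int


class GramCache:
    """Precomputed ``G = X'X/n`` reusable across fits with different responses."""

    def __init__(self, X: np.ndarray):
        X = np.ascontiguousarray(X, dtype=np.float64)
        self.X = X
        self.n = X.shape[0]
        self.G = np.asfortranarray(X.T @ X / self.n)

    def xty(self, y: np.ndarray) -> np.ndarray:
        return self.X.T @ np.asarray(y, dtype=np.float64) / self.n


def precompute_gram(X: np.ndarray) -> GramCache:
    return GramCache(X)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _check_xy(X, y):
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise InvalidParameterError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
        )
    return X, y


def kkt_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Max violation of the stationarity conditions at ``beta``.

    For zero coordinates the subgradient condition is |x_j'(y-Xb)/n| <= lam;
    for nonzero ones x_j'(y-Xb)/n = lam*sign(b_j).
    """
    X, y = _check_xy(X, y)
    n = X.shape[0]
    g = X.T @ (y - X @ beta) / n
    nz = beta != 0.0
    v_zero = np.max(np.abs(g[~nz]) - lam, initial=0.0)
    v_nz = np.max(np.abs(g[nz] - lam * np.sign(beta[nz])), initial=0.0)
    return max(v_zero, max(v_nz, 0.0))


def _fit_beta_gram(gram: GramCache, c: np.ndarray, lam: float,
                   warm_start: np.ndarray | None = None,
                   tol: float = CD_TOL, max_sweeps: int = CD_MAX_SWEEPS):
    """Fast path: coefficients only, from a precomputed Gram and c = X'y/n."""
    p = c.shape[0]
    if warm_start is not None and np.any(warm_start):
        beta = np.array(warm_start, dtype=np.float64)
        q = gram.G @ beta
    else:
        beta = np.zeros(p)
        q = np.zeros(p)
    sweeps, change = _cd_gram(gram.G, c, q, beta, lam, tol, max_sweeps)
    if change >= tol:
        viol = float(np.max(np.abs(np.clip(np.abs(c - q) - lam, 0.0, None))))
        raise ConvergenceError(
            f"coordinate descent did not converge at lam={lam:g} "
            f"({sweeps} sweeps, KKT violation {viol:.3e})", viol)
    return beta, sweeps


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float,
              warm_start: np.ndarray | None = None, *,
              tol: float = CD_TOL, max_sweeps: int = CD_MAX_SWEEPS,
              precompute: GramCache | None = None) -> LassoFit:
    """Fit the Lasso at a single penalty value by cyclic coordinate descent.

    Parameters
    ----------
    X : (n, p) standardized design (columns mean 0; x_j'x_j/n need not be
        exactly 1 — column norms are handled explicitly).
    y : length-n centered response.
    lam : penalty on the 1/n-scaled objective; must be >= 0.
    warm_start : optional initial coefficient vector.
    precompute : optional :class:`GramCache` built from the same ``X``; makes
        repeated fits with varying ``y`` (permutations, bootstrap) much cheaper.

    Raises
    ------
    InvalidParameterError
        If ``lam < 0``.
    ConvergenceError
        If the stated tolerance is not reached within ``max_sweeps``; the
        exception carries the attained KKT violation.
    """
    if lam < 0:
        raise InvalidParameterError(f"lam must be nonnegative, got {lam}")
    X, y = _check_xy(X, y)
    n, p = X.shape

    if precompute is not None:
        c = precompute.xty(y)
        beta, sweeps = _fit_beta_gram(precompute, c, lam, warm_start,
                                      tol, max_sweeps)
        r = y - X @ beta
    else:
        beta = (np.array(warm_start, dtype=np.float64) if warm_start is not None
                else np.zeros(p))
        r = y - X @ beta if np.any(beta) else y.copy()
        colnorm = np.einsum("ij,ij->j", X, X) / n
        sweeps, change = _cd_naive(X, r, beta, colnorm, lam, tol, max_sweeps)
        if change >= tol:
            viol = kkt_violation(X, y, beta, lam)
            raise ConvergenceError(
                f"coordinate descent did not converge at lam={lam:g} "
                f"({sweeps} sweeps, KKT violation {viol:.3e})", viol)

    obj = 0.5 * float(r @ r) / n + lam * float(np.abs(beta).sum())
    return LassoFit(lam=float(lam), beta=beta, intercept=0.0,
                    n_nonzero=int(np.count_nonzero(beta)), residuals=r,
                    objective=obj, n_sweeps=int(sweeps))


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution: max_j |x_j'y| / n."""
    X, y = _check_xy(X, y)
    return float(np.max(np.abs(X.T @ y)) / X.shape[0]) if X.shape[1] else 0.0


def partial_residual_ols(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                         j: int) -> float:
    """Marginal OLS coefficient of SNP j against its partial residual.

    Computes (1/n) * x_j' r_(j) with r_(j) = y - sum_{k != j} x_k beta_k.
    At a Lasso solution this equals beta_j + lam*sign(beta_j) for active
    coordinates and lies in [-lam, lam] for inactive ones.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if not (0 <= j < p):
        raise IndexError(f"SNP index {j} out of range for p={p}")
    r_j = y - X @ beta + X[:, j] * beta[j]
    return float(X[:, j] @ r_j / n)


# ---------------------------------------------------------------------------
# bisection for an exact nonzero count
# ---------------------------------------------------------------------------


def _nnz_at(lam, X, y, gram, c, state):
    """Nonzero count at lam, warm-starting from the previous evaluation."""
    if gram is not None:
        beta, _ = _fit_beta_gram(gram, c, lam, warm_start=state.get("beta"))
    else:
        fit = fit_lasso(X, y, lam, warm_start=state.get("beta"))
        beta = fit.beta
    state["beta"] = beta
    return int(np.count_nonzero(beta))


def find_lambda_for_sparsity(X: np.ndarray, y: np.ndarray, s: int, *,
                             tol: float | None = None,
                             precompute: GramCache | None = None,
                             return_trace: bool = False):
    """Largest penalty whose Lasso fit has exactly ``s`` nonzero coefficients.

    Bisects on [0, lambda_max].  The nonzero count is a (generically)
    non-increasing step function of the penalty, so the bracket
    ``count(a) >= s > count(b)`` shrinks until ``b - a`` is below ``tol``
    (default 1e-6 * lambda_max).  If the count jumps past ``s`` — several
    coefficients entering at once — the smallest bracketed penalty with
    count <= s is returned and the discrepancy logged, which errs on the side
    of fewer discoveries.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if not 0 <= s <= p:
        raise InvalidParameterError(f"target sparsity s={s} not in [0, p={p}]")
    if s > n:
        raise InvalidParameterError(f"target sparsity s={s} exceeds n={n}")
    lmax = lambda_max(X, y)
    trace: list[tuple[float, int]] = []
    if s == 0 or lmax == 0.0:
        return (lmax, trace) if return_trace else lmax
    if tol is None:
        tol = 1e-6 * lmax

    gram = precompute
    c = gram.xty(y) if gram is not None else None
    state: dict = {}

    def nnz(lam):
        k = _nnz_at(lam, X, y, gram, c, state)
        trace.append((lam, k))
        return k

    # bracket: count(b) < s always (b starts at lmax where count = 0)
    b = lmax
    a = 0.5 * lmax
    while nnz(a) < s:
        b = a
        a *= 0.5
        if a < 1e-14 * lmax:
            raise InvalidParameterError(
                f"no penalty on the path yields {s} nonzero coefficients")
    for _ in range(100):
        if b - a <= tol:
            break
        m = 0.5 * (a + b)
        if nnz(m) >= s:
            a = m
        else:
            b = m
    count_a = _nnz_at(a, X, y, gram, c, state)
    if count_a == s:
        lam_out = a
    else:
        # simultaneous entries: fall back to the conservative side
        count_b = _nnz_at(b, X, y, gram, c, state)
        logger.debug(
            "exact sparsity %d unattainable (counts %d/%d at bracket); "
            "returning conservative lam=%g with %d nonzeros",
            s, count_a, count_b, b, count_b)
        lam_out = b
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug("bisection trace (s=%d): %s", s,
                     [(round(l, 6), k) for l, k in trace])
    return (lam_out, trace) if return_trace else lam_out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 100,
                        ratio: float | None = None) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to ratio*lambda_max.

    The default floor follows the usual path convention: 1e-4*lambda_max
    when n > p, 1e-2*lambda_max when p >= n (where the unpenalized limit is
    ill-posed and coordinate descent stalls).
    """
    lmax = lambda_max(X, y)
    if lmax <= 0:
        return np.array([0.0])
    if ratio is None:
        n, p = X.shape
        ratio = 1e-4 if n > p else 1e-2
    return np.geomspace(lmax, ratio * lmax, n_points)


def cv_lambda(X: np.ndarray, y: np.ndarray, n_folds: int = 10,
              grid: np.ndarray | None = None, seed: int = 0,
              tol: float = 1e-4) -> CvResult:
    """Select the penalty by K-fold cross-validation (minimum mean MSE).

    Fold assignment is a seeded random partition; the selection rule is the
    plain CV-error minimiser (no one-standard-error rule).  Within each fold
    the descending grid is fit with warm starts.  The fold fits use a looser
    coordinate tolerance than the inference fits: held-out MSE is flat to
    far below it, while the dense low-penalty end of a p >= n path would
    take orders of magnitude longer at the sparsity-resolving tolerance.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < n_folds:
        raise InvalidParameterError(f"n={n} < n_folds={n_folds}")
    if grid is None:
        grid = default_lambda_grid(X, y)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise InvalidParameterError("empty lambda grid")
    grid = np.sort(grid)[::-1].copy()

    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(n) % n_folds)
    sse = np.zeros(grid.size)
    use_gram = p <= GRAM_MAX_P
    for f in range(n_folds):
        test = fold_of == f
        Xtr, ytr = X[~test], y[~test]
        Xte, yte = X[test], y[test]
        gram = GramCache(Xtr) if use_gram else None
        c = gram.xty(ytr) if gram is not None else None
        beta = np.zeros(p)
        for k, lam in enumerate(grid):
            if gram is not None:
                beta, _ = _fit_beta_gram(gram, c, lam, warm_start=beta, tol=tol)
            else:
                beta = fit_lasso(Xtr, ytr, lam, warm_start=beta, tol=tol).beta
            resid = yte - Xte @ beta
            sse[k] += float(resid @ resid)
    cv_error = sse / n
    best = int(np.argmin(cv_error))
    return CvResult(lambda_grid=grid, cv_error=cv_error,
                    lambda_selected=float(grid[best]), fold_seed=int(seed))
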