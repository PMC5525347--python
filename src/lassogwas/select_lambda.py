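"""Penalty selection for direct type-1-error control.

Three selectors share one idea: under the global null (all coefficients
zero), the event "SNP j has a nonzero Lasso coefficient at penalty lam" is
(coordinate-wise) the event |marginal OLS statistic| > lam, and the marginal
statistic is ~ N(0, sigma^2/n).  The penalty lam_alpha whose selection rule
has per-SNP type-1-error alpha is therefore the (1 - alpha/2) quantile of
that null distribution.

* ``estimate_lambda_alpha_once`` — permute the response once and locate the
  penalty that leaves exactly ``s = alpha*p`` coefficients nonzero (the
  sample-quantile estimate); for alpha < 1/p the k-max variant takes the
  maximum first-entry penalty over k permutations, alpha = 1/(p*k).
* ``estimate_lambda_alpha`` — average B independent replicates
  (lambda-bar), shrinking the estimator's variance by 1/B.  B=1 is exactly
  the single-permutation selector of Ayers & Cordell.
* ``analytic_lambda_alpha`` — invert the normal approximation
  2*Phi(-sqrt(n)*lam/sigma_hat(lam)) = alpha over a penalty grid, with
  sigma^2 re-estimated from the Lasso residuals at each grid point.

The decision rule at the selected penalty is: reject H0: beta_j = 0 iff the
Lasso coefficient at that penalty is nonzero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lasso import (GramCache, InvalidParameterError, fit_lasso,
                    find_lambda_for_sparsity, lambda_max)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class DecisionSet:
    """Per-SNP reject/accept decisions from one inference method."""

    reject: np.ndarray
    method: str
    alpha: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.reject = np.asarray(self.reject, dtype=bool)

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())

    def to_frame(self, snp_ids=None) -> pd.DataFrame:
        p = self.reject.shape[0]
        ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(p)]
        out = pd.DataFrame({"snp_id": ids, "reject": self.reject})
        for key, val in self.extras.items():
            arr = np.asarray(val)
            if arr.shape == (p,):
                out[key] = arr
        return out


@dataclass
class LambdaEstimate:
    """Replicated permutation estimates of the error-controlling penalty."""

    alpha: float
    attained_alpha: float
    replicates: np.ndarray
    aggregate: float
    aggregate_stat: str  # "mean" | "median"
    variant: str         # "s-sparse" | "k-max"
    B: int
    s: int | None
    k: int | None
    seed: int


@dataclass
class StabilityTrace:
    """Selected-SNP counts as a function of the number of permutations B."""

    B: np.ndarray
    selected_count: np.ndarray
    #: symmetric-difference size between the selections at B and B-1
    #: (NaN at B=1, where there is no predecessor)
    discrepancy: np.ndarray
    lambdas: np.ndarray


# ---------------------------------------------------------------------------
# significance-level bookkeeping
# ---------------------------------------------------------------------------


def resolve_alpha(alpha: float, p: int):
    """Map alpha to the nearest representable level s/p or 1/(p*k).

    Returns (variant, s_or_k, attained_alpha).  Levels alpha >= 1/p use the
    s-sparse variant with s = round(alpha*p) >= 1; smaller levels use the
    k-max variant with k = round(1/(alpha*p)).
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    if p < 1:
        raise InvalidParameterError(f"need p >= 1 SNPs, got {p}")
    target = alpha * p
    if target >= 0.5:
        s = max(1, int(round(target)))
        if s > p:
            s = p
        return "s-sparse", s, s / p
    k = max(1, int(round(1.0 / target)))
    return "k-max", k, 1.0 / (p * k)


# ---------------------------------------------------------------------------
# permutation selectors
# ---------------------------------------------------------------------------


def estimate_lambda_alpha_once(X: np.ndarray, y: np.ndarray, alpha: float,
                               seed=0, *, precompute: GramCache | None = None
                               ) -> float:
    """One permutation replicate of the error-controlling penalty.

    s-sparse variant: permute y and bisect for the largest penalty whose fit
    on the permuted data has exactly s nonzero coefficients.  k-max variant
    (alpha < 1/p): pool the k*p marginal null statistics |x_j'y_perm|/n from
    k permutations; any penalty between the largest and second-largest pooled
    statistic leaves exactly one of the k*p null coefficients nonzero, and
    the midpoint of that interval is taken.  (The midpoint is the Hazen
    empirical-quantile estimate at level 1 - 1/(k*p) and is unbiased for the
    target null quantile z_{1-alpha/2}*sigma/sqrt(n); the upper endpoint —
    the strict maximum — overshoots it by several percent at k*p ~ 100.)
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    variant, sk, _ = resolve_alpha(alpha, p)
    rng = np.random.default_rng(seed)
    if variant == "s-sparse":
        y_perm = rng.permutation(y)
        return float(find_lambda_for_sparsity(X, y_perm, sk,
                                              precompute=precompute))
    top = np.zeros(2)  # two largest pooled statistics
    for _ in range(sk):
        stats_i = np.abs(X.T @ rng.permutation(y)) / n
        top = np.sort(np.concatenate([top, np.sort(stats_i)[-2:]]))[-2:]
    return float(top.mean())


def estimate_lambda_alpha(X: np.ndarray, y: np.ndarray, alpha: float,
                          B: int = 100, aggregate: str = "mean", seed: int = 0,
                          *, precompute: GramCache | None = None
                          ) -> LambdaEstimate:
    """lambda-bar: aggregate of B independent permutation replicates."""
    if B < 1:
        raise InvalidParameterError(f"need B >= 1 replicates, got {B}")
    if aggregate not in ("mean", "median"):
        raise InvalidParameterError(f"aggregate must be mean|median, got {aggregate!r}")
    X = np.asarray(X, dtype=np.float64)
    variant, sk, attained = resolve_alpha(alpha, X.shape[1])
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(B)
    reps = np.array([
        estimate_lambda_alpha_once(X, y, alpha, seed=child, precompute=precompute)
        for child in children])
    agg = float(np.mean(reps) if aggregate == "mean" else np.median(reps))
    return LambdaEstimate(
        alpha=alpha, attained_alpha=attained, replicates=reps, aggregate=agg,
        aggregate_stat=aggregate, variant=variant, B=B,
        s=sk if variant == "s-sparse" else None,
        k=sk if variant == "k-max" else None, seed=seed)


def _decide_at_lambda(X, y, lam, alpha, method, precompute, extras=None):
    fit = fit_lasso(X, y, lam, precompute=precompute)
    ex = {"lambda": lam, "beta_at_lambda": fit.beta}
    if extras:
        ex.update(extras)
    return DecisionSet(reject=fit.beta != 0.0, method=method, alpha=alpha,
                       extras=ex)


def lasso_pl_test(X: np.ndarray, y: np.ndarray, alpha: float, B: int = 100,
                  aggregate: str = "mean", seed: int = 0, *,
                  precompute: GramCache | None = None) -> DecisionSet:
    """Permutation-averaged penalty selection (B replicates), then decide.

    The Lasso is refit to the *original* (unpermuted) data at lambda-bar;
    every SNP with a nonzero coefficient there is declared significant.
    """
    est = estimate_lambda_alpha(X, y, alpha, B=B, aggregate=aggregate,
                                seed=seed, precompute=precompute)
    return _decide_at_lambda(X, y, est.aggregate, alpha, "Lasso-PL",
                             precompute, {"lambda_estimate": est})


def lasso_ayers_test(X: np.ndarray, y: np.ndarray, alpha: float,
                     seed: int = 0, *, precompute: GramCache | None = None
                     ) -> DecisionSet:
    """Single-permutation penalty selection: lasso_pl_test with B = 1."""
    out = lasso_pl_test(X, y, alpha, B=1, aggregate="mean", seed=seed,
                        precompute=precompute)
    out.method = "Lasso-Ayers"
    return out


# ---------------------------------------------------------------------------
# analytic selector
# ---------------------------------------------------------------------------


def default_al_grid(y: np.ndarray, n: int, alpha: float,
                    n_points: int = 200) -> np.ndarray:
    """Log-spaced window around the closed-form guess z_{1-a/2}*sd(y)/sqrt(n)."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    guess = z * float(np.std(y)) / np.sqrt(n)
    return np.geomspace(0.3 * guess, 1.5 * guess, n_points)


def analytic_lambda_alpha(X: np.ndarray, y: np.ndarray, alpha: float,
                          grid: np.ndarray | None = None, *,
                          precompute: GramCache | None = None):
    """Analytic penalty selection via the estimated type-1-error profile.

    For each grid penalty: fit the Lasso, estimate the residual variance as
    RSS/(n - df) with df = number of nonzero coefficients, and estimate the
    per-SNP type-1-error e(lam) = 2*Phi(-sqrt(n)*lam/sigma_hat).  Returns the
    penalty whose estimated error is closest to alpha (preferring the
    conservative side on ties) together with the full profile.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    if grid is None:
        grid = default_al_grid(y, n, alpha)
    grid = np.sort(np.asarray(grid, dtype=np.float64))[::-1]
    if grid.size == 0:
        raise InvalidParameterError("empty penalty grid")

    lams, dfs, sigmas, rates = [], [], [], []
    beta = np.zeros(p)
    for lam in grid:  # descending, warm-started
        fit = fit_lasso(X, y, lam, warm_start=beta, precompute=precompute)
        beta = fit.beta
        df = fit.n_nonzero
        rss = float(fit.residuals @ fit.residuals)
        sigma = np.sqrt(rss / (n - df)) if df < n else np.inf
        rate = 2.0 * stats.norm.sf(np.sqrt(n) * lam / sigma) if np.isfinite(sigma) else 1.0
        lams.append(lam); dfs.append(df); sigmas.append(sigma); rates.append(rate)

    profile = pd.DataFrame({"lambda": lams, "n_nonzero": dfs,
                            "sigma_hat": sigmas, "est_type1": rates})
    diff = np.abs(profile["est_type1"].to_numpy() - alpha)
    conservative = profile["est_type1"].to_numpy() <= alpha
    order = np.lexsort((~conservative, diff))  # min |diff|, prefer e <= alpha
    best = int(order[0])
    if diff[best] > 10.0 * alpha:
        warnings.warn(
            f"no grid penalty attains an estimated type-1-error within "
            f"10*alpha of alpha={alpha:g} (closest: "
            f"{profile['est_type1'].iloc[best]:.3g}); widen the grid",
            stacklevel=2)
    return float(profile["lambda"].iloc[best]), profile


def lasso_al_test(X: np.ndarray, y: np.ndarray, alpha: float,
                  grid: np.ndarray | None = None, *,
                  precompute: GramCache | None = None) -> DecisionSet:
    """Decision rule at the analytically selected penalty."""
    lam, profile = analytic_lambda_alpha(X, y, alpha, grid,
                                         precompute=precompute)
    return _decide_at_lambda(X, y, lam, alpha, "Lasso-AL", precompute,
                             {"al_profile": profile})


# ---------------------------------------------------------------------------
# stability diagnostic
# ---------------------------------------------------------------------------


def stability_diagnostic(X: np.ndarray, y: np.ndarray, alpha: float,
                         B_max: int, seed: int = 0, aggregate: str = "mean",
                         *, precompute: GramCache | None = None
                         ) -> StabilityTrace:
    """Selection stability as the number of permutations grows.

    For each B = 1..B_max the decisions under lambda-bar computed from the
    first B replicates are compared with those at B-1; a stable estimate
    shows the selected count converging and the discrepancy hitting zero.
    The B=1 entry reproduces the single-permutation (Ayers) selection.
    """
    if B_max < 2:
        raise InvalidParameterError(f"need B_max >= 2, got {B_max}")
    est = estimate_lambda_alpha(X, y, alpha, B=B_max, aggregate=aggregate,
                                seed=seed, precompute=precompute)
    reps = est.replicates
    stat = np.mean if aggregate == "mean" else np.median
    counts = np.zeros(B_max, dtype=np.intp)
    disc = np.full(B_max, np.nan)
    lambdas = np.zeros(B_max)
    prev_sel = None
    beta = None
    for b in range(1, B_max + 1):
        lam = float(stat(reps[:b]))
        fit = fit_lasso(X, y, lam, warm_start=beta, precompute=precompute)
        beta = fit.beta
        sel = frozenset(np.flatnonzero(beta).tolist())
        counts[b - 1] = len(sel)
        lambdas[b - 1] = lam
        if prev_sel is not None:
            disc[b - 1] = len(sel ^ prev_sel)
        prev_sel = sel
    return StabilityTrace(B=np.arange(1, B_max + 1), selected_count=counts,
                          discrepancy=disc, lambdas=lambdas)
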