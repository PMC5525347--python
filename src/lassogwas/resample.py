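"""Residual bootstrap, modified residual bootstrap, and permutation test.

All three fix the penalty first (typically by 10-fold cross-validation) and
then resample at that fixed penalty:

* Lasso-RB — resample centered model residuals with replacement, rebuild
  y* = X beta_hat + e*, refit, and form reflected ("basic") percentile
  confidence intervals 2*beta_hat - q*; reject where 0 is outside.
* Lasso-MRB — the same around a hard-thresholded coefficient vector
  beta_tilde (|beta_hat| <= tau zeroed), with residuals taken from the
  thresholded fit and interval beta_hat + beta_tilde - q**.
* Lasso-PT — permute y, refit, and compare |coefficients|; the p-value is
  (#{|beta_perm| > |beta_obs|} + 1) / (B + 1).

These procedures are known to degrade as the number of null predictors
grows at fixed n: cross-validation then over-penalises and the bootstrap no
longer approximates the sampling distribution of the Lasso.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lasso import GramCache, InvalidParameterError, fit_lasso
from .select_lambda import DecisionSet


@dataclass
class BootstrapDistribution:
    """B x p matrix of bootstrap coefficient draws around a fixed center."""

    draws: np.ndarray
    center: np.ndarray
    lam: float
    B: int
    tau: float | None = None


@dataclass
class PermutationPvalues:
    """Permutation p-values on the attainable grid {1/(B+1), ..., 1}."""

    p_values: np.ndarray
    B: int
    observed: np.ndarray


def _centered_residuals(y, yhat):
    e = y - yhat
    return e - e.mean()


def _check_b_alpha(B, alpha):
    if B < 2:
        raise InvalidParameterError(f"need B >= 2 bootstrap draws, got {B}")
    if alpha / 2.0 < 1.0 / B:
        raise InvalidParameterError(
            f"B={B} too small to estimate the alpha/2={alpha / 2:g} quantile; "
            f"need B >= {int(np.ceil(2.0 / alpha))}")


def _bootstrap_draws(X, y_center, e_c, lam, B, seed, precompute, start):
    """Refit the Lasso at fixed lam on B resampled responses."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    draws = np.empty((B, p))
    beta = start.copy()
    for b in range(B):
        e_star = e_c[rng.integers(0, n, size=n)]
        y_star = y_center + e_star
        beta = fit_lasso(X, y_star, lam, warm_start=beta,
                         precompute=precompute).beta
        draws[b] = beta
    return draws


def residual_bootstrap(X: np.ndarray, y: np.ndarray, lam: float, B: int = 1000,
                       alpha: float = 0.01, seed: int = 0, *,
                       precompute: GramCache | None = None
                       ) -> tuple[DecisionSet, BootstrapDistribution]:
    """Residual-bootstrap test of every coefficient at a fixed penalty."""
    _check_b_alpha(B, alpha)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    fit = fit_lasso(X, y, lam, precompute=precompute)
    yhat = X @ fit.beta  # same reconstruction as the thresholded variant
    e_c = _centered_residuals(y, yhat)
    draws = _bootstrap_draws(X, yhat, e_c, lam, B, seed, precompute, fit.beta)
    lo_q = np.quantile(draws, alpha / 2.0, axis=0)        # linear interpolation
    hi_q = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    ci_lo = 2.0 * fit.beta - hi_q
    ci_hi = 2.0 * fit.beta - lo_q
    reject = (ci_lo > 0.0) | (ci_hi < 0.0)
    dist = BootstrapDistribution(draws=draws, center=fit.beta.copy(), lam=lam, B=B)
    dec = DecisionSet(reject=reject, method="Lasso-RB", alpha=alpha,
                      extras={"lambda": lam, "estimate": fit.beta,
                              "ci_low": ci_lo, "ci_high": ci_hi})
    return dec, dist


def modified_residual_bootstrap(X: np.ndarray, y: np.ndarray, lam: float,
                                tau: float, B: int = 1000, alpha: float = 0.01,
                                seed: int = 0, *,
                                precompute: GramCache | None = None
                                ) -> tuple[DecisionSet, BootstrapDistribution]:
    """Residual bootstrap around the hard-thresholded coefficient vector."""
    if tau < 0:
        raise InvalidParameterError(f"threshold tau must be >= 0, got {tau}")
    _check_b_alpha(B, alpha)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    fit = fit_lasso(X, y, lam, precompute=precompute)
    beta_t = np.where(np.abs(fit.beta) > tau, fit.beta, 0.0)
    yhat_t = X @ beta_t
    e_c = _centered_residuals(y, yhat_t)
    draws = _bootstrap_draws(X, yhat_t, e_c, lam, B, seed, precompute, beta_t)
    lo_q = np.quantile(draws, alpha / 2.0, axis=0)
    hi_q = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    ci_lo = fit.beta + beta_t - hi_q
    ci_hi = fit.beta + beta_t - lo_q
    reject = (ci_lo > 0.0) | (ci_hi < 0.0)
    dist = BootstrapDistribution(draws=draws, center=beta_t, lam=lam, B=B, tau=tau)
    dec = DecisionSet(reject=reject, method=f"Lasso-MRB(t={tau:g})", alpha=alpha,
                      extras={"lambda": lam, "tau": tau, "estimate": fit.beta,
                              "ci_low": ci_lo, "ci_high": ci_hi})
    return dec, dist


#: threshold sweep conventionally reported for the modified bootstrap
MRB_TAU_PRESET = (0.001, 0.005, 0.01, 0.03, 0.05)


def permutation_test(X: np.ndarray, y: np.ndarray, lam: float, B: int = 999,
                     seed: int = 0, *, precompute: GramCache | None = None
                     ) -> PermutationPvalues:
    """Permutation p-values for |beta_j| at a fixed penalty.

    p_j = (#{b : |beta_perm_jb| >= |beta_obs_j|} + 1) / (B + 1), so the
    smallest attainable p-value is 1/(B+1).  The as-extreme-or-more (>=)
    convention matters only on the atom at zero: a SNP whose observed
    coefficient is zero ties with every all-zero permutation fit and gets
    p = 1 rather than the floor, which keeps never-selected SNPs from being
    declared significant en masse under heavy penalties.
    """
    if B < 1:
        raise InvalidParameterError(f"need B >= 1 permutations, got {B}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    fit = fit_lasso(X, y, lam, precompute=precompute)
    observed = np.abs(fit.beta)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1], dtype=np.intp)
    beta = fit.beta.copy()
    for _ in range(B):
        y_perm = rng.permutation(y)
        beta = fit_lasso(X, y_perm, lam, warm_start=beta,
                         precompute=precompute).beta
        exceed += np.abs(beta) >= observed
    pvals = (exceed + 1.0) / (B + 1.0)
    return PermutationPvalues(p_values=pvals, B=B, observed=observed)


def lasso_pt_test(X: np.ndarray, y: np.ndarray, lam: float, B: int = 999,
                  alpha: float = 0.01, seed: int = 0, *,
                  precompute: GramCache | None = None) -> DecisionSet:
    """Permutation-test decisions: reject where p_j <= alpha."""
    pt = permutation_test(X, y, lam, B=B, seed=seed, precompute=precompute)
    return DecisionSet(reject=pt.p_values <= alpha, method="Lasso-PT",
                       alpha=alpha,
                       extras={"lambda": lam, "p_value": pt.p_values})
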