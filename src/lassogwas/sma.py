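"""Single-marker association baseline: per-SNP marginal regression t-tests.

Each SNP is tested one at a time in the simple linear model
Y = b0 + x_j b_j + eps; the two-sided p-value for H0: b_j = 0 comes from a
t-distribution with n - 2 degrees of freedom.  An intercept is always
included (numerically immaterial for centered y and standardized x, but it
fixes the degrees of freedom at the conventional n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SmaResult:
    beta_hat: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    df: int

    def to_frame(self, snp_ids=None, alpha: float | None = None):
        import pandas as pd

        p = self.beta_hat.shape[0]
        ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(p)]
        out = pd.DataFrame({"snp_id": ids, "beta": self.beta_hat,
                            "t": self.t_stat, "p": self.p_value})
        if alpha is not None:
            out["reject"] = self.p_value <= alpha
        return out


def sma_scan(X: np.ndarray, y: np.ndarray) -> SmaResult:
    """Marginal regression of y on each column of X (vectorized over SNPs)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need n >= 3 subjects for a t-test, got {n}")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    dead = np.flatnonzero(sxx == 0.0)
    if dead.size:
        raise ValueError(f"constant column(s): slope undefined for SNP index "
                         f"{dead.tolist()[:5]}")
    sxy = xc.T @ yc
    beta = sxy / sxx
    df = n - 2
    rss = np.maximum(yc @ yc - beta * sxy, 0.0)
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return SmaResult(beta_hat=beta, t_stat=t, p_value=pvals, df=df)


def sma_decide(result: SmaResult, alpha: float):
    """Reject H0: b_j = 0 wherever p_j <= alpha (the boundary rejects)."""
    from .select_lambda import DecisionSet

    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return DecisionSet(reject=result.p_value <= alpha, method="SMA",
                       alpha=alpha, extras={"p_value": result.p_value})
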