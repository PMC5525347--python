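"""Scoring decisions against simulation truth and the replicate-level harness.

Marker-level scenarios score the true positive rate (fraction of causal SNPs
declared significant) and false positive rate (fraction of null SNPs declared
significant) per replicate dataset, averaged across replicates with
Monte-Carlo standard errors (sd / sqrt(n_reps)).

Region-structured scenarios, where the causal SNPs themselves are absent and
must be tagged through linkage disequilibrium, additionally score:

* TPR   — fraction of causal regions with at least one *linked* SNP
          (|r| >= tau_ld to the region's latent causal SNP) rejected;
* LTPR  — fraction of all linked SNPs rejected;
* FPR   — fraction of SNPs linked to no causal SNP that are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import resample, select_lambda, sma
from .lasso import GRAM_MAX_P, GramCache, cv_lambda
from .select_lambda import DecisionSet
from .simdata import GenotypeMatrix, PhenotypeVector, ScenarioConfig, make_scenario


@dataclass
class MetricsReport:
    """Aggregated method comparison over replicate datasets."""

    scenario: str
    n_reps: int
    alpha: float
    summary: pd.DataFrame
    per_replicate: pd.DataFrame
    tau_ld: float | None = None
    failures: dict = field(default_factory=dict)

    def to_tsv(self, path):
        self.summary.to_csv(path, sep="\t", index=False)

    def to_json(self, path):
        import json

        with open(path, "w") as fh:
            json.dump({
                "scenario": self.scenario, "n_reps": self.n_reps,
                "alpha": self.alpha, "tau_ld": self.tau_ld,
                "summary": self.summary.to_dict(orient="records"),
                "failures": {k: len(v) for k, v in self.failures.items()},
            }, fh, indent=2)


# ---------------------------------------------------------------------------
# per-replicate scoring
# ---------------------------------------------------------------------------


def tpr_fpr(decisions: DecisionSet, causal_idx) -> tuple[float, float]:
    """Proportions of causal and null SNPs rejected in one replicate."""
    reject = decisions.reject
    causal_idx = np.atleast_1d(np.asarray(causal_idx, dtype=np.intp))
    is_causal = np.zeros(reject.shape[0], dtype=bool)
    is_causal[causal_idx] = True
    tpr = float(reject[is_causal].mean()) if is_causal.any() else np.nan
    fpr = float(reject[~is_causal].mean()) if (~is_causal).any() else np.nan
    return tpr, fpr


def region_metrics(decisions: DecisionSet, r_to_causal: np.ndarray,
                   tau_ld: float) -> tuple[float, float, float]:
    """Region-level TPR, linked TPR, and FPR under an LD-tagging cutoff.

    A SNP is linked to a latent causal SNP when |r| >= tau_ld; a region
    counts as detected when at least one of its linked SNPs is rejected.
    Regions with no linked SNP at the chosen cutoff are dropped from the
    TPR denominator (with a warning).
    """
    if not 0.0 < tau_ld < 1.0:
        raise ValueError(f"tau_ld must be in (0, 1), got {tau_ld}")
    reject = decisions.reject
    r = np.asarray(r_to_causal, dtype=np.float64)
    if r.shape[0] != reject.shape[0]:
        raise ValueError("r_to_causal rows must match the number of SNPs")
    linked = np.abs(r) >= tau_ld              # (p, n_regions)
    linked_any = linked.any(axis=1)

    detected, valid = 0, 0
    for k in range(r.shape[1]):
        members = linked[:, k]
        if not members.any():
            warnings.warn(f"region {k} has no SNP with |r| >= {tau_ld}; "
                          f"excluded from the TPR denominator", stacklevel=2)
            continue
        valid += 1
        detected += bool(reject[members].any())
    tpr = detected / valid if valid else np.nan
    ltpr = float(reject[linked_any].mean()) if linked_any.any() else np.nan
    nulls = ~linked_any
    fpr = float(reject[nulls].mean()) if nulls.any() else np.nan
    return tpr, ltpr, fpr


# ---------------------------------------------------------------------------
# method registry
# ---------------------------------------------------------------------------

#: penalty shared across the CV-based resampling methods within a replicate
_CV_METHODS = {"rb", "mrb", "pt"}


def _run_method(name: str, params: dict, X, yc, alpha, seed, gram, cv_cache):
    def get_lam():
        lam = params.get("lam", "cv")
        if lam == "cv":
            if "lam" not in cv_cache:
                cv_cache["lam"] = cv_lambda(
                    X, yc, seed=cv_cache["seed"]).lambda_selected
            return cv_cache["lam"]
        return float(lam)

    if name == "sma":
        return sma.sma_decide(sma.sma_scan(X, yc), alpha)
    if name == "pl":
        return select_lambda.lasso_pl_test(
            X, yc, alpha, B=params.get("B", 100),
            aggregate=params.get("aggregate", "mean"), seed=seed,
            precompute=gram)
    if name == "ayers":
        return select_lambda.lasso_ayers_test(X, yc, alpha, seed=seed,
                                              precompute=gram)
    if name == "al":
        return select_lambda.lasso_al_test(X, yc, alpha,
                                           grid=params.get("grid"),
                                           precompute=gram)
    if name == "rb":
        dec, _ = resample.residual_bootstrap(
            X, yc, get_lam(), B=params.get("B", 1000), alpha=alpha,
            seed=seed, precompute=gram)
        return dec
    if name == "mrb":
        dec, _ = resample.modified_residual_bootstrap(
            X, yc, get_lam(), tau=params.get("tau", 0.001),
            B=params.get("B", 1000), alpha=alpha, seed=seed, precompute=gram)
        return dec
    if name == "pt":
        return resample.lasso_pt_test(X, yc, get_lam(),
                                      B=params.get("B", 999), alpha=alpha,
                                      seed=seed, precompute=gram)
    raise ValueError(f"unknown method {name!r}")


def _method_label(spec: dict) -> str:
    return spec.get("label", spec["method"])


# ---------------------------------------------------------------------------
# study harness
# ---------------------------------------------------------------------------


def run_simulation_study(scenario: ScenarioConfig, methods, n_reps: int,
                         alpha: float, seed: int = 0,
                         tau_ld: float = 0.3) -> MetricsReport:
    """Run every requested method on fresh replicate datasets and aggregate.

    ``methods`` is a sequence of dicts, each with a ``method`` key naming one
    of sma|pl|ayers|al|rb|mrb|pt plus method parameters (B, tau, lam, ...).
    Within a replicate all methods see the identical dataset, and the
    CV-selected penalty is computed once and shared by rb/mrb/pt.  A method
    failing on a replicate is recorded and excluded from its averages.
    Fully reproducible from (scenario, seed).
    """
    if n_reps < 1:
        raise ValueError(f"need n_reps >= 1, got {n_reps}")
    methods = [m if isinstance(m, dict) else {"method": m} for m in methods]
    region_mode = scenario.ld_mode == "block"
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_reps)

    rows = []
    failures: dict[str, list] = {}
    for rep, rep_ss in enumerate(rep_seeds):
        data_ss, *method_ss = rep_ss.spawn(len(methods) + 1)
        data_state = data_ss.generate_state(2)
        cfg = ScenarioConfig(**{**scenario.__dict__,
                                "seed": int(data_state[0] % 2**31)})
        G, pheno = make_scenario(cfg)
        X = G.values
        yc = pheno.values - pheno.values.mean()
        gram = GramCache(X) if X.shape[1] <= GRAM_MAX_P else None
        cv_cache: dict = {"seed": int(data_state[1] % 2**31)}
        for spec, m_ss in zip(methods, method_ss):
            label = _method_label(spec)
            try:
                dec = _run_method(spec["method"], spec, X, yc, alpha, m_ss,
                                  gram, cv_cache)
                if region_mode:
                    t, l, f = region_metrics(dec, G.r_to_causal, tau_ld)
                    rows.append({"rep": rep, "method": label, "tpr": t,
                                 "ltpr": l, "fpr": f})
                else:
                    t, f = tpr_fpr(dec, pheno.causal_idx)
                    rows.append({"rep": rep, "method": label, "tpr": t, "fpr": f})
            except Exception as err:  # noqa: BLE001 - recorded, not fatal
                failures.setdefault(label, []).append((rep, repr(err)))

    per_rep = pd.DataFrame(rows)
    rate_cols = [c for c in ("tpr", "ltpr", "fpr") if c in per_rep.columns]
    groups = per_rep.groupby("method", sort=False)
    summary = groups[rate_cols].mean()
    for c in rate_cols:
        summary[f"{c}_se"] = groups[c].std(ddof=1) / np.sqrt(groups[c].count())
    summary["n_ok"] = groups["rep"].count()
    summary = summary.reset_index()
    return MetricsReport(scenario=scenario.name or scenario.ld_mode,
                         n_reps=n_reps, alpha=alpha, summary=summary,
                         per_replicate=per_rep,
                         tau_ld=tau_ld if region_mode else None,
                         failures=failures)
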