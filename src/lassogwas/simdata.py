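"""Synthetic genotype/phenotype generation for the power and error studies.

Genotypes are additive minor-allele counts (0/1/2) for common variants
(MAF > 0.05).  Two correlation structures are supported:

* independent SNPs — each column Binomial(2, maf), Hardy–Weinberg marginals;
* LD blocks — a latent Gaussian one-factor copula per block, thresholded at
  the Hardy–Weinberg cut points so marginals stay Binomial(2, maf) while the
  realized genotype correlation with the block's anchor SNP hits a requested
  r^2 target.  The latent correlation needed for a given genotype r is found
  by inverting the exact thresholded-bivariate-normal moment with brentq.

The quantitative trait follows the linear model Y = X_causal beta + eps,
eps ~ N(0, sigma^2 I), applied to *standardized* genotypes.  Standardization
uses the population variance convention (divide by n) so that x_j'x_j/n = 1
exactly, which the penalty-scale arithmetic elsewhere relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats


class SimulationParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive-coded genotypes with MAF metadata."""

    values: np.ndarray
    mafs: np.ndarray
    standardized: bool = False
    snp_ids: list[str] = field(default_factory=list)
    ld_groups: np.ndarray | None = None
    #: (p, n_regions) signed sample correlation of each retained SNP with each
    #: latent causal SNP; populated by region-structured scenarios after the
    #: causal columns have been removed.
    r_to_causal: np.ndarray | None = None
    #: original 0/1/2 counts, retained through standardization so that a
    #: standardized matrix can still be written in genotype formats
    raw_values: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mafs = np.asarray(self.mafs, dtype=np.float64)
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(self.values.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeVector:
    """Quantitative trait with the generating truth attached."""

    values: np.ndarray
    causal_idx: np.ndarray
    causal_beta: np.ndarray
    sigma: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.causal_idx = np.asarray(self.causal_idx, dtype=np.intp)
        self.causal_beta = np.asarray(self.causal_beta, dtype=np.float64)


@dataclass
class LdBlock:
    """One causal region: an anchor SNP plus correlated neighbors.

    ``r2`` may be a scalar (every neighbor targets that r^2 with the anchor),
    a (lo, hi) tuple (targets drawn uniformly), or a sequence of length
    ``n_snps - 1`` with one target per neighbor.
    """

    n_snps: int
    r2: float | tuple | list = 0.2


@dataclass
class ScenarioConfig:
    """One replicate-generating configuration for the simulation studies."""

    n: int = 600
    n_causal: int = 5
    beta: float = 0.15
    sigma: float = 1.0
    p0: int = 0
    ld_mode: str = "independent"  # "independent" | "block"
    block_spec: list[LdBlock] | None = None
    seed: int = 0
    name: str = ""


# ---------------------------------------------------------------------------
# latent-correlation calibration for the LD-block copula
# ---------------------------------------------------------------------------

_INF = 12.0


def _hw_cuts(maf: float) -> tuple[float, float]:
    p0 = (1.0 - maf) ** 2
    p1 = 2.0 * maf * (1.0 - maf)
    return stats.norm.ppf(p0), stats.norm.ppf(p0 + p1)


def _bvn_cdf(x: float, y: float, rho: float) -> float:
    return float(stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([x, y]))


def _genotype_corr(rho: float, maf_a: float, maf_b: float) -> float:
    """Exact genotype correlation induced by latent correlation ``rho``."""
    ta1, ta2 = _hw_cuts(maf_a)
    tb1, tb2 = _hw_cuts(maf_b)

    def rect(x1, x2, y1, y2):
        return (_bvn_cdf(x2, y2, rho) - _bvn_cdf(x1, y2, rho)
                - _bvn_cdf(x2, y1, rho) + _bvn_cdf(x1, y1, rho))

    exy = 0.0
    for gi, (xa, xb) in ((1, (ta1, ta2)), (2, (ta2, _INF))):
        for gj, (ya, yb) in ((1, (tb1, tb2)), (2, (tb2, _INF))):
            exy += gi * gj * rect(xa, xb, ya, yb)
    va = 2.0 * maf_a * (1.0 - maf_a)
    vb = 2.0 * maf_b * (1.0 - maf_b)
    return (exy - 4.0 * maf_a * maf_b) / np.sqrt(va * vb)


@lru_cache(maxsize=4096)
def _latent_rho(target_r: float, maf_a: float, maf_b: float) -> float:
    """Latent Gaussian correlation giving genotype correlation ``target_r``."""
    if abs(target_r) < 1e-12:
        return 0.0
    hi = 0.999
    reach = _genotype_corr(np.sign(target_r) * hi, maf_a, maf_b)
    if abs(target_r) >= abs(reach):
        raise SimulationParameterError(
            f"target genotype r={target_r:.3f} unattainable for MAFs "
            f"({maf_a:.3f}, {maf_b:.3f}); max |r| ~ {abs(reach):.3f}")
    return float(optimize.brentq(
        lambda rho: _genotype_corr(rho, maf_a, maf_b) - target_r,
        -hi, hi, xtol=1e-4))


def _threshold_to_genotype(z: np.ndarray, maf: float) -> np.ndarray:
    t1, t2 = _hw_cuts(maf)
    return (z > t1).astype(np.float64) + (z > t2)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _check_mafs(mafs: np.ndarray):
    if np.any((mafs <= 0.0) | (mafs > 0.5)):
        bad = np.flatnonzero((mafs <= 0.0) | (mafs > 0.5))
        raise SimulationParameterError(
            f"MAFs must lie in (0, 0.5]; offending indices {bad.tolist()[:5]}")


def simulate_genotypes(n: int, mafs, ld_spec: list[LdBlock] | None = None,
                       seed: int = 0) -> GenotypeMatrix:
    """Draw an n x p additive genotype matrix.

    With ``ld_spec`` None every SNP is an independent Binomial(2, maf) draw.
    Otherwise the blocks occupy the leading columns in order (the first SNP
    of each block is its anchor) and any remaining columns are independent.
    """
    mafs = np.atleast_1d(np.asarray(mafs, dtype=np.float64))
    _check_mafs(mafs)
    if n < 2:
        raise SimulationParameterError(f"need n >= 2 subjects, got {n}")
    p = mafs.size
    rng = np.random.default_rng(seed)
    ld_groups = None

    if not ld_spec:
        values = rng.binomial(2, mafs, size=(n, p)).astype(np.float64)
    else:
        sizes = [b.n_snps for b in ld_spec]
        if sum(sizes) > p:
            raise SimulationParameterError(
                f"LD blocks need {sum(sizes)} SNPs but only {p} MAFs given")
        values = np.empty((n, p))
        ld_groups = np.full(p, -1, dtype=np.intp)
        col = 0
        for bi, block in enumerate(ld_spec):
            m = block.n_snps
            block_mafs = mafs[col:col + m]
            targets_r2 = _neighbor_r2_targets(block, rng)
            if np.any(targets_r2 > 0.99):
                raise SimulationParameterError(
                    f"block {bi}: target r^2 > 0.99 is unattainable")
            z0 = rng.standard_normal(n)
            values[:, col] = _threshold_to_genotype(z0, block_mafs[0])
            for k in range(1, m):
                r = float(np.sqrt(targets_r2[k - 1]))
                w = _latent_rho(round(r, 3), round(float(block_mafs[0]), 3),
                                round(float(block_mafs[k]), 3))
                z = w * z0 + np.sqrt(max(0.0, 1.0 - w * w)) * rng.standard_normal(n)
                values[:, col + k] = _threshold_to_genotype(z, block_mafs[k])
            ld_groups[col:col + m] = bi
            col += m
        if col < p:
            values[:, col:] = rng.binomial(2, mafs[col:], size=(n, p - col))

    return GenotypeMatrix(values=values, mafs=mafs, standardized=False,
                          ld_groups=ld_groups)


def _neighbor_r2_targets(block: LdBlock, rng) -> np.ndarray:
    k = block.n_snps - 1
    r2 = block.r2
    if np.isscalar(r2):
        return np.full(k, float(r2))
    if isinstance(r2, tuple):  # (lo, hi) range; lists/arrays are per-neighbor
        lo, hi = r2
        return rng.uniform(lo, hi, size=k)
    r2 = np.asarray(r2, dtype=np.float64)
    if r2.size != k:
        raise SimulationParameterError(
            f"per-neighbor r2 targets must have length {k}, got {r2.size}")
    return r2


def standardize(G: GenotypeMatrix) -> GenotypeMatrix:
    """Columnwise z-score with the population (1/n) variance denominator.

    Idempotent: an already-standardized matrix is returned unchanged.
    Raises on monomorphic columns, naming the offending SNP.
    """
    if G.standardized:
        return G
    X = G.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0 so that x_j'x_j / n == 1 afterwards
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise SimulationParameterError(
            f"monomorphic SNP(s) cannot be standardized: "
            f"{[G.snp_ids[j] for j in dead[:5]]}")
    Z = (X - mu) / sd
    return GenotypeMatrix(values=Z, mafs=G.mafs, standardized=True,
                          snp_ids=list(G.snp_ids), ld_groups=G.ld_groups,
                          r_to_causal=G.r_to_causal, raw_values=X)


def simulate_phenotype(G: GenotypeMatrix, causal_idx, beta, sigma: float = 1.0,
                       seed: int = 0) -> PhenotypeVector:
    """Y = X_causal beta + N(0, sigma^2 I) on the standardized genotype scale."""
    if not G.standardized:
        raise SimulationParameterError(
            "phenotype simulation requires standardized genotypes")
    causal_idx = np.atleast_1d(np.asarray(causal_idx, dtype=np.intp))
    beta = np.broadcast_to(np.atleast_1d(np.asarray(beta, dtype=np.float64)),
                           causal_idx.shape).copy()
    if causal_idx.size and causal_idx.max(initial=-1) >= G.n_snps:
        raise SimulationParameterError("causal index out of range")
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, sigma, size=G.n_subjects)
    if causal_idx.size:
        y = y + G.values[:, causal_idx] @ beta
    return PhenotypeVector(values=y, causal_idx=causal_idx, causal_beta=beta,
                           sigma=float(sigma))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def make_scenario(config: ScenarioConfig) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Generate one replicate dataset for a configured study scenario.

    Independent mode: ``n_causal + p0`` independent SNPs, the leading
    ``n_causal`` carrying effect ``beta`` each.  Block mode: each block's
    anchor is a latent causal SNP; after the phenotype is generated the anchor
    columns are *removed* and the signed sample correlation of every retained
    SNP with every latent causal SNP is recorded for region-level scoring.
    """
    rng = np.random.default_rng(config.seed)
    # sub-seeds below 2^31 for the constituent generators
    geno_seed, pheno_seed = rng.integers(0, 2**31 - 1, size=2)

    if config.ld_mode == "independent":
        p = config.n_causal + config.p0
        mafs = rng.uniform(0.05, 0.5, size=p)
        G = simulate_genotypes(config.n, mafs, seed=int(geno_seed))
        G = standardize(G)
        causal = np.arange(config.n_causal)
        pheno = simulate_phenotype(G, causal, config.beta, config.sigma,
                                   seed=int(pheno_seed))
        return G, pheno

    if config.ld_mode != "block":
        raise SimulationParameterError(f"unknown ld_mode {config.ld_mode!r}")

    blocks = config.block_spec
    if blocks is None:
        blocks = [LdBlock(n_snps=11, r2=(0.05, 0.6)) for _ in range(config.n_causal)]
    n_block_snps = sum(b.n_snps for b in blocks)
    p_total = n_block_snps + config.p0
    # SNPs in strong LD share similar allele frequencies; drawing neighbor
    # MAFs near the anchor's keeps the requested r^2 attainable (the maximal
    # genotype correlation shrinks as the MAFs separate)
    block_mafs = []
    for b in blocks:
        anchor_maf = rng.uniform(0.1, 0.5)
        neigh = np.clip(anchor_maf * np.exp(rng.uniform(-0.15, 0.15,
                                                        b.n_snps - 1)),
                        0.06, 0.5)
        block_mafs.append(np.concatenate([[anchor_maf], neigh]))
    mafs = np.concatenate(block_mafs + [rng.uniform(0.05, 0.5, config.p0)])
    G_raw = simulate_genotypes(config.n, mafs, ld_spec=blocks, seed=int(geno_seed))
    G = standardize(G_raw)

    anchors = np.cumsum([0] + [b.n_snps for b in blocks[:-1]])
    pheno = simulate_phenotype(G, anchors, config.beta, config.sigma,
                               seed=int(pheno_seed))

    # signed r of every SNP with each latent causal SNP, then drop the anchors
    Z = G.values
    n = config.n
    r_all = Z.T @ Z[:, anchors] / n  # columns are unit-variance, mean 0
    keep = np.setdiff1d(np.arange(p_total), anchors)
    G_out = GenotypeMatrix(
        values=Z[:, keep], mafs=G.mafs[keep], standardized=True,
        snp_ids=[G.snp_ids[j] for j in keep],
        ld_groups=None if G.ld_groups is None else G.ld_groups[keep],
        r_to_causal=r_all[keep, :],
        raw_values=None if G.raw_values is None else G.raw_values[:, keep])
    truth = PhenotypeVector(values=pheno.values, causal_idx=np.array([], dtype=np.intp),
                            causal_beta=np.array([]), sigma=config.sigma)
    return G_out, truth


#: named presets matching the two simulation studies
SCENARIO_PRESETS = {
    "sim1-p00": dict(p0=0),
    "sim1-p045": dict(p0=45),
    "sim1-p0300": dict(p0=300),
    "sim1-p0900": dict(p0=900),
    "sim1-p020000": dict(p0=20000),
    "sim2": dict(ld_mode="block", p0=950),
}


def scenario_preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named study conditions: n=600, 5 causal SNPs, beta=0.15, sigma=1."""
    if name not in SCENARIO_PRESETS:
        raise SimulationParameterError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIO_PRESETS)}")
    return ScenarioConfig(seed=seed, name=name, **SCENARIO_PRESETS[name])
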