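"""Synthetic GAW17-Q1-like cohorts: Hardy-Weinberg genotypes, additive trait.

The generator emulates the statistical structure the selection pipeline
assumes: a fixed genotype matrix of unrelated individuals (each SNP an
independent Binomial(2, MAF) draw, optionally correlated inside LD
blocks via a Gaussian copula), non-genetic covariates Sex/Age/Smoke, and
phenotype replicates y_r = sum_j beta_j G_j + gamma' Z + eps_r with fresh
Gaussian noise per replicate over the same genotypes and covariates.

The default causal table is the seven common variants (MAF > 0.01) of
the GAW17 Q1 simulating model, with their published MAFs and additive
effect sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import brentq

from snplasso.core_data import GenotypeMatrix, PhenotypeReplicates, SnpInfo

_REGENERATE_LIMIT = 100


@dataclass(frozen=True)
class CausalSnpSpec:
    """One causal SNP: identity, MAF used for genotype draws, additive effect."""

    snp_id: str
    gene: str
    maf: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"causal MAF must be in (0, 0.5], got {self.maf}")

    @property
    def chromosome(self) -> str:
        # ids follow the C<chrom>S<index> convention
        if self.snp_id.startswith("C") and "S" in self.snp_id:
            return self.snp_id[1:].split("S", 1)[0]
        return ""

    @property
    def variance_explained(self) -> float:
        """Additive trait variance beta^2 * 2 p (1-p) under Hardy-Weinberg."""
        return self.beta**2 * 2.0 * self.maf * (1.0 - self.maf)


#: The seven common (MAF > 0.01) causal SNPs of the GAW17 Q1 model.
TABLE1_CAUSAL_SNPS: tuple[CausalSnpSpec, ...] = (
    CausalSnpSpec("C1S6533", "ARNT", 0.011478, 0.56190),
    CausalSnpSpec("C13S431", "FLT1", 0.017217, 0.74136),
    CausalSnpSpec("C13S522", "FLT1", 0.027977, 0.61830),
    CausalSnpSpec("C13S523", "FLT1", 0.066714, 0.64997),
    CausalSnpSpec("C14S1734", "HIF1A", 0.012195, 0.21203),
    CausalSnpSpec("C4S1878", "KDR", 0.164993, 0.13573),
    CausalSnpSpec("C4S1884", "KDR", 0.020803, 0.29558),
)


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort.

    Defaults mirror the emulated data set: 697 unrelated individuals and
    a post-filter panel of 6,321 common SNPs (7 causal + 6,314 null).
    Null MAFs are uniform on [0.01, 0.5] (``null_maf_law="uniform"``) or
    rare-skewed Beta(0.5, 3) truncated to the same range
    (``null_maf_law="beta_rare"``).  Covariate effects default to zero:
    Sex/Age/Smoke are adjustment terms, not signal.
    """

    n_individuals: int = 697
    n_null_snps: int = 6314
    causal_table: tuple[CausalSnpSpec, ...] = TABLE1_CAUSAL_SNPS
    null_maf_law: str = "uniform"
    null_maf_range: tuple[float, float] = (0.01, 0.5)
    covariate_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    residual_sd: float = 1.0
    n_replicates: int = 1
    ld_blocks: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.n_null_snps < 0:
            raise ValueError("n_null_snps must be nonnegative")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        self.causal_table = tuple(self.causal_table)
        self.ld_blocks = tuple(tuple(b) for b in self.ld_blocks)
        if sum(b[0] for b in self.ld_blocks) > self.n_null_snps:
            raise ValueError("ld_blocks exceed the number of null SNPs")

    @property
    def n_snps(self) -> int:
        return self.n_null_snps + len(self.causal_table)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["causal_table"] = [dataclasses.asdict(c) for c in self.causal_table]
        d["ld_blocks"] = [list(b) for b in self.ld_blocks]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["causal_table"] = tuple(CausalSnpSpec(**c) for c in d["causal_table"])
        d["ld_blocks"] = tuple(tuple(b) for b in d.get("ld_blocks", ()))
        d["covariate_effects"] = tuple(d["covariate_effects"])
        d["null_maf_range"] = tuple(d["null_maf_range"])
        return cls(**d)


def truth_set(cfg: SimConfig) -> set[str]:
    """Ids of the causal SNPs — the ground truth selections are scored against."""
    return {c.snp_id for c in cfg.causal_table}


def _null_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.null_maf_range
    if cfg.null_maf_law == "uniform":
        return rng.uniform(lo, hi, size=cfg.n_null_snps)
    if cfg.null_maf_law == "beta_rare":
        # rare-heavy spectrum: Beta(0.5, 3) rescaled into [lo, hi]
        return lo + (hi - lo) * rng.beta(0.5, 3.0, size=cfg.n_null_snps)
    raise ValueError(f"unknown null_maf_law {cfg.null_maf_law!r}")


def _draw_column(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    """Binomial(2, maf) dosages, redrawn if monomorphic (panel is post-filter)."""
    for _ in range(_REGENERATE_LIMIT):
        col = rng.binomial(2, maf, size=n)
        if col.min() != col.max():
            return col
    raise RuntimeError(f"could not draw a polymorphic column at maf={maf}")


def _latent_rho(maf: float, target_r: float) -> float:
    """Latent haplotype correlation giving dosage correlation ``target_r``.

    Dosage correlation between two SNPs of equal MAF equals the allele-
    indicator correlation (P11 - p^2) / (p(1-p)) where P11 is the
    bivariate-normal orthant probability below the shared threshold.
    Solved by bisection; exact at the limits 0 and 1.
    """
    if target_r >= 1.0:
        return 1.0
    if target_r <= 0.0:
        return 0.0
    t = stats.norm.ppf(maf)
    pq = maf * (1.0 - maf)

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ).cdf([t, t])
        return (p11 - maf**2) / pq - target_r

    return brentq(gap, 1e-9, 1.0 - 1e-9, xtol=1e-10)


def _draw_ld_block(
    rng: np.random.Generator, n: int, maf: float, size: int, target_r: float
) -> np.ndarray:
    """Block of ``size`` SNPs at equal MAF with pairwise dosage correlation target.

    Gaussian copula per haplotype: z_j = sqrt(rho) u + sqrt(1-rho) e_j,
    allele = 1{z_j < Phi^{-1}(maf)}, dosage = sum of two haplotypes.
    target_r = 1 yields bit-identical columns.
    """
    rho = _latent_rho(maf, target_r)
    t = stats.norm.ppf(maf)
    dos = np.zeros((n, size), dtype=np.int8)
    for _hap in range(2):
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, size))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        dos += (z < t).astype(np.int8)
    return dos


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw the fixed genotype matrix: causal SNPs first, then null SNPs.

    Every column is Binomial(2, MAF) per individual (Hardy-Weinberg,
    independent individuals); null SNPs assigned to an LD block are drawn
    from a shared latent Gaussian instead.  Monomorphic draws are retried
    up to a limit so the panel stays polymorphic.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_individuals

    cols: list[np.ndarray] = []
    snps: list[SnpInfo] = []
    for spec in cfg.causal_table:
        cols.append(_draw_column(rng, n, spec.maf))
        snps.append(
            SnpInfo(
                snp_id=spec.snp_id,
                chromosome=spec.chromosome,
                gene=spec.gene,
                maf_declared=spec.maf,
            )
        )

    mafs = _null_mafs(cfg, rng)
    next_null = 0

    def null_info(j: int, maf: float) -> SnpInfo:
        return SnpInfo(
            snp_id=f"N{j + 1:05d}",
            chromosome=str(j % 22 + 1),
            maf_declared=round(float(maf), 6),
        )

    for size, target_r in cfg.ld_blocks:
        maf = float(mafs[next_null])  # block shares its first member's MAF
        block = _draw_ld_block(rng, n, maf, size, target_r)
        for k in range(size):
            while block[:, k].min() == block[:, k].max():
                block[:, k] = _draw_column(rng, n, maf)
            cols.append(block[:, k])
            snps.append(null_info(next_null + k, maf))
        next_null += size

    for j in range(next_null, cfg.n_null_snps):
        cols.append(_draw_column(rng, n, float(mafs[j])))
        snps.append(null_info(j, float(mafs[j])))

    dosages = (
        np.column_stack(cols).astype(np.int8)
        if cols
        else np.zeros((n, 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=[f"ind{i + 1:04d}" for i in range(n)], snps=snps, dosages=dosages)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig) -> PhenotypeReplicates:
    """Covariates drawn once; each replicate adds fresh Gaussian noise.

    Sex ~ Bernoulli(0.5), Age ~ Normal(50, 10) rounded to integer years,
    Smoke ~ Bernoulli(0.3).  Trait per replicate:
    y_r = sum_j beta_j G_j + gamma_sex Sex + gamma_age Age + gamma_smoke Smoke + eps_r,
    eps_r iid Normal(0, residual_sd^2), independent across replicates.
    """
    missing = truth_set(cfg) - set(g.snp_ids)
    if missing:
        raise ValueError(f"causal SNPs absent from genotype matrix: {sorted(missing)}")

    n = g.n_samples
    rng_cov = np.random.default_rng([cfg.seed, 2])
    sex = rng_cov.binomial(1, 0.5, size=n).astype(float)
    age = np.round(rng_cov.normal(50.0, 10.0, size=n))
    smoke = rng_cov.binomial(1, 0.3, size=n).astype(float)
    covariates = np.column_stack([sex, age, smoke])

    idx = {sid: j for j, sid in enumerate(g.snp_ids)}
    genetic = np.zeros(n)
    for spec in cfg.causal_table:
        genetic += spec.beta * g.dosages[:, idx[spec.snp_id]].astype(float)
    fixed = genetic + covariates @ np.asarray(cfg.covariate_effects, dtype=float)

    traits = {}
    for r in range(1, cfg.n_replicates + 1):
        rng_r = np.random.default_rng([cfg.seed, 3, r])
        traits[f"rep{r}"] = fixed + rng_r.normal(0.0, cfg.residual_sd, size=n)

    return PhenotypeReplicates(samples=list(g.samples), covariates=covariates, traits=traits)
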