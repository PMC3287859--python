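"""Canned study scenarios used by the analysis scripts and validation runs.

The *scaled-down replicate experiment* is the package's desk-scale analog
of the 200-replicate benchmark: the same cohort size (697 individuals)
and the same seven causal common variants, but a 2,000-SNP null panel
and 20 phenotype replicates, so the whole six-procedure pipeline runs in
minutes on one core while preserving the qualitative structure of the
benchmark (near-certain selection of the strongest signal, near-never
selection of the weakest, parsimony ordering BIC <= AIC <= LASSO).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from snplasso._seeds import derive_seed
from snplasso.core_data import GenotypeMatrix, PhenotypeReplicates, SelectionReport
from snplasso.evaluate import EvalConfig, ReplicateRun, run_replicates, selection_summary
from snplasso.simulate import SimConfig, simulate_genotypes, simulate_phenotypes, truth_set

#: Conditions of the scaled-down replicate experiment.
SCALED_DOWN_N_NULL = 2000
SCALED_DOWN_N_REPLICATES = 20


@dataclass
class ExperimentResult:
    config: SimConfig
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeReplicates
    truth: set[str]
    runs: list[ReplicateRun]
    reports: dict[str, SelectionReport] = field(default_factory=dict)


def scaled_down_experiment(
    seed: int,
    n_null_snps: int = SCALED_DOWN_N_NULL,
    n_replicates: int = SCALED_DOWN_N_REPLICATES,
    rules: tuple[str, ...] = ("min",),
    criteria: tuple[str, ...] = ("AIC", "BIC"),
    k_folds: int = 10,
) -> ExperimentResult:
    """Run the scaled-down replicate experiment end to end.

    One genotype draw (697 individuals, the seven causal common variants
    at their published MAFs/effects plus ``n_null_snps`` null SNPs with
    MAF ~ Uniform(0.01, 0.5)), ``n_replicates`` phenotype replicates at
    residual sd 1.0 with zero covariate effects; per replicate a 10-fold
    CV chooses the penalty and the requested procedure variants run.
    All randomness derives from ``seed``.
    """
    cfg = SimConfig(
        n_null_snps=n_null_snps,
        n_replicates=n_replicates,
        seed=derive_seed(seed, "simulate"),
    )
    g = simulate_genotypes(cfg)
    p = simulate_phenotypes(g, cfg)
    truth = truth_set(cfg)
    runs = run_replicates(
        g,
        p,
        EvalConfig(
            k_folds=k_folds,
            rules=rules,
            criteria=criteria,
            seed=derive_seed(seed, "evaluate"),
        ),
    )
    return ExperimentResult(
        config=cfg,
        genotypes=g,
        phenotypes=p,
        truth=truth,
        runs=runs,
        reports=selection_summary(runs, truth),
    )
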