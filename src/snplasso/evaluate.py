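"""Replicate-level evaluation: selection frequencies, proportions, ranks.

The six procedure variants are the stage-1 LASSO at lambda_min and at
lambda_1se, each alone and followed by stepwise refinement under AIC or
BIC.  Running them over many phenotype replicates of the same genotypes
yields per-SNP selection frequencies, the mean numbers of selected and
correctly selected SNPs, and the proportion correct — the headline
comparison between the procedure variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snplasso.core_data import GenotypeMatrix, PhenotypeReplicates, SelectionReport
from snplasso.lasso import cross_validate, select_at
from snplasso.preprocess import standardize
from snplasso.stepwise import refine_selection
from snplasso._seeds import derive_seed

logger = logging.getLogger(__name__)

PROCEDURES = (
    "lasso_min",
    "lasso_min+AIC",
    "lasso_min+BIC",
    "lasso_1se",
    "lasso_1se+AIC",
    "lasso_1se+BIC",
)


@dataclass
class EvalConfig:
    """Knobs of the replicate experiment.

    ``lambda_mode='per_replicate'`` re-runs CV on every replicate (the
    self-contained default); ``'fixed'`` runs (repeated) CV once on
    ``fixed_lambda_replicate`` and reuses its penalties everywhere.
    ``rules``/``criteria`` restrict the procedure variants computed.
    """

    k_folds: int = 10
    cv_repeats: int = 1
    lambda_mode: str = "per_replicate"
    fixed_lambda_replicate: str | None = None
    rules: tuple[str, ...] = ("min", "1se")
    criteria: tuple[str, ...] = ("AIC", "BIC")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_mode not in ("per_replicate", "fixed"):
            raise ValueError("lambda_mode must be 'per_replicate' or 'fixed'")
        bad = set(self.rules) - {"min", "1se"}
        if bad:
            raise ValueError(f"unknown lambda rules: {sorted(bad)}")
        bad = set(self.criteria) - {"AIC", "BIC"}
        if bad:
            raise ValueError(f"unknown criteria: {sorted(bad)}")


@dataclass
class ReplicateRun:
    """Selections of every procedure variant on one phenotype replicate."""

    replicate_id: str
    selections: dict[str, set[str]]
    lambda_min: float
    lambda_1se: float
    seed: int


def _drop_constant_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    keep = g.dosages.std(axis=0) > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} monomorphic SNP column(s) before fitting")
        g = g.subset_snps(keep)
    return g


def run_replicates(
    g: GenotypeMatrix,
    p: PhenotypeReplicates,
    config: EvalConfig | None = None,
    replicate_ids: list[str] | None = None,
) -> list[ReplicateRun]:
    """Run the requested procedure variants on each phenotype replicate.

    Per replicate (default mode): 10-fold CV fixes lambda_min/lambda_1se,
    the LASSO is refit on the full replicate at each rule's penalty, and
    each stepwise criterion refines each stage-1 set.  Fold assignment
    seeds derive deterministically from ``config.seed`` and the replicate
    id, so a run is reproducible regardless of execution order.  Failing
    replicates are logged and excluded (never zero-filled).
    """
    config = config or EvalConfig()
    replicate_ids = replicate_ids or p.replicate_ids
    if not replicate_ids:
        raise ValueError("no phenotype replicates to run")
    g = _drop_constant_snps(g)

    fixed_cv = None
    if config.lambda_mode == "fixed":
        rid0 = config.fixed_lambda_replicate or replicate_ids[0]
        d0 = standardize(g, p, rid0)
        fixed_cv = cross_validate(
            d0,
            K=config.k_folds,
            n_repeats=config.cv_repeats,
            seed=derive_seed(config.seed, "cv", rid0),
        )

    runs: list[ReplicateRun] = []
    for rid in replicate_ids:
        try:
            runs.append(_run_one(g, p, rid, config, fixed_cv))
        except Exception:
            logger.exception("replicate %s failed; excluded from summaries", rid)
    if not runs:
        raise RuntimeError("every replicate failed")
    return runs


def _run_one(g, p, rid, config: EvalConfig, fixed_cv) -> ReplicateRun:
    d = standardize(g, p, rid)
    rep_seed = derive_seed(config.seed, "cv", rid)
    cv = fixed_cv or cross_validate(
        d, K=config.k_folds, n_repeats=config.cv_repeats, seed=rep_seed
    )
    lam = {"min": cv.lambda_min, "1se": cv.lambda_1se}
    selections: dict[str, set[str]] = {}
    for rule in config.rules:
        stage1 = select_at(d, lam[rule])
        selections[f"lasso_{rule}"] = stage1
        for crit in config.criteria:
            if stage1:
                refined = refine_selection(d, stage1, crit).included_set - set(
                    d.covariate_names
                )
            else:
                refined = set()
            selections[f"lasso_{rule}+{crit}"] = refined
    return ReplicateRun(
        replicate_id=rid,
        selections=selections,
        lambda_min=cv.lambda_min,
        lambda_1se=cv.lambda_1se,
        seed=rep_seed,
    )


def selection_summary(
    runs: list[ReplicateRun], truth: set[str] | None = None
) -> dict[str, SelectionReport]:
    """One SelectionReport per procedure variant present in the runs."""
    if not runs:
        raise ValueError("no runs to summarize")
    procedures = [pr for pr in PROCEDURES if pr in runs[0].selections]
    return {
        pr: SelectionReport(
            procedure=pr,
            selections={r.replicate_id: set(r.selections[pr]) for r in runs},
            truth=set(truth) if truth is not None else None,
        )
        for pr in procedures
    }


def proportion_correct(report: SelectionReport) -> float:
    """Mean total correct / mean total selected, as a fraction in [0, 1]."""
    sel = report.mean_total_selected
    if sel <= 0:
        raise ZeroDivisionError(
            f"procedure {report.procedure}: nothing selected, proportion undefined"
        )
    return report.mean_total_correct / sel


def selection_ranks(
    report: SelectionReport, truth: set[str] | None = None
) -> pd.DataFrame:
    """Rank every ever-selected SNP by descending selection frequency.

    Ties share the minimum rank (then id order in the listing).  With a
    truth set the table flags which ranked SNPs are causal.
    """
    counts = report.snp_counts
    if not counts:
        raise ValueError("empty report: no SNP was ever selected")
    n_rep = report.n_replicates
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    freqs = np.array([c for _, c in items], dtype=float) / n_rep
    # minimum-rank ("1224") convention for ties
    ranks = np.empty(len(items), dtype=int)
    for i in range(len(items)):
        ranks[i] = 1 + int(np.sum(freqs > freqs[i]))
    df = pd.DataFrame(
        {
            "snp_id": [s for s, _ in items],
            "frequency": freqs,
            "rank": ranks,
        }
    )
    if truth is not None:
        df["is_truth"] = df["snp_id"].isin(sorted(truth))
    return df


def summary_table(
    reports: dict[str, SelectionReport], truth: set[str]
) -> pd.DataFrame:
    """Benchmark-style table: per-causal-SNP frequencies and the totals row."""
    rows = {}
    for sid in sorted(truth):
        rows[sid] = {pr: rep.snp_frequency(sid) for pr, rep in reports.items()}
    rows["Total correct"] = {
        pr: rep.mean_total_correct for pr, rep in reports.items()
    }
    rows["Total selected"] = {
        pr: rep.mean_total_selected for pr, rep in reports.items()
    }
    return pd.DataFrame(rows).T
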