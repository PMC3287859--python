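"""End-to-end orchestration: simulate/load -> preprocess -> select -> report.

Every stage writes delimited-text outputs under one output directory and
the run closes with a JSON manifest recording the configuration, derived
seeds, and per-stage row/SNP counts, so a run can be audited and
reproduced exactly from its directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from snplasso._version import __version__
from snplasso._seeds import derive_seed
from snplasso.bagging import bag_lasso, rmip_report
from snplasso.core_data import (
    align_samples,
    read_genotypes,
    read_phenotypes,
    write_genotypes,
    write_phenotypes,
)
from snplasso.evaluate import (
    EvalConfig,
    proportion_correct,
    run_replicates,
    selection_ranks,
    selection_summary,
    summary_table,
)
from snplasso.preprocess import collapse_duplicates, filter_by_maf
from snplasso.simulate import SimConfig, simulate_genotypes, simulate_phenotypes, truth_set

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    genotype_dialect: str = "delimited"
    truth_path: str | None = None
    maf_threshold: float = 0.01
    collapse: bool = True
    k_folds: int = 10
    cv_repeats: int = 1
    rules: tuple[str, ...] = ("min", "1se")
    criteria: tuple[str, ...] = ("AIC", "BIC")
    bagging_B: int | None = 100
    bagging_rule: str = "min"
    seed: int = 0
    out_dir: str = "results/run"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["causal_table"] = [
                dataclasses.asdict(c) for c in self.sim.causal_table
            ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            sim = d["sim"]
            from snplasso.simulate import CausalSnpSpec

            sim["causal_table"] = tuple(
                CausalSnpSpec(**c) for c in sim["causal_table"]
            )
            sim["ld_blocks"] = tuple(tuple(b) for b in sim.get("ld_blocks", ()))
            sim["covariate_effects"] = tuple(sim["covariate_effects"])
            sim["null_maf_range"] = tuple(sim["null_maf_range"])
            d["sim"] = SimConfig(**sim)
        for key in ("rules", "criteria"):
            d[key] = tuple(d[key])
        return cls(**d)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
        "status": "running",
    }

    def checkpoint() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        # ---- input stage: simulate or load -------------------------------
        if cfg.sim is not None:
            sim = dataclasses.replace(cfg.sim, seed=derive_seed(cfg.seed, "simulate"))
            g = simulate_genotypes(sim)
            p = simulate_phenotypes(g, sim)
            truth = truth_set(sim)
            write_genotypes(g, out / "genotypes.tsv")
            write_phenotypes(p, out / "phenotypes.tsv")
            (out / "truth_snps.txt").write_text("".join(s + "\n" for s in sorted(truth)))
            manifest["stages"]["simulate"] = {
                "seed": sim.seed,
                "n_samples": g.n_samples,
                "n_snps": g.n_snps,
                "n_replicates": len(p.traits),
                "n_truth": len(truth),
            }
        else:
            if cfg.genotype_path is None or cfg.phenotype_path is None:
                raise ValueError("need either a SimConfig or genotype+phenotype paths")
            g = read_genotypes(cfg.genotype_path, cfg.genotype_dialect)
            p = read_phenotypes(cfg.phenotype_path)
            g, p = align_samples(g, p)
            truth = None
            if cfg.truth_path:
                truth = {
                    line.strip()
                    for line in Path(cfg.truth_path).read_text().splitlines()
                    if line.strip()
                }
            manifest["stages"]["load"] = {
                "n_samples": g.n_samples,
                "n_snps": g.n_snps,
                "n_replicates": len(p.traits),
            }
        checkpoint()

        # ---- preprocess --------------------------------------------------
        n_before = g.n_snps
        g = filter_by_maf(g, cfg.maf_threshold)
        n_after_maf = g.n_snps
        groups = {}
        if cfg.collapse:
            g, groups = collapse_duplicates(g)
        if groups:
            pd.DataFrame(
                [
                    {"representative": rep, "members": ",".join(mem)}
                    for rep, mem in groups.items()
                ]
            ).to_csv(out / "duplicate_groups.tsv", sep="\t", index=False)
        manifest["stages"]["preprocess"] = {
            "n_snps_in": n_before,
            "n_snps_after_maf": n_after_maf,
            "n_snps_out": g.n_snps,
            "n_duplicate_groups": len(groups),
        }
        checkpoint()

        # ---- replicate selection experiment ------------------------------
        eval_cfg = EvalConfig(
            k_folds=cfg.k_folds,
            cv_repeats=cfg.cv_repeats,
            rules=cfg.rules,
            criteria=cfg.criteria,
            seed=derive_seed(cfg.seed, "evaluate"),
        )
        runs = run_replicates(g, p, eval_cfg)
        reports = selection_summary(runs, truth)
        pd.DataFrame(
            [
                {
                    "replicate": r.replicate_id,
                    "lambda_min": r.lambda_min,
                    "lambda_1se": r.lambda_1se,
                    **{
                        pr: ";".join(sorted(sel))
                        for pr, sel in r.selections.items()
                    },
                }
                for r in runs
            ]
        ).to_csv(out / "selections.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        summary: dict = {
            pr: {
                "mean_total_selected": rep.mean_total_selected,
            }
            for pr, rep in reports.items()
        }
        if truth is not None:
            for pr, rep in reports.items():
                summary[pr]["mean_total_correct"] = rep.mean_total_correct
                if rep.mean_total_selected > 0:
                    summary[pr]["proportion_correct"] = proportion_correct(rep)
            summary_table(reports, truth).to_csv(
                out / "selection_frequencies.tsv", sep="\t", float_format=_FLOAT_FMT
            )
            ranks = selection_ranks(reports[next(iter(reports))], truth)
            ranks.to_csv(out / "selection_ranks.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
        manifest["stages"]["evaluate"] = {
            "n_replicates_run": len(runs),
            "n_snps_in": g.n_snps,
            "procedures": summary,
            "lambda_min_per_replicate": [r.lambda_min for r in runs],
            "lambda_1se_per_replicate": [r.lambda_1se for r in runs],
        }
        checkpoint()

        # ---- bagging (optional) ------------------------------------------
        if cfg.bagging_B:
            rid = p.replicate_ids[0]
            lam = runs[0].lambda_min if cfg.bagging_rule == "min" else runs[0].lambda_1se
            table = bag_lasso(
                g, p, rid, lam, B=cfg.bagging_B, seed=derive_seed(cfg.seed, "bag")
            )
            report = rmip_report(table, truth)
            report.to_csv(out / "rmip.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            manifest["stages"]["bagging"] = {
                "lambda_used": lam,
                "B": cfg.bagging_B,
                "n_nonzero_rmip": report.attrs["n_nonzero"],
                **(
                    {
                        "n_true_above_0.5": report.attrs["n_true_above"],
                        "n_spurious_above_0.5": report.attrs["n_spurious_above"],
                    }
                    if truth is not None
                    else {}
                ),
            }
        else:
            manifest["stages"]["bagging"] = {"skipped": True}
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        checkpoint()
        raise
    checkpoint()
    cfg.to_yaml(out / "config.yaml")
    return out
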