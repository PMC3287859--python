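"""Simulate the synthetic GAW17-Q1-like cohort used by the later steps.

697 unrelated individuals; the seven causal common variants at their
published MAFs and additive effects; 2,000 null SNPs with MAF uniform on
[0.01, 0.5]; covariates Sex/Age/Smoke with zero effects; 20 phenotype
replicates with unit residual noise.  Writes the genotype, phenotype,
and truth-set files under results/data/.
"""

from pathlib import Path

from snplasso import (
    SimConfig,
    simulate_genotypes,
    simulate_phenotypes,
    truth_set,
    write_genotypes,
    write_phenotypes,
)

OUT = Path("scratch/data")
SEED = 1

cfg = SimConfig(n_null_snps=2000, n_replicates=20, seed=SEED)
g = simulate_genotypes(cfg)
p = simulate_phenotypes(g, cfg)

OUT.mkdir(parents=True, exist_ok=True)
write_genotypes(g, OUT / "genotypes.tsv")
write_phenotypes(p, OUT / "phenotypes.tsv")
(OUT / "truth_snps.txt").write_text("".join(s + "\n" for s in sorted(truth_set(cfg))))
cfg.to_yaml(OUT / "sim_config.yaml")

print(f"cohort: {g.n_samples} individuals x {g.n_snps} SNPs, "
      f"{len(p.traits)} phenotype replicates -> {OUT}")
print(f"truth set ({len(truth_set(cfg))} SNPs): {sorted(truth_set(cfg))}")
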