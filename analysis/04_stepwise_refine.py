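"""Stage 2 on replicate 1: bidirectional stepwise refinement under AIC and BIC.

Starts from the full stage-1 model (lambda_min selection plus the three
covariates) and greedily applies the best single-term deletion or
re-addition until neither criterion improves.  Writes the refined models
and their search traces.
"""

from pathlib import Path

import pandas as pd

from snplasso import align_samples, read_genotypes, read_phenotypes, standardize
from snplasso.stepwise import refine_selection

DATA = Path("scratch/data")
OUT = Path("results")

g, p = align_samples(read_genotypes(DATA / "genotypes.tsv"), read_phenotypes(DATA / "phenotypes.tsv"))
d = standardize(g, p, "rep1")
stage1 = set(pd.read_csv(OUT / "stage1_selected_min.tsv", sep="\t")["snp_id"])
truth = set((DATA / "truth_snps.txt").read_text().split())
print(f"stage-1 pool: {len(stage1)} SNPs ({len(stage1 & truth)} causal) + Sex/Age/Smoke")

for criterion in ("AIC", "BIC"):
    res = refine_selection(d, stage1, criterion)
    kept = res.included_set - {"Sex", "Age", "Smoke"}
    pd.DataFrame({"term": res.included_terms}).to_csv(
        OUT / f"stage2_{criterion.lower()}.tsv", sep="\t", index=False
    )
    pd.DataFrame(res.trace, columns=["move", "term", "criterion"]).to_csv(
        OUT / f"stage2_{criterion.lower()}_trace.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    print(f"{criterion}: {len(kept)} SNPs kept ({len(kept & truth)} causal), "
          f"{len(res.trace) - 1} moves, final criterion {res.final_criterion:.2f}")
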