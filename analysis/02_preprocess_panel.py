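"""Preprocess the simulated panel: MAF filter, duplicate collapse, LD screen.

Mirrors the benchmark preprocessing (drop SNPs with folded MAF < 0.01,
keep one representative per group of identical columns) and screens the
causal SNPs for their strongest LD partner — a causal SNP in high LD
with a null SNP can be replaced by it in the selected model.
"""

from pathlib import Path

from snplasso import collapse_duplicates, filter_by_maf, ld_screen, read_genotypes

DATA = Path("scratch/data")
OUT = Path("results")

g = read_genotypes(DATA / "genotypes.tsv")
truth = (DATA / "truth_snps.txt").read_text().split()

n0 = g.n_snps
g = filter_by_maf(g, 0.01)
print(f"MAF >= 0.01: kept {g.n_snps} of {n0} SNPs")

g, groups = collapse_duplicates(g)
print(f"duplicate collapse: kept {g.n_snps} ({len(groups)} groups of identical columns)")

focal = [s for s in truth if s in set(g.snp_ids)]
screen = ld_screen(g, focal, threshold=0.1)
screen.to_csv(OUT / "ld_screen.tsv", sep="\t", index=False, float_format="%.4f")
print("strongest LD partner per causal SNP (r^2 >= 0.1 flagged):")
print(screen.to_string(index=False))
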