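"""Windowed dN/dS under planted purifying selection.

Simulates genes with a CDS in which nonsynonymous mutations are retained
at 50% of the neutral rate, and recovers r ~ 0.5 with resampling CIs.
The BGC stratification of the same mutation set is also shown.
"""

import tssmut as tm
from tssmut import selection as sel

cfg = tm.SimulationConfig(
    n_chroms=1, chrom_length=130_000, n_genes=4,
    gene_length_range=(9_000, 11_000), baseline_rate=8e-3,
    selection_nonsyn_retention=0.5, seed=0)

genome, genes, cds = tm.simulate_genome(cfg)
muts, _ = tm.simulate_mutations(genome, genes, cfg, cds)
ws = tm.build_windows(genes, genome, W=1000, flank=5000)
ws = tm.resolve_intergenic_overlaps(ws)
mat = tm.build_matrix(muts, ws, genome, k=5)

counts = sel.selection_counts(muts, ws, genome, mat, cds)
pooled = counts.copy()
pooled["anchor"], pooled["side"], pooled["bin"] = "ALL", "all", 1
out = sel.resample_dnds(pooled, B=100, seed=0, level=90.0).iloc[0]
print(f"pooled dN/dS r = {out['r']:.3f}  (90% CI {out['ci_low']:.3f}-"
      f"{out['ci_high']:.3f}); planted retention = 0.5")

cls = sel.bgc_stratify(muts)
print("\nBGC classes (counts):")
print(cls.value_counts().to_string())
print("\nr below 1 reflects the planted purifying selection on "
      "nonsynonymous sites; the BGC classes partition all 12 substitution "
      "types into favoured / indifferent / unfavoured.")
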