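"""Planted TSS hotspot -> context-corrected mutation density mu'.

Simulates a small genome with a 1.5-fold mutation-rate excess within
1 kb of every TSS, runs the window/matrix/density pipeline and prints the
per-bin mu' with bootstrap confidence intervals.  mu' should sit near 1.5
in bins +-1 and near 1 elsewhere.
"""

import tssmut as tm
from tssmut.density import bootstrap_bins, density_table

cfg = tm.SimulationConfig(
    n_chroms=10, chrom_length=1_500_000, n_genes=200,
    gene_length_range=(10_000, 14_000), gene_types=("divergent_lncRNA",),
    baseline_rate=2e-3, hotspot_fold=1.5, hotspot_halfwidth=1000,
    hotspot_decay="box", seed=0)

genome, genes, cds = tm.simulate_genome(cfg)
muts, info = tm.simulate_mutations(genome, genes, cfg)
print(f"simulated {info['n_mutations']} mutations on {len(genes)} genes")

ws = tm.build_windows(genes, genome, W=1000, flank=20_000)
ws = tm.resolve_intergenic_overlaps(ws)
ws = tm.exclude_multigene_transcription(ws, genes)

mat = tm.build_matrix(muts, ws, genome, k=5)
obs = tm.observed_counts(ws, muts, genome, k=5)
exp = tm.expected_counts(ws, mat, genome)
print(f"conservation check: observed {obs.sum():.0f} vs expected {exp.sum():.2f}")

dt = density_table(ws, obs, exp)
bs = bootstrap_bins(dt, B=100, seed=0)
tss = bs[bs.anchor == "TSS"].sort_values(["side", "bin"])
print("\nmu' around the TSS (point = bootstrap mean, 90% CI):")
for row in tss[tss["bin"] <= 5].itertuples():
    print(f"  {row.side:>10} bin {row.bin:>2}: "
          f"{row.point:5.3f}  [{row.ci_low:5.3f}, {row.ci_high:5.3f}]")
print("\nbins +-1 carry the planted 1.5-fold excess; the remaining bins "
      "hover near 1 (slightly below, because the hotspot inflates each "
      "gene's overall mutation ratio g_t).")
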