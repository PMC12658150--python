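import numpy as np
import pandas as pd
import pytest

import tssmut as tm


@pytest.fixture(scope="session")
def small_world():
    """A small simulated dataset shared by read-only tests."""
    cfg = tm.SimulationConfig(n_chroms=2, chrom_length=400_000, n_genes=6,
                              gene_length_range=(8_000, 12_000),
                              baseline_rate=2e-3, hotspot_fold=1.5, seed=3)
    genome, genes, cds = tm.simulate_genome(cfg)
    muts, info = tm.simulate_mutations(genome, genes, cfg, cds)
    ws = tm.build_windows(genes, genome, W=1000)
    ws = tm.resolve_intergenic_overlaps(ws)
    ws = tm.exclude_multigene_transcription(ws, genes)
    mat = tm.build_matrix(muts, ws, genome, k=5)
    obs = tm.observed_counts(ws, muts, genome, k=5)
    exp = tm.expected_counts(ws, mat, genome)
    return dict(cfg=cfg, genome=genome, genes=genes, cds=cds, muts=muts,
                info=info, ws=ws, mat=mat, obs=obs, exp=exp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "gene_type"])
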