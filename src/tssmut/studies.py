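"""Canonical simulation studies exercising the full pipeline.

Each study generates its own synthetic inputs at the documented study
conditions, runs the corresponding method end to end and returns the
measured quantities.  They are used both by the acceptance test suite and
by ``scripts/acceptance.py``; the problem sizes are chosen so that every
study completes on a single CPU in minutes.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import regression as rg
from . import selection as sel
from . import signatures as sg
from . import strandbias as sb
from .contexts import build_matrix, expected_counts, observed_counts
from .density import bootstrap_bins, bracket_labels, density_table, pooled_rate_model
from .simulate import SimulationConfig, simulate_genome, simulate_mutations
from .windows import build_windows, exclude_multigene_transcription, \
    resolve_intergenic_overlaps


def load_fixture_signatures() -> pd.DataFrame:
    """The repository's five synthetic 96-channel signatures."""
    with resources.files("tssmut.data").joinpath(
            "synthetic_signatures_v1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def _pipeline(cfg: SimulationConfig, W: int = 1000, flank: int = 50_000):
    genome, genes, cds = simulate_genome(cfg)
    muts, info = simulate_mutations(genome, genes, cfg, cds)
    ws = build_windows(genes, genome, W=W, flank=flank)
    ws = resolve_intergenic_overlaps(ws)
    ws = exclude_multigene_transcription(ws, genes)
    mat = build_matrix(muts, ws, genome, k=5)
    obs = observed_counts(ws, muts, genome, k=5)
    exp = expected_counts(ws, mat, genome)
    return dict(genome=genome, genes=genes, cds=cds, muts=muts, info=info,
                ws=ws, mat=mat, obs=obs, exp=exp)


def hotspot_recovery_study(seed: int = 0, n_genes: int = 2000,
                           fold: float = 1.5, B: int = 100) -> dict:
    """Planted box hotspot (fold 1.5 within +-1 kb of the TSS) on 2000
    genes with a uniform baseline and ~2x10^5 mutations; mu' recovery in
    the first bins and in the far bins 6-50.
    """
    cfg = SimulationConfig(
        n_chroms=50, chrom_length=2_880_000, n_genes=n_genes,
        gene_length_range=(10_000, 14_000), gene_types=("divergent_lncRNA",),
        baseline_rate=1.4e-3, hotspot_fold=fold, hotspot_halfwidth=1000,
        hotspot_decay="box", seed=seed)
    run = _pipeline(cfg)
    dt = density_table(run["ws"], run["obs"], run["exp"])
    bs = bootstrap_bins(dt, B=B, seed=seed, value="mu_prime")
    tss = bs[bs.anchor == "TSS"].set_index(["side", "bin"])
    # far bins pooled into one key so the bootstrap yields one SE
    far = dt[(dt.anchor == "TSS") & (dt["bin"] >= 6) & (dt["bin"] <= 50)].copy()
    far["side"] = "far"
    far["bin"] = 0
    far_bs = bootstrap_bins(far, B=B, seed=seed, value="mu_prime").iloc[0]
    far_bins = bs[(bs.anchor == "TSS") & (bs["bin"] >= 6) & (bs["bin"] <= 50)]
    return {
        "n_mutations": int(run["info"]["n_mutations"]),
        "n_genes": n_genes,
        "down1": float(tss.loc[("downstream", 1), "point"]),
        "down1_se": float(tss.loc[("downstream", 1), "se"]),
        "up1": float(tss.loc[("upstream", 1), "point"]),
        "up1_se": float(tss.loc[("upstream", 1), "se"]),
        "far_pooled": float(far_bs["point"]),
        "far_pooled_se": float(far_bs["se"]),
        "far_bins_within_3se": float(np.mean(
            np.abs(far_bins["point"] - 1.0) <= 3 * far_bins["se"])),
        "n_far_bins": int(len(far_bins)),
        "density": dt,
        "run": run,
    }


def bracket_ratio_study(dt: pd.DataFrame) -> pd.DataFrame:
    """Pooled interceptless rate model over the TSS bin brackets
    +-[1], +-[2,5], +-[6,50]."""
    lab = bracket_labels(dt)
    return pooled_rate_model(lab, dt["observed"], dt["expected"])


def nnls_recovery_study(seed: int = 0, n_mut: int = 100_000,
                        n_seeds: int = 20) -> dict:
    """Multinomial draws from a 0.5/0.3/0.2 mixture of three fixture
    signatures, decomposed over all five; worst-case weight error over
    seeds, plus the noiseless exact-recovery error."""
    S = load_fixture_signatures()
    names = list(S.columns[:3])
    truth = dict(zip(names, (0.5, 0.3, 0.2)))
    mix = sum(w * S[n] for n, w in truth.items())
    exact = sg.nnls_fit(mix * 1e4, S).weights_norm
    exact_err = max(abs(exact[n] - w) for n, w in truth.items())
    worst = 0.0
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        counts = rng.multinomial(n_mut, (mix / mix.sum()).to_numpy())
        fit = sg.nnls_fit(pd.Series(counts.astype(float), index=S.index), S)
        err = max(abs(fit.weights_norm[n] - w) for n, w in truth.items())
        worst = max(worst, err)
    return {"noiseless_error": float(exact_err), "max_weight_error": float(worst),
            "n_mutations": n_mut, "n_seeds": n_seeds}


POS4 = ["downstream_TSS", "downstream_far", "upstream_TSS", "upstream_far"]


def regression_recovery_study(seed: int = 0, n: int = 20_000,
                              effect: float = 0.3) -> dict:
    """Negative-binomial counts with one planted TSS-specific interaction
    (+0.3 on the log scale); recovery by the downstream TSS-far contrast."""
    rng = np.random.default_rng(seed)
    feat = pd.DataFrame({"x1": rng.normal(size=n)})
    pos = pd.Series(rng.choice(POS4, size=n))
    spec, X, _ = rg.build_design(feat, pos, interactions=True)
    eta = 0.5 + 0.1 * feat["x1"].to_numpy() \
        + effect * feat["x1"].to_numpy() * (pos == "downstream_TSS").to_numpy()
    mu = np.exp(eta)
    alpha = 0.3
    y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
    fit = rg.fit_count_model(X, y, np.zeros(n), family="negative_binomial")
    C = rg.tss_effect_contrasts(spec)
    res = rg.contrast_tests(fit, C, adjust="single_step_maxz", seed=seed)
    row = res.loc["x1|downstream|TSS-far"]
    null_row = res.loc["x1|upstream|TSS-far"]
    return {"estimate": float(row["estimate"]), "se": float(row["se"]),
            "p_adj": float(row["p_adj"]), "true_effect": effect,
            "null_estimate": float(null_row["estimate"]),
            "null_se": float(null_row["se"]), "n_windows": n}


def regression_fwer_study(seed: int = 0, n_runs: int = 500,
                          n: int = 400) -> dict:
    """Global-null simulation of the family-wise error of the max-|z|
    adjusted contrasts: fraction of runs with any adjusted p < 0.05."""
    rng = np.random.default_rng(seed)
    any_sig = 0
    for r in range(n_runs):
        feat = pd.DataFrame({"x1": rng.normal(size=n),
                             "x2": rng.normal(size=n)})
        pos = pd.Series(rng.choice(POS4, size=n))
        spec, X, _ = rg.build_design(feat, pos, interactions=True)
        y = rng.poisson(2.0, n)
        fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
        C = rg.tss_effect_contrasts(spec, total=False)
        res = rg.contrast_tests(fit, C, adjust="single_step_maxz",
                                seed=seed + r, draws=100_000)
        any_sig += int((res["p_adj"] < 0.05).any())
    return {"fwer": any_sig / n_runs, "n_runs": n_runs, "n_windows": n}


def _dnds_replicate(seed: int, retention: float = 1.0, B: int = 100):
    cfg = SimulationConfig(
        n_chroms=1, chrom_length=130_000, n_genes=4,
        gene_length_range=(9_000, 11_000), baseline_rate=8e-3,
        selection_nonsyn_retention=retention, seed=seed)
    genome, genes, cds = simulate_genome(cfg)
    muts, _ = simulate_mutations(genome, genes, cfg, cds)
    ws = build_windows(genes, genome, W=1000, flank=5000)
    ws = resolve_intergenic_overlaps(ws)
    mat = build_matrix(muts, ws, genome, k=5)
    counts = sel.selection_counts(muts, ws, genome, mat, cds)
    pooled = counts.copy()
    pooled["anchor"], pooled["side"], pooled["bin"] = "ALL", "all", 1
    out = sel.resample_dnds(pooled, B=B, seed=seed, level=90.0)
    return out.iloc[0]


def dnds_neutral_coverage_study(seed: int = 0, n_reps: int = 100) -> dict:
    """Coverage of the 90% resampling CI for r under neutral simulations."""
    covered = 0
    rs = []
    for i in range(n_reps):
        row = _dnds_replicate(seed * 10_000 + i)
        rs.append(row["r"])
        if row["ci_low"] <= 1.0 <= row["ci_high"]:
            covered += 1
    return {"coverage": covered / n_reps, "mean_r": float(np.nanmean(rs)),
            "n_reps": n_reps}


def dnds_retention_study(seed: int = 0, retention: float = 0.5) -> dict:
    """Planted purifying selection: r should recover the nonsynonymous
    retention fraction within resampling error."""
    row = _dnds_replicate(seed, retention=retention, B=100)
    return {"r": float(row["r"]), "se": float(row["se"]),
            "retention": retention}


def strand_asymmetry_study(seed: int = 0, fold: float = 2.0) -> dict:
    """Planted coding-strand C>T excess; recovery of the coding/template
    density ratio on the window universe."""
    cfg = SimulationConfig(
        n_chroms=3, chrom_length=800_000, n_genes=12,
        gene_length_range=(40_000, 50_000), baseline_rate=6e-3,
        strand_bias_fold={"C>T": fold}, seed=seed)
    genome, genes, _ = simulate_genome(cfg)
    muts, _ = simulate_mutations(genome, genes, cfg)
    ws = build_windows(genes, genome, W=1000, flank=20_000)
    ws = resolve_intergenic_overlaps(ws)
    sd = sb.strand_stratified_density(muts, ws, genome)
    # the asymmetry is planted on transcribed sequence only
    tr = sd[((sd.anchor == "TSS") & (sd.side == "downstream"))
            | ((sd.anchor == "TTS") & (sd.side == "upstream"))]
    pooled = tr[tr.mut_type == "C>T"].groupby("strand")[["count", "sites"]].sum()
    dens = pooled["count"] / pooled["sites"]
    ratio = float(dens["coding"] / dens["template"])
    se = ratio * np.sqrt(1 / pooled.loc["coding", "count"]
                         + 1 / pooled.loc["template", "count"])
    return {"ratio": ratio, "se": float(se), "fold": fold,
            "n_mutations": int(pooled["count"].sum())}


def geneset_recovery_study(seed: int = 0, n_terms: int = 8) -> dict:
    """A gene set carrying a TSS hotspot should rank first in the scan."""
    from . import genesets as gs
    cfg = SimulationConfig(
        n_chroms=4, chrom_length=1_500_000, n_genes=40,
        gene_length_range=(8_000, 12_000), baseline_rate=3e-3,
        hotspot_fold=3.0, hotspot_halfwidth=1000, seed=seed)
    genome, genes, cds = simulate_genome(cfg)
    # plant the hotspot only at the first 10 genes' TSSs: simulate twice
    cfg_null = SimulationConfig(**{**cfg.__dict__, "hotspot_fold": 1.0})
    hot_genes = genes.iloc[:10]
    cold_genes = genes.iloc[10:]
    m_hot, _ = simulate_mutations(genome, hot_genes, cfg, cds)
    m_cold, _ = simulate_mutations(genome, cold_genes, cfg_null, cds)
    # restrict each mutation set to its gene group's neighbourhoods
    ws = build_windows(genes, genome, W=1000, flank=20_000)
    ws = resolve_intergenic_overlaps(ws)
    from .contexts import assign_windows
    muts = pd.concat([m_hot, m_cold], ignore_index=True)
    widx = assign_windows(muts, ws)
    owner = ws.table["gene_id"].reindex(widx[widx >= 0]).to_numpy()
    keep = np.zeros(len(muts), dtype=bool)
    hot_ids = set(hot_genes["gene_id"])
    src_hot = np.arange(len(muts)) < len(m_hot)
    keep[widx >= 0] = np.where(np.isin(owner, list(hot_ids)),
                               src_hot[widx >= 0], ~src_hot[widx >= 0])
    muts = muts[keep].reset_index(drop=True)
    mat = build_matrix(muts, ws, genome, k=5)
    obs = observed_counts(ws, muts, genome, k=5)
    exp = expected_counts(ws, mat, genome)
    dt = density_table(ws, obs, exp)
    rng = np.random.default_rng(seed)
    gene_ids = genes["gene_id"].to_numpy()
    terms = [pd.DataFrame({"term_id": "HOT", "term_name": "hotspot set",
                           "gene_id": gene_ids[:10]})]
    for t in range(n_terms - 1):
        terms.append(pd.DataFrame({
            "term_id": f"RND{t}", "term_name": f"random set {t}",
            "gene_id": rng.choice(gene_ids[10:], size=10, replace=False)}))
    res = gs.geneset_scan(pd.concat(terms, ignore_index=True), dt)
    rank = int(res.reset_index(drop=True).query("term_id == 'HOT'").index[0]) + 1
    return {"top_term": res.iloc[0]["term_id"], "hot_rank": rank,
            "hot_ratio": float(res.set_index("term_id").loc["HOT", "ratio"]),
            "n_terms": len(res)}
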