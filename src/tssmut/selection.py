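"""Windowed dN/dS, allele-frequency density ratios and BGC stratification.

dN/dS per window pools transcripts: ``r(b) = (sum d^z / sum h^z) /
(sum d^s / sum h^s)`` where ``d`` are observed and ``h`` context-model
expected counts of nonsynonymous (z) and synonymous (s) changes.  The
effect of every CDS site x alternate is determined by recomputing the
codon under the standard genetic code; stop gains/losses count as
nonsynonymous.  CDS lengths must be multiples of 3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .contexts import ContextMatrix, assign_windows
from .genome import BASES, Genome, decode
from .windows import WindowSet

NONCODING, SYN, NONSYN = 0, 1, 2

# amino acid (with '*' for stop) per codon code c0*16+c1*4+c2
_AA = np.array([str(Seq(BASES[c // 16] + BASES[(c // 4) % 4] + BASES[c % 4]).translate())
                for c in range(64)])


def _transcript_effects(exons: pd.DataFrame, genome: Genome):
    """Genomic positions (coding order) and per-alt effect codes of one CDS.

    Returns (positions, effects) with effects of shape (n_sites, 4) indexed
    by the *genomic* alternate base code; the reference column is NONCODING.
    """
    strand = exons["strand"].iloc[0]
    chrom = exons["chrom"].iloc[0]
    parts = [np.arange(r.start, r.end) for r in exons.sort_values("start").itertuples()]
    gpos = np.concatenate(parts)
    codes = genome.seqs[chrom][gpos].astype(np.int64)
    if strand == "-":
        gpos = gpos[::-1]
        codes = 3 - genome.seqs[chrom][gpos].astype(np.int64)
    n = len(gpos)
    if n % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    if np.any(codes >= 4):
        raise ValueError("CDS contains ambiguous bases")
    codons = codes.reshape(-1, 3).astype(np.int64)
    codon_code = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    ref_aa = _AA[codon_code]
    eff = np.zeros((n, 4), dtype=np.int8)
    frame = np.arange(n) % 3
    q = np.arange(n) // 3
    for a in range(4):
        alt_code = codon_code[q] + (a - codes) * 4 ** (2 - frame)
        same = _AA[alt_code] == ref_aa[q]
        col = eff[:, a] if strand == "+" else eff[:, 3 - a]
        col[:] = np.where(codes == a, NONCODING, np.where(same, SYN, NONSYN))
        if strand == "+":
            eff[:, a] = col
        else:
            eff[:, 3 - a] = col
    return gpos, eff


def per_site_effects(cds: pd.DataFrame, genome: Genome) -> dict[str, np.ndarray]:
    """Per-chromosome (L, 4) effect arrays (NONCODING / SYN / NONSYN).

    ``cds`` has one row per CDS exon (gene_id, chrom, start, end, strand);
    multi-exon transcripts are concatenated in transcript order.  Sites in
    multiple CDS keep the effect of the last transcript processed.
    """
    out = {c: np.zeros((len(s), 4), dtype=np.int8) for c, s in genome.seqs.items()}
    for gid, exons in cds.groupby("gene_id", sort=False):
        try:
            gpos, eff = _transcript_effects(exons, genome)
        except ValueError as err:
            raise ValueError(f"transcript {gid}: {err}") from None
        out[exons["chrom"].iloc[0]][gpos] = eff
    return out


def mutation_effect(chrom: str, pos: int, alt: str, cds: pd.DataFrame, genome: Genome) -> str:
    """Effect of a single genomic substitution: synonymous / nonsynonymous /
    noncoding (relative to the supplied CDS annotations)."""
    eff = per_site_effects(cds[cds.chrom == chrom], genome)[chrom]
    code = eff[pos, BASES.index(alt.upper())]
    return {NONCODING: "noncoding", SYN: "synonymous", NONSYN: "nonsynonymous"}[code]


def selection_counts(mutations: pd.DataFrame, ws: WindowSet, genome: Genome,
                     matrix: ContextMatrix, cds: pd.DataFrame) -> pd.DataFrame:
    """Observed (d) and expected (h) syn/nonsyn counts per gene x window."""
    effects = per_site_effects(cds, genome)
    m = matrix.m
    tab = ws.table
    d_z = np.zeros(len(tab)); d_s = np.zeros(len(tab))
    h_z = np.zeros(len(tab)); h_s = np.zeros(len(tab))

    # expected: per-site per-genomic-alt rates restricted by effect class
    for (chrom, strand, tr), ssub in tab.groupby(["chrom", "strand", "transcribed"],
                                                 sort=False):
        eff = effects[chrom]
        v = ws.valid_mask(chrom, tr)
        ctx = genome.context_codes(chrom, matrix.k, strand)
        rates = np.zeros((len(v), 4))
        ok = ctx >= 0
        rows = m[ctx[ok]]
        rates[ok] = rows if strand == "+" else rows[:, ::-1]
        rates[~v] = 0.0
        for arr, cls in ((h_z, NONSYN), (h_s, SYN)):
            persite = (rates * (eff == cls)).sum(axis=1)
            cs = np.concatenate([[0.0], np.cumsum(persite)])
            arr[ssub.index.to_numpy()] = cs[ssub["end"].to_numpy()] - cs[ssub["start"].to_numpy()]

    muts = mutations.reset_index(drop=True)
    widx = assign_windows(muts, ws)
    keep = widx >= 0
    muts, widx = muts[keep].reset_index(drop=True), widx[keep]
    alts = muts["alt"].str.upper().map({b: i for i, b in enumerate(BASES)}).to_numpy()
    for chrom, sub in muts.groupby("chrom", sort=False):
        i = sub.index.to_numpy()
        e = effects[chrom][sub["pos"].to_numpy(), alts[i]]
        np.add.at(d_z, widx[i[e == NONSYN]], 1.0)
        np.add.at(d_s, widx[i[e == SYN]], 1.0)

    out = tab[["gene_id", "anchor", "side", "bin"]].copy()
    out["d_z"], out["d_s"], out["h_z"], out["h_s"] = d_z, d_s, h_z, h_s
    return out


def dnds_window(counts: pd.DataFrame) -> pd.DataFrame:
    """Pooled dN/dS per window key (Eq. 7); missing where undefined."""
    g = counts.groupby(["anchor", "side", "bin"])[["d_z", "d_s", "h_z", "h_s"]].sum().reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (g["d_z"] / g["h_z"]) / (g["d_s"] / g["h_s"])
    missing = (g["d_s"] <= 0) | (g["h_z"] <= 0) | (g["h_s"] <= 0)
    g["r"] = np.where(missing, np.nan, r)
    g["missing"] = missing
    return g


def resample_dnds(counts: pd.DataFrame, B: int = 100, seed: int = 0,
                  level: float = 90.0) -> pd.DataFrame:
    """Percentile CIs for r(b) by resampling each transcript-window's
    observed mutations with replacement B times.

    Replicates in which a window draws zero synonymous mutations contribute
    no value there; windows with no usable replicate keep the point
    estimate without an interval.
    """
    rng = np.random.default_rng(seed)
    point = dnds_window(counts)
    d = counts[(counts.d_z + counts.d_s) > 0]
    key = d[["anchor", "side", "bin"]].astype(str).agg("|".join, axis=1).to_numpy()
    keys, kidx = np.unique(key, return_inverse=True)
    tot = (d["d_z"] + d["d_s"]).to_numpy().astype(int)
    pz = (d["d_z"].to_numpy() / tot)
    allkey = point[["anchor", "side", "bin"]].astype(str).agg("|".join, axis=1).to_numpy()
    hz = point.set_index(["anchor", "side", "bin"])["h_z"]
    hs = point.set_index(["anchor", "side", "bin"])["h_s"]
    reps = np.full((B, len(allkey)), np.nan)
    order = {k: j for j, k in enumerate(allkey)}
    for r in range(B):
        z = rng.binomial(tot, pz)
        s = tot - z
        sz = np.bincount(kidx, weights=z, minlength=len(keys))
        ss = np.bincount(kidx, weights=s, minlength=len(keys))
        for j, k in enumerate(keys):
            col = order[k]
            hzv, hsv = hz.iloc[col], hs.iloc[col]
            if ss[j] > 0 and hzv > 0 and hsv > 0:
                reps[r, col] = (sz[j] / hzv) / (ss[j] / hsv)
    lo_q, hi_q = (100 - level) / 2, 100 - (100 - level) / 2
    ci_low, ci_high, se, boot = [], [], [], []
    for col in range(len(allkey)):
        v = reps[:, col]
        v = v[np.isfinite(v)]
        if len(v) >= 2:
            ci_low.append(np.percentile(v, lo_q)); ci_high.append(np.percentile(v, hi_q))
            se.append(np.std(v, ddof=1)); boot.append(np.mean(v))
        else:
            ci_low.append(np.nan); ci_high.append(np.nan); se.append(np.nan); boot.append(np.nan)
    out = point.copy()
    out["r_boot"], out["ci_low"], out["ci_high"], out["se"] = boot, ci_low, ci_high, se
    return out


def af_ratio(density_a: pd.DataFrame, density_b: pd.DataFrame,
             B: int = 100, seed: int = 0, level: float = 90.0) -> pd.DataFrame:
    """Per-bin ratio of the simple (unweighted) gene means of mu_tb between
    two allele-frequency strata (a / b), with mutation-resampling CIs.

    Each stratum's density table must come from its own context matrix.
    Mutation resampling redraws each stratum's observed counts as a
    multinomial over its gene x window cells.
    """
    rng = np.random.default_rng(seed)

    def prep(df):
        d = df[np.isfinite(df["mu"]) & (df["expected"] > 0)]
        key = d[["anchor", "side", "bin"]].astype(str).agg("|".join, axis=1).to_numpy()
        return d, key

    da, ka = prep(density_a)
    db, kb = prep(density_b)
    keys = np.unique(np.concatenate([ka, kb]))

    def binmeans(obs, exp, key):
        mu = obs / exp
        s = pd.Series(mu).groupby(key).mean()
        return s.reindex(keys).to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        pa = binmeans(da["observed"].to_numpy(), da["expected"].to_numpy(), ka)
        pb = binmeans(db["observed"].to_numpy(), db["expected"].to_numpy(), kb)
        point = pa / pb
        reps = np.empty((B, len(keys)))
        for r in range(B):
            oa = rng.multinomial(int(da["observed"].sum()),
                                 da["observed"].to_numpy() / da["observed"].sum())
            ob = rng.multinomial(int(db["observed"].sum()),
                                 db["observed"].to_numpy() / db["observed"].sum())
            reps[r] = binmeans(oa, da["expected"].to_numpy(), ka) / \
                binmeans(ob, db["expected"].to_numpy(), kb)
    lo_q, hi_q = (100 - level) / 2, 100 - (100 - level) / 2
    rows = []
    for j, k in enumerate(keys):
        anchor, side, b = k.split("|")
        v = reps[:, j]
        v = v[np.isfinite(v)]
        rows.append({"anchor": anchor, "side": side, "bin": int(b), "ratio": point[j],
                     "ratio_boot": np.mean(v) if len(v) else np.nan,
                     "ci_low": np.percentile(v, lo_q) if len(v) else np.nan,
                     "ci_high": np.percentile(v, hi_q) if len(v) else np.nan})
    return pd.DataFrame(rows).sort_values(["anchor", "side", "bin"]).reset_index(drop=True)


BGC_FAVOURED = "favoured"      # weak -> strong: A/T -> G/C
BGC_UNFAVOURED = "unfavoured"  # strong -> weak: G/C -> A/T
BGC_INDIFFERENT = "indifferent"  # A<>T, C<>G


def bgc_class(ref: str, alt: str) -> str:
    """GC-biased gene conversion class of a substitution."""
    weak = {"A", "T"}
    r, a = ref.upper(), alt.upper()
    if r in weak and a not in weak:
        return BGC_FAVOURED
    if r not in weak and a in weak:
        return BGC_UNFAVOURED
    return BGC_INDIFFERENT


def bgc_stratify(mutations: pd.DataFrame) -> pd.Series:
    """BGC class per mutation (strand-symmetric)."""
    return pd.Series([bgc_class(r, a) for r, a in zip(mutations["ref"], mutations["alt"])],
                     index=mutations.index, name="bgc_class")
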