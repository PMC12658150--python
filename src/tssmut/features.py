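"""Per-window genomic feature values: signal densities, composition,
TATA-box scores, polymerase stalling ratios and divergent-promoter flags.

Composition-type features are computed on each window's full span; signal
densities honour the requested missing-data policy (absent signal counted
as zero, or absent bases ignored as for replication timing).  Gene-level
features are propagated to all windows of the gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BASES, Genome, revcomp_str
from .windows import WindowSet, tss_position


def _per_base_signal(track: pd.DataFrame, length: int) -> tuple[np.ndarray, np.ndarray]:
    """(value, covered) per-base arrays; overlapping intervals are summed."""
    val = np.zeros(length)
    cov = np.zeros(length, dtype=bool)
    for iv in track.itertuples(index=False):
        s, e = max(0, iv.start), min(length, iv.end)
        if e > s:
            val[s:e] += iv.value
            cov[s:e] = True
    return val, cov


def signal_density(track: pd.DataFrame, ws: WindowSet,
                   missing_policy: str = "zero_fill") -> pd.Series:
    """Per-base signal density per window.

    zero_fill: sum(value x overlap) / window sites, treating unreported
    bases as zero signal.  ignore_missing: divide by the number of covered
    bases only; windows with no coverage get NaN.
    """
    if missing_policy not in ("zero_fill", "ignore_missing"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    out = np.full(len(ws.table), np.nan)
    for chrom, sub in ws.table.groupby("chrom", sort=False):
        val, cov = _per_base_signal(track[track.chrom == chrom], ws.chrom_len(chrom))
        cval = np.concatenate([[0.0], np.cumsum(val)])
        ccov = np.concatenate([[0], np.cumsum(cov.astype(np.int64))])
        s = sub["start"].to_numpy(); e = sub["end"].to_numpy()
        tot = cval[e] - cval[s]
        if missing_policy == "zero_fill":
            n = (e - s).astype(float)
        else:
            n = (ccov[e] - ccov[s]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sub.index.to_numpy()] = np.where(n > 0, tot / n, np.nan)
    return pd.Series(out, index=ws.table.index, name="signal_density")


def _base_counts(ws: WindowSet, genome: Genome) -> pd.DataFrame:
    out = np.zeros((len(ws.table), 4), dtype=np.int64)
    for chrom, sub in ws.table.groupby("chrom", sort=False):
        codes = genome.seqs[chrom]
        cs = {b: np.concatenate([[0], np.cumsum(codes == i)])
              for i, b in enumerate(BASES)}
        s = sub["start"].to_numpy(); e = sub["end"].to_numpy()
        for i, b in enumerate(BASES):
            out[sub.index.to_numpy(), i] = cs[b][e] - cs[b][s]
    return pd.DataFrame(out, columns=list(BASES), index=ws.table.index)


def gc_skew(ws: WindowSet, genome: Genome) -> pd.Series:
    """(G - C) / (G + C) on the template strand of each window's gene.

    For plus-strand genes the template is the minus strand, so template G
    equals reference C; the sign flips relative to the coding strand.
    """
    bc = _base_counts(ws, genome)
    plus = (ws.table["strand"] == "+").to_numpy()
    g_t = np.where(plus, bc["C"], bc["G"]).astype(float)
    c_t = np.where(plus, bc["G"], bc["C"]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = (g_t - c_t) / (g_t + c_t)
    return pd.Series(skew, index=ws.table.index, name="gc_skew")


def composition(ws: WindowSet, genome: Genome) -> pd.DataFrame:
    """G/C content and CpG dinucleotide density per window full span."""
    bc = _base_counts(ws, genome)
    span = (ws.table["end"] - ws.table["start"]).to_numpy().astype(float)
    gc = (bc["G"] + bc["C"]).to_numpy() / np.maximum(span, 1)
    cpg = np.zeros(len(ws.table))
    for chrom, sub in ws.table.groupby("chrom", sort=False):
        codes = genome.seqs[chrom]
        is_cpg = np.zeros(len(codes), dtype=np.int64)
        is_cpg[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)
        cs = np.concatenate([[0], np.cumsum(is_cpg)])
        s = sub["start"].to_numpy(); e = sub["end"].to_numpy()
        cpg[sub.index.to_numpy()] = cs[e] - cs[s]
    return pd.DataFrame({"gc_content": gc, "cpg_density": cpg / np.maximum(span, 1)},
                        index=ws.table.index)


def interval_fraction(ws: WindowSet, bed: pd.DataFrame) -> pd.Series:
    """Fraction of each window's span covered by BED intervals (e.g. CpG
    islands)."""
    out = np.zeros(len(ws.table))
    for chrom, sub in ws.table.groupby("chrom", sort=False):
        cov = np.zeros(ws.chrom_len(chrom), dtype=bool)
        for iv in bed[bed.chrom == chrom].itertuples(index=False):
            cov[max(0, iv.start):iv.end] = True
        cs = np.concatenate([[0], np.cumsum(cov.astype(np.int64))])
        s = sub["start"].to_numpy(); e = sub["end"].to_numpy()
        span = np.maximum(e - s, 1).astype(float)
        out[sub.index.to_numpy()] = (cs[e] - cs[s]) / span
    return pd.Series(out, index=ws.table.index, name="interval_fraction")


def position_weight_matrix(pfm: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """PWM from a 4 x L position frequency matrix.

    Columns are normalized to probabilities, divided by the 0.25 background,
    a pseudocount is added and base-2 logarithms taken.
    """
    pfm = np.asarray(pfm, dtype=float)
    colsum = pfm.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("PFM has a zero column")
    return np.log2(pfm / colsum / 0.25 + pseudocount)


def tata_score(pfm: np.ndarray, genome: Genome, gene, scan: tuple[int, int] = (-40, -20)) -> float:
    """Maximum PWM score over sliding motif windows (both orientations)
    in the promoter scan region, expressed relative to the TSS along the
    direction of transcription."""
    pwm = position_weight_matrix(pfm)
    mlen = pwm.shape[1]
    tss = tss_position(gene)
    lo, hi = scan
    if gene.strand == "+":
        region = (tss + lo, tss + hi + 1)
    else:
        region = (tss - hi, tss - lo + 1)
    clen = genome.length(gene.chrom)
    start, end = max(0, region[0]), min(clen, region[1])
    seq = genome.sequence(gene.chrom, start, end)
    if gene.strand == "-":
        seq = revcomp_str(seq)
    best = -np.inf
    for i in range(0, len(seq) - mlen + 1):
        for s in (seq[i:i + mlen], revcomp_str(seq[i:i + mlen])):
            if "N" in s:
                continue
            best = max(best, sum(pwm[BASES.index(b), j] for j, b in enumerate(s)))
    return float(best)


def proseq_ratio(reads: pd.DataFrame, ws: WindowSet, gene,
                 start_bp: int = 500) -> float:
    """log10(start density + 1) - log10(body density + 1) for one gene.

    ``reads``: DataFrame (chrom, pos, strand, count); only reads from the
    gene's transcribed strand are used.  The start is the first ``start_bp``
    of the first downstream-TSS window; the body is the remainder of the
    downstream-TSS windows.  Returns NaN when the body has no sites.
    """
    sub = ws.table[(ws.table.gene_id == gene.gene_id) & (ws.table.anchor == "TSS")
                   & (ws.table.side == "downstream")].sort_values("bin")
    if len(sub) == 0:
        return float("nan")
    r = reads[(reads.chrom == gene.chrom) & (reads.strand == gene.strand)]
    pos = r["pos"].to_numpy(); cnt = r["count"].to_numpy()

    def tally(intervals):
        total, sites = 0.0, 0
        for s, e in intervals:
            if e > s:
                sel = (pos >= s) & (pos < e)
                total += cnt[sel].sum()
                sites += e - s
        return total, sites

    first = sub.iloc[0]
    if gene.strand == "+":
        start_iv = [(first.start, min(first.start + start_bp, first.end))]
        body_iv = [(min(first.start + start_bp, first.end), first.end)]
    else:
        start_iv = [(max(first.end - start_bp, first.start), first.end)]
        body_iv = [(first.start, max(first.end - start_bp, first.start))]
    body_iv += [(r2.start, r2.end) for r2 in sub.iloc[1:].itertuples(index=False)]
    st, sn = tally(start_iv)
    bt, bn = tally(body_iv)
    if bn == 0:
        return float("nan")
    return float(np.log10(st / sn + 1) - np.log10(bt / bn + 1))


def divergent_promoter_flags(pairs: pd.DataFrame, ws: WindowSet) -> pd.DataFrame:
    """Per-gene flags for divergent-promoter regions overlapping the first
    window upstream / downstream of the TSS.

    ``pairs`` has one row per opposite-strand start pair (chrom, start_a,
    end_a, start_b, end_b); the putative divergent promoter is the gap
    between the two annotations, or their overlap when they intersect.
    """
    regions: dict[str, list[tuple[int, int]]] = {}
    for p in pairs.itertuples(index=False):
        lo = min(p.end_a, p.end_b)
        hi = max(p.start_a, p.start_b)
        if hi < lo:  # annotations overlap: use the overlapping region
            lo, hi = hi, lo
        regions.setdefault(p.chrom, []).append((lo, hi))
    rows = []
    for gid, sub in ws.table.groupby("gene_id", sort=False):
        flags = {}
        for side, col in (("upstream", "up_divergent"), ("downstream", "down_divergent")):
            w = sub[(sub.anchor == "TSS") & (sub.side == side) & (sub.bin == 1)]
            hit = False
            for row in w.itertuples(index=False):
                for lo, hi in regions.get(row.chrom, []):
                    if lo < row.end and hi > row.start:
                        hit = True
            flags[col] = hit
        rows.append({"gene_id": gid, **flags})
    return pd.DataFrame(rows)


def propagate_gene_features(gene_features: pd.DataFrame, ws: WindowSet) -> pd.DataFrame:
    """Broadcast gene-level columns (indexed by gene_id) to all windows."""
    missing = set(ws.table["gene_id"]) - set(gene_features.index)
    if missing:
        raise AssertionError(f"windows owned by unannotated genes: {sorted(missing)[:5]}")
    return gene_features.reindex(ws.table["gene_id"]).set_index(ws.table.index)
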