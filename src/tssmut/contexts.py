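"""k-mer mutational matrices and context-based expected mutation counts.

The matrix element ``m[i, j]`` is the genome-wide average probability that
the central base of k-mer context ``i`` (read on the coding strand of the
gene owning the site) mutates to base ``j``:  ``m_ij = n_ij / a_i`` where
``n_ij`` is the number of observed mutations of that type over the
analysed site universe and ``a_i`` the abundance of context ``i`` among
the same sites.  The expected number of mutations in a window is the sum
over its valid sites of the total mutation probability of the site's
context; by construction the expectations summed over the estimation site
set equal the observed total exactly.

Sites whose context is undefined (contig edge, N) are excluded from both
the abundances and the countable mutations.  Mutation classes
(``CpG>TpG`` vs ``nonCpG>TpG``) are defined per variant from its genomic
dinucleotide context (strand-symmetric) and applied as an identical filter
to matrix estimation and window counting, which keeps the conservation
identity exact for every k including the 12-type mononucleotide mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BASES, Genome, central_base, code_to_kmer, kmer_to_code, revcomp_str
from .windows import WindowSet

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "dataset", "af_class"]

CLASS_ALL = "all"
CLASS_CPG = "CpG>TpG"
CLASS_NONCPG = "nonCpG>TpG"


def classify_mutation(ref_context: str, alt: str) -> str:
    """Mutation class from a (coding-strand oriented) context string.

    The context must be centred on the mutated base.  CpG>TpG means the
    central base is a C immediately followed by G, mutating to T.
    """
    k = len(ref_context)
    if k % 2 != 1:
        raise ValueError("context length must be odd")
    h = k // 2
    ref = ref_context[h].upper()
    if ref == alt.upper():
        raise ValueError("alt equals ref")
    if ref == "C" and alt.upper() == "T" and h + 1 < k and ref_context[h + 1].upper() == "G":
        return CLASS_CPG
    return CLASS_NONCPG


def orient_to_coding(ref: str, alt: str, context: str, gene_strand: str):
    """Orient a genomic-plus-strand call to the gene's coding strand.

    Minus-strand genes get ref, alt and context reverse-complemented;
    plus-strand calls pass through (the operation is an involution).
    """
    if gene_strand == "+":
        return ref, alt, context
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return comp[ref.upper()], comp[alt.upper()], revcomp_str(context)


def classify_mutations_df(mutations: pd.DataFrame, genome: Genome) -> np.ndarray:
    """Vectorised strand-symmetric class label per variant (row-aligned)."""
    m = mutations.reset_index(drop=True)
    out = np.full(len(m), CLASS_NONCPG, dtype=object)
    refs = m["ref"].str.upper().to_numpy()
    alts = m["alt"].str.upper().to_numpy()
    for chrom, sub in m.groupby("chrom", sort=False):
        codes = genome.seqs[chrom]
        i = sub.index.to_numpy()
        p = sub["pos"].to_numpy()
        nxt = np.where(p + 1 < len(codes), codes[np.minimum(p + 1, len(codes) - 1)], 4)
        prv = np.where(p >= 1, codes[np.maximum(p - 1, 0)], 4)
        r, a = refs[i], alts[i]
        is_cpg = ((r == "C") & (a == "T") & (nxt == 2)) | ((r == "G") & (a == "A") & (prv == 1))
        out[i[is_cpg]] = CLASS_CPG
    return out


@dataclass
class ContextMatrix:
    """Per-(context, alternate) mutation probabilities with abundances."""

    k: int
    counts: np.ndarray      # (4**k, 4) mutation tallies n_ij
    abundances: np.ndarray  # (4**k,)  site tallies a_i
    dataset: str | None = None
    mut_class: str = CLASS_ALL

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.abundances = np.asarray(self.abundances, dtype=np.float64)
        nctx = 4 ** self.k
        if self.counts.shape != (nctx, 4) or self.abundances.shape != (nctx,):
            raise ValueError("matrix shape does not match k")
        central = central_base(np.arange(nctx), self.k)
        if np.any(self.counts[np.arange(nctx), central] != 0):
            raise ValueError("counts present for alt == central base")
        if np.any((self.abundances == 0) & (self.counts.sum(axis=1) > 0)):
            raise ValueError("mutations counted at contexts with zero abundance")

    @property
    def m(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / self.abundances[:, None]
        out[self.abundances == 0] = 0.0
        return out

    def site_rate(self) -> np.ndarray:
        """Total mutation probability per context, Sum_j m_ij."""
        return self.m.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        nctx = 4 ** self.k
        rows = []
        for i in range(nctx):
            ctx = code_to_kmer(i, self.k)
            for j, b in enumerate(BASES):
                if j == central_base(i, self.k):
                    continue
                rows.append((ctx, b, self.counts[i, j], self.abundances[i], self.m[i, j]))
        return pd.DataFrame(rows, columns=["context", "alt", "count", "abundance", "m"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, k: int | None = None, **kw) -> "ContextMatrix":
        df = pd.read_csv(path, sep="\t")
        k = k or len(df["context"].iloc[0])
        counts = np.zeros((4 ** k, 4))
        abund = np.zeros(4 ** k)
        for r in df.itertuples(index=False):
            i = kmer_to_code(r.context)
            counts[i, BASES.index(r.alt)] = r.count
            abund[i] = r.abundance
        return cls(k, counts, abund, **kw)

    @classmethod
    def uniform(cls, k: int, total_rate: float) -> "ContextMatrix":
        """Context-homogeneous matrix with Sum_j m_ij == total_rate everywhere."""
        nctx = 4 ** k
        counts = np.full((nctx, 4), total_rate / 3.0)
        central = central_base(np.arange(nctx), k)
        counts[np.arange(nctx), central] = 0.0
        return cls(k, counts, np.ones(nctx))


def _valid_membership(ws: WindowSet, chrom: str, strand: str) -> np.ndarray:
    """Bool array marking valid bases of `chrom` inside windows of `strand`
    genes (each class of window checked against its own mask)."""
    member = np.zeros(ws.chrom_len(chrom), dtype=bool)
    sub = ws.table[(ws.table.chrom == chrom) & (ws.table.strand == strand)]
    for tr, ssub in sub.groupby("transcribed", sort=False):
        m = np.zeros_like(member)
        for row in ssub.itertuples(index=False):
            m[row.start : row.end] = True
        member |= m & ws.valid_mask(chrom, tr)
    return member


def assign_windows(mutations: pd.DataFrame, ws: WindowSet) -> np.ndarray:
    """Window row index for each mutation (-1: outside or masked site).

    Transcribed windows take priority: a site transcribed by exactly one
    gene is looked up among that gene's transcribed windows; remaining
    sites are matched against the untranscribed windows, which must be
    disjoint (run resolve_intergenic_overlaps first).
    """
    out = np.full(len(mutations), -1, dtype=np.int64)
    tab = ws.table
    for chrom, msub in mutations.groupby("chrom", sort=False):
        L = ws.chrom_len(chrom)
        wsub = tab[(tab.chrom == chrom) & (tab.start < tab.end)]
        if len(wsub) == 0:
            continue
        p = msub["pos"].to_numpy()
        midx = msub.index.to_numpy()
        tsub = wsub[wsub.transcribed]
        towner = np.full(L, -1, dtype=np.int64)
        gene_windows = {}
        for gi, (g, gw) in enumerate(tsub.groupby("gene_id", sort=False)):
            for row in gw.itertuples(index=False):
                seg = towner[row.start:row.end]
                seg[(seg >= 0) & (seg != gi)] = -2
                seg[seg == -1] = gi
            order = np.argsort(gw["start"].to_numpy(), kind="stable")
            gene_windows[gi] = (gw["start"].to_numpy()[order],
                                gw["end"].to_numpy()[order],
                                gw.index.to_numpy()[order])
        own = towner[p]
        tsel = (own >= 0) & ws.valid_t[chrom][p]
        for gi in np.unique(own[tsel]):
            starts, ends, ridx = gene_windows[gi]
            sel = tsel & (own == gi)
            i = np.searchsorted(starts, p[sel], side="right") - 1
            ok = (i >= 0) & (p[sel] < ends[np.maximum(i, 0)])
            out[midx[sel][ok]] = ridx[i[ok]]
        usub = wsub[~wsub.transcribed]
        if len(usub):
            order = np.argsort(usub["start"].to_numpy(), kind="stable")
            starts = usub["start"].to_numpy()[order]
            ends = usub["end"].to_numpy()[order]
            ridx = usub.index.to_numpy()[order]
            sel = (out[midx] == -1) & ws.valid_u[chrom][p] & (own == -1)
            i = np.searchsorted(starts, p[sel], side="right") - 1
            ok = (i >= 0) & (p[sel] < ends[np.maximum(i, 0)])
            out[midx[sel][ok]] = ridx[i[ok]]
    return out


def _filter_mutations(mutations: pd.DataFrame, genome: Genome,
                      mut_class: str, dataset: str | None) -> pd.DataFrame:
    m = mutations.reset_index(drop=True)
    keep = np.ones(len(m), dtype=bool)
    if dataset is not None:
        keep &= (m["dataset"] == dataset).to_numpy()
    if mut_class != CLASS_ALL:
        keep &= classify_mutations_df(m, genome) == mut_class
    return m[keep].reset_index(drop=True)


def build_matrix(mutations: pd.DataFrame, ws: WindowSet, genome: Genome, k: int = 5,
                 mut_class: str = CLASS_ALL, dataset: str | None = None) -> ContextMatrix:
    """Estimate the k-mer matrix over the window set's valid sites (Eq. 1).

    Contexts are read on the coding strand of the gene owning each site.
    Mutations outside the valid site universe, at undefined contexts, or
    not matching the class/dataset filters do not contribute.
    """
    nctx = 4 ** k
    abund = np.zeros(nctx, dtype=np.float64)
    for chrom in ws.chroms:
        for strand in "+-":
            member = _valid_membership(ws, chrom, strand)
            if not member.any():
                continue
            ctx = genome.context_codes(chrom, k, strand)[member]
            abund += np.bincount(ctx[ctx >= 0], minlength=nctx)

    counts = np.zeros((nctx, 4), dtype=np.float64)
    muts = _filter_mutations(mutations, genome, mut_class, dataset)
    widx = assign_windows(muts, ws)
    keep = widx >= 0
    muts, widx = muts[keep].reset_index(drop=True), widx[keep]
    strands = ws.table["strand"].to_numpy()[widx]
    alts = muts["alt"].str.upper().map({b: i for i, b in enumerate(BASES)}).to_numpy()
    for chrom, sub in muts.groupby("chrom", sort=False):
        i = sub.index.to_numpy()
        p = sub["pos"].to_numpy()
        for strand in "+-":
            sel = strands[i] == strand
            if not sel.any():
                continue
            ctx = genome.context_codes(chrom, k, strand)[p[sel]]
            a = alts[i[sel]]
            if strand == "-":
                a = 3 - a
            ok = ctx >= 0
            np.add.at(counts, (ctx[ok], a[ok]), 1.0)
    if np.any((abund == 0) & (counts.sum(axis=1) > 0)):
        raise ValueError("mutation observed at a context absent from the site universe")
    return ContextMatrix(k, counts, abund, dataset=dataset, mut_class=mut_class)


def mononucleotide_matrix(mutations: pd.DataFrame, ws: WindowSet, genome: Genome,
                          mut_class: str = CLASS_ALL, dataset: str | None = None) -> ContextMatrix:
    """12-type matrix without sequence context (k=1), for sparse datasets."""
    return build_matrix(mutations, ws, genome, k=1, mut_class=mut_class, dataset=dataset)


def expected_counts(ws: WindowSet, matrix: ContextMatrix, genome: Genome) -> np.ndarray:
    """Expected mutations per window row (Eq. 2 denominator)."""
    rate = np.append(matrix.site_rate(), 0.0)  # ctx code -1 -> rate 0
    out = np.zeros(len(ws.table), dtype=np.float64)
    for (chrom, strand, tr), ssub in ws.table.groupby(
            ["chrom", "strand", "transcribed"], sort=False):
        ctx = genome.context_codes(chrom, matrix.k, strand)
        persite = rate[ctx] * ws.valid_mask(chrom, tr)
        cs = np.concatenate([[0.0], np.cumsum(persite)])
        out[ssub.index.to_numpy()] = (
            cs[ssub["end"].to_numpy()] - cs[ssub["start"].to_numpy()]
        )
    return out


def observed_counts(ws: WindowSet, mutations: pd.DataFrame, genome: Genome, k: int,
                    mut_class: str = CLASS_ALL, dataset: str | None = None) -> np.ndarray:
    """Observed mutations per window row, with the same filters as Eq. 1."""
    muts = _filter_mutations(mutations, genome, mut_class, dataset)
    widx = assign_windows(muts, ws)
    # drop mutations at undefined contexts so observed and expected match
    keep = widx >= 0
    out = np.zeros(len(ws.table), dtype=np.float64)
    if keep.any():
        m2, w2 = muts[keep].reset_index(drop=True), widx[keep]
        strands = ws.table["strand"].to_numpy()[w2]
        ok = np.ones(len(m2), dtype=bool)
        for chrom, sub in m2.groupby("chrom", sort=False):
            i = sub.index.to_numpy()
            for strand in "+-":
                sel = i[strands[i] == strand]
                ctx = genome.context_codes(chrom, k, strand)[m2["pos"].to_numpy()[sel]]
                ok[sel] = ctx >= 0
        np.add.at(out, w2[ok], 1.0)
    return out
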