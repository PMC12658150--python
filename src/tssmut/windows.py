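"""TSS/TTS-anchored, transcription-oriented genomic window sets.

Each gene contributes up to four classes of non-overlapping windows of
fixed nominal width ``W``: untranscribed upstream of the TSS, transcribed
downstream of the TSS, transcribed upstream of the TTS and untranscribed
downstream of the TTS.  Bin indices are 1-based and increase with distance
from the anchor.  All coordinates are 0-based half-open; minus-strand
genes are mirrored so that "downstream" always means "in the direction of
transcription".

Conventions (documented, not inferred from data):

* The TSS base itself is the first base of downstream bin 1; upstream
  bin 1 ends one base before it.  Symmetrically for the TTS.
* Transcribed sites of genes shorter than twice the flank are split
  between the TSS- and TTS-anchored window sets by proximity to the
  respective anchor base; an exact tie goes to the anchor with the lower
  genomic coordinate.
* Windows truncated by the gene end, a chromosome edge or the
  nearest-anchor rule keep their nominal bin index with a reduced span.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Genome

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "gene_type"]

WINDOW_COLUMNS = [
    "gene_id", "chrom", "strand", "anchor", "side", "bin",
    "start", "end", "transcribed", "anchor_pos", "n_valid_sites",
]


def tss_position(gene: pd.Series) -> int:
    """Genomic coordinate of the TSS base (first transcribed base)."""
    return int(gene.start) if gene.strand == "+" else int(gene.end) - 1


def tts_position(gene: pd.Series) -> int:
    """Genomic coordinate of the TTS base (last transcribed base)."""
    return int(gene.end) - 1 if gene.strand == "+" else int(gene.start)


class WindowSet:
    """A window table plus per-chromosome valid-site masks.

    Validity is tracked separately for transcribed and untranscribed
    windows: a base transcribed by exactly one gene stays valid in that
    gene's transcribed windows while being excluded from any other gene's
    untranscribed flank that happens to span it.
    """

    def __init__(self, table: pd.DataFrame, valid_t: dict[str, np.ndarray],
                 valid_u: dict[str, np.ndarray], width: int):
        self.table = table.reset_index(drop=True)
        self.valid_t = valid_t
        self.valid_u = valid_u
        self.width = width
        self.recount()

    def copy(self) -> "WindowSet":
        return WindowSet(self.table.copy(),
                         {c: v.copy() for c, v in self.valid_t.items()},
                         {c: v.copy() for c, v in self.valid_u.items()}, self.width)

    @property
    def chroms(self) -> list[str]:
        return list(self.valid_t.keys())

    def chrom_len(self, chrom: str) -> int:
        return len(self.valid_t[chrom])

    def valid_mask(self, chrom: str, transcribed: bool) -> np.ndarray:
        return self.valid_t[chrom] if transcribed else self.valid_u[chrom]

    def recount(self) -> None:
        """Recompute n_valid_sites from the masks."""
        counts = np.zeros(len(self.table), dtype=np.int64)
        for (chrom, tr), sub in self.table.groupby(["chrom", "transcribed"], sort=False):
            cs = np.concatenate([[0], np.cumsum(self.valid_mask(chrom, tr).astype(np.int64))])
            counts[sub.index.to_numpy()] = (
                cs[sub["end"].to_numpy()] - cs[sub["start"].to_numpy()]
            )
        self.table["n_valid_sites"] = counts

    def valid_positions(self, row) -> np.ndarray:
        v = self.valid_mask(row.chrom, row.transcribed)[row.start : row.end]
        return np.arange(row.start, row.end)[v]

    def assert_disjoint(self) -> None:
        """No genomic base may be valid in two windows."""
        for chrom in self.chroms:
            cover = np.zeros(self.chrom_len(chrom), dtype=np.int16)
            sub = self.table[self.table.chrom == chrom]
            for row in sub.itertuples(index=False):
                v = self.valid_mask(chrom, row.transcribed)[row.start : row.end]
                cover[row.start : row.end] += v
            if (cover > 1).any():
                raise AssertionError(f"base valid in two windows on {chrom}")


def _chrom_lengths(genome) -> dict[str, int]:
    if isinstance(genome, Genome):
        return {c: genome.length(c) for c in genome.chroms}
    return dict(genome)


def build_windows(genes: pd.DataFrame, genome, W: int, flank: int | None = None) -> WindowSet:
    """Build the per-gene TSS/TTS-anchored window set.

    Parameters
    ----------
    genes : DataFrame with GENE_COLUMNS (0-based half-open spans).
    genome : Genome or {chrom: length} mapping, used for edge clipping.
    W : nominal window width in bp (typically 1000 or 100).
    flank : maximal untranscribed / transcribed extent per anchor; defaults
        to 50 kb (5 kb when W == 100).
    """
    if flank is None:
        flank = 5_000 if W == 100 else 50_000
    lengths = _chrom_lengths(genome)
    nbins = int(np.ceil(flank / W))

    bad = genes[genes.start >= genes.end]
    if len(bad):
        raise ValueError(f"degenerate genes (tss==tts): {list(bad.gene_id)}")

    rows = []
    for gene in genes.itertuples(index=False):
        L = gene.end - gene.start
        clen = lengths[gene.chrom]
        tssb = gene.start if gene.strand == "+" else gene.end - 1
        ttsb = gene.end - 1 if gene.strand == "+" else gene.start
        if L >= 2 * flank:
            n_tss = n_tts = flank
        else:
            # proximity split; exact tie to the lower-coordinate anchor
            n_tss = -(-L // 2) if tssb < ttsb else L // 2
            n_tts = L - n_tss

        def clip(a, b):
            return max(a, 0), min(b, clen)

        def emit(anchor, side, b, start, end, transcribed, anchor_pos):
            start, end = clip(start, end)
            if end > start:
                rows.append((gene.gene_id, gene.chrom, gene.strand, anchor, side,
                             b, start, end, transcribed, anchor_pos, 0))

        if gene.strand == "+":
            s, e = gene.start, gene.end
            for b in range(1, int(np.ceil(n_tss / W)) + 1):
                emit("TSS", "downstream", b, s + (b - 1) * W, min(s + b * W, s + n_tss), True, tssb)
            for b in range(1, int(np.ceil(n_tts / W)) + 1):
                emit("TTS", "upstream", b, max(e - b * W, e - n_tts), e - (b - 1) * W, True, ttsb)
            for b in range(1, nbins + 1):
                emit("TSS", "upstream", b, s - b * W, s - (b - 1) * W, False, tssb)
                emit("TTS", "downstream", b, e + (b - 1) * W, e + b * W, False, ttsb)
        else:
            s, e = gene.start, gene.end
            for b in range(1, int(np.ceil(n_tss / W)) + 1):
                emit("TSS", "downstream", b, max(e - b * W, e - n_tss), e - (b - 1) * W, True, tssb)
            for b in range(1, int(np.ceil(n_tts / W)) + 1):
                emit("TTS", "upstream", b, s + (b - 1) * W, min(s + b * W, s + n_tts), True, ttsb)
            for b in range(1, nbins + 1):
                emit("TSS", "upstream", b, e + (b - 1) * W, e + b * W, False, tssb)
                emit("TTS", "downstream", b, s - b * W, s - (b - 1) * W, False, ttsb)

    table = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    valid_t = {c: np.ones(n, dtype=bool) for c, n in lengths.items()}
    valid_u = {c: np.ones(n, dtype=bool) for c, n in lengths.items()}
    return WindowSet(table, valid_t, valid_u, W)


def resolve_intergenic_overlaps(ws: WindowSet) -> WindowSet:
    """Assign each untranscribed base to its nearest TSS/TTS anchor.

    Untranscribed flanks of neighbouring genes can overlap; every such base
    is kept only in the window whose anchor is nearest (exact ties go to the
    lower-coordinate anchor).  Window intervals are clipped to the resulting
    anchor cells; transcribed windows are untouched (they are always nearest
    to their own gene's anchors).
    """
    ws = ws.copy()
    tab = ws.table
    new_start = tab["start"].to_numpy().copy()
    new_end = tab["end"].to_numpy().copy()
    for chrom, sub in tab.groupby("chrom", sort=False):
        anchors = np.unique(sub["anchor_pos"].to_numpy())
        un = sub[~sub["transcribed"]]
        for idx, row in zip(un.index.to_numpy(), un.itertuples(index=False)):
            a = row.anchor_pos
            i = np.searchsorted(anchors, a)
            lo = -np.inf if i == 0 else (anchors[i - 1] + a) // 2 + 1
            hi = np.inf if i == len(anchors) - 1 else (a + anchors[i + 1]) // 2 + 1
            new_start[idx] = int(max(row.start, lo))
            new_end[idx] = int(min(row.end, hi))
    new_end = np.maximum(new_end, new_start)
    tab["start"], tab["end"] = new_start, new_end
    ws.recount()
    return ws


def exclude_multigene_transcription(ws: WindowSet, all_genes: pd.DataFrame) -> WindowSet:
    """Mask sites transcribed by more than one gene (any strand) everywhere,
    and sites transcribed by any gene from untranscribed windows.

    ``all_genes`` should include genes of excluded types: their transcribed
    spans still veto sites.
    """
    ws = ws.copy()
    for chrom in ws.chroms:
        cover = np.zeros(ws.chrom_len(chrom), dtype=np.int16)
        gsub = all_genes[all_genes.chrom == chrom]
        for gene in gsub.itertuples(index=False):
            cover[gene.start : gene.end] += 1
        ws.valid_t[chrom] &= cover < 2
        ws.valid_u[chrom] &= cover < 1
    ws.recount()
    return ws


def apply_site_masks(ws: WindowSet, mask: pd.DataFrame, mode: str = "subtract") -> WindowSet:
    """Apply a BED-style mask (chrom, start, end) to the valid-site masks.

    mode="subtract" clears masked bases; mode="intersect" keeps only masked
    bases.  Masks on unknown chromosomes are ignored with a warning.
    """
    import warnings

    if mode not in ("subtract", "intersect"):
        raise ValueError(f"unknown mode {mode!r}")
    ws = ws.copy()
    cov = {c: np.zeros(ws.chrom_len(c), dtype=bool) for c in ws.chroms}
    for iv in mask.itertuples(index=False):
        if iv.chrom not in cov:
            warnings.warn(f"mask interval on unknown chromosome {iv.chrom} ignored")
            continue
        cov[iv.chrom][max(0, iv.start) : iv.end] = True
    for chrom in ws.chroms:
        keep = ~cov[chrom] if mode == "subtract" else cov[chrom]
        ws.valid_t[chrom] &= keep
        ws.valid_u[chrom] &= keep
    ws.recount()
    return ws


def read_genes_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return genes


def write_windows_tsv(ws: WindowSet, path, mask_sidecar=None) -> None:
    """Write the window table; optionally a run-length-encoded valid-mask
    sidecar TSV (chrom, window_class, start, end of each invalid run)."""
    cols = ["gene_id", "anchor", "side", "bin", "chrom", "start", "end", "n_valid_sites"]
    ws.table[cols].to_csv(path, sep="\t", index=False)
    if mask_sidecar is not None:
        rows = []
        for chrom in ws.chroms:
            for label, mask in (("transcribed", ws.valid_t[chrom]),
                                ("untranscribed", ws.valid_u[chrom])):
                inv = ~mask
                if not inv.any():
                    continue
                edges = np.flatnonzero(np.diff(np.concatenate([[0], inv.view(np.int8), [0]])))
                for s, e in zip(edges[::2], edges[1::2]):
                    rows.append((chrom, label, int(s), int(e)))
        pd.DataFrame(rows, columns=["chrom", "window_class", "start", "end"]) \
            .to_csv(mask_sidecar, sep="\t", index=False)
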