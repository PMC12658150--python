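"""Transcription- and replication-strand stratified mutation densities.

A replication-direction map is called from a replication-timing profile:
maximal monotone runs of the smoothed profile, with per-step slope at
least ``min_slope`` and total span at least ``min_domain``, are assigned a
fork direction (by convention, timing decreasing with coordinate -- early
to late -- means a rightward-moving fork); everything else is unknown.
Whether the coding strand of a gene is the leading or lagging strand then
follows from the fork direction and the gene's orientation via a single
declared convention constant that can be flipped in configuration; the
package's tests pin only the involution symmetries, not the biological
sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contexts import assign_windows
from .genome import BASES, Genome
from .windows import WindowSet

# convention: rightward fork => plus-strand gene's coding strand is leading
_CONVENTION = {("rightward", "+"): "coding_leading", ("rightward", "-"): "coding_lagging",
               ("leftward", "+"): "coding_lagging", ("leftward", "-"): "coding_leading"}

# six representative mononucleotide types; the complementary type of each
# is its template-strand counterpart
STRAND_TYPES = ("A>G", "T>G", "A>T", "G>T", "C>G", "C>T")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def infer_replication_direction(timing: pd.DataFrame, min_domain: int = 250_000,
                                min_slope: float = 0.01, smooth_span: int = 50_000,
                                flip: bool = False) -> pd.DataFrame:
    """Fork-direction segments from a bedGraph-style timing profile.

    ``timing``: (chrom, start, end, value); values are taken at interval
    midpoints, smoothed with a moving average over ``smooth_span`` and
    segmented into monotone runs.  Returns (chrom, start, end, direction)
    with direction in {rightward, leftward, unknown} covering the profile.
    """
    rows = []
    for chrom, sub in timing.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        val = sub["value"].to_numpy(dtype=float)
        if len(mid) < 2 or mid[-1] - mid[0] < min_domain:
            rows.append((chrom, int(sub["start"].min()), int(sub["end"].max()), "unknown"))
            continue
        spacing = np.median(np.diff(mid))
        w = max(1, int(round(smooth_span / max(spacing, 1))))
        if w > 1:
            kernel = np.ones(w) / w
            val = np.convolve(np.pad(val, (w // 2, w - 1 - w // 2), mode="edge"),
                              kernel, mode="valid")
        slopes = np.diff(val) / np.maximum(np.diff(mid), 1)
        # slope sign per inter-point step; below-threshold steps break runs
        sign = np.sign(slopes) * (np.abs(slopes) >= min_slope)
        bounds = np.concatenate([[sub["start"].min()], (mid[:-1] + mid[1:]) // 2,
                                 [sub["end"].max()]])
        run_start = 0
        for i in range(1, len(sign) + 1):
            if i == len(sign) or sign[i] != sign[run_start]:
                seg_lo, seg_hi = int(bounds[run_start]), int(bounds[i])
                s = sign[run_start]
                if s != 0 and seg_hi - seg_lo >= min_domain:
                    d = "rightward" if s < 0 else "leftward"
                    if flip:
                        d = "leftward" if d == "rightward" else "rightward"
                else:
                    d = "unknown"
                rows.append((chrom, seg_lo, seg_hi, d))
                run_start = i
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    # merge adjacent unknowns for tidiness
    return out


def window_replication_category(ws: WindowSet, direction_map: pd.DataFrame,
                                flip: bool = False) -> pd.Series:
    """coding_leading / coding_lagging / unknown per window.

    Windows containing bases replicated in a mix of directions, or in an
    unknown direction, are unknown.
    """
    out = np.full(len(ws.table), "unknown", dtype=object)
    for chrom, sub in ws.table.groupby("chrom", sort=False):
        segs = direction_map[(direction_map.chrom == chrom)
                             & (direction_map.direction != "unknown")]
        starts = segs["start"].to_numpy()
        ends = segs["end"].to_numpy()
        dirs = segs["direction"].to_numpy()
        for idx, row in zip(sub.index.to_numpy(), sub.itertuples(index=False)):
            hit = (starts <= row.start) & (ends >= row.end)
            if hit.sum() == 1:
                d = dirs[np.flatnonzero(hit)[0]]
                if flip:
                    d = "leftward" if d == "rightward" else "rightward"
                out[idx] = _CONVENTION[(d, row.strand)]
    return pd.Series(out, index=ws.table.index, name="replication_category")


def strand_stratified_density(mutations: pd.DataFrame, ws: WindowSet, genome: Genome,
                              replication_category: pd.Series | None = None) -> pd.DataFrame:
    """Mononucleotide mutation densities per bin, type and strand.

    For each representative type (e.g. C>T), the coding-strand density is
    the count of coding-strand-oriented C>T mutations divided by the number
    of valid C sites on the coding strand; the template-strand density uses
    the complementary mutations and source bases.  With a replication
    category the tallies are additionally stratified by it.
    """
    tab = ws.table
    repcat = (replication_category if replication_category is not None
              else pd.Series("all", index=tab.index))
    muts = mutations.reset_index(drop=True)
    widx = assign_windows(muts, ws)
    keep = widx >= 0
    muts, widx = muts[keep].reset_index(drop=True), widx[keep]
    strands = tab["strand"].to_numpy()[widx]
    refs = muts["ref"].str.upper().to_numpy()
    alts = muts["alt"].str.upper().to_numpy()
    # orient to coding strand
    oref = np.where(strands == "+", refs, [ _COMP[r] for r in refs ])
    oalt = np.where(strands == "+", alts, [ _COMP[a] for a in alts ])

    # per-window oriented base counts over valid sites
    base_counts = np.zeros((len(tab), 4), dtype=np.int64)
    for (chrom, tr), sub in tab.groupby(["chrom", "transcribed"], sort=False):
        v = ws.valid_mask(chrom, tr)
        codes = genome.seqs[chrom]
        for i, b in enumerate(BASES):
            cs = np.concatenate([[0], np.cumsum((codes == i) & v)])
            s = sub["start"].to_numpy(); e = sub["end"].to_numpy()
            n = cs[e] - cs[s]
            plus = (sub["strand"] == "+").to_numpy()
            base_counts[sub.index.to_numpy()[plus], i] += n[plus]
            base_counts[sub.index.to_numpy()[~plus], 3 - i] += n[~plus]

    wkey = (tab["anchor"].astype(str) + "|" + tab["side"].astype(str) + "|"
            + tab["bin"].astype(str) + "|" + repcat.astype(str))
    mut_key = pd.Series([f"{r}>{a}" for r, a in zip(oref, oalt)])
    counts = pd.crosstab(wkey.to_numpy()[widx], mut_key.to_numpy())

    sites = pd.DataFrame(base_counts, columns=list(BASES)).groupby(wkey.to_numpy()).sum()
    rows = []
    for gk in sites.index:
        anchor, side, b, rc = gk.split("|")
        for t in STRAND_TYPES:
            r, a = t.split(">")
            comp_t = f"{_COMP[r]}>{_COMP[a]}"
            for strand_name, tname, src in (("coding", t, r), ("template", comp_t, _COMP[r])):
                n = counts.loc[gk, tname] if (gk in counts.index and tname in counts.columns) else 0
                s = sites.loc[gk, src]
                rows.append({"anchor": anchor, "side": side, "bin": int(b),
                             "replication_category": rc, "mut_type": t,
                             "strand": strand_name, "count": int(n), "sites": int(s),
                             "density": n / s if s > 0 else np.nan})
    return pd.DataFrame(rows)
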