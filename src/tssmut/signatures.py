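"""Abundance-rescaled NNLS decomposition of mutation profiles.

Mutation counts are pooled per window group into 96 pyrimidine-collapsed
trinucleotide channels (or 192 strand-resolved channels read on the coding
strand), rescaled so that windows with atypical trinucleotide composition
become comparable to whole-genome-derived signatures, and decomposed with
non-negative least squares.  Windows with too few mutations are flagged
ineligible, and eligible windows can be downsampled without replacement to
a common count so decomposition quality is comparable across windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import assign_windows
from .genome import BASES, Genome, code_to_kmer, revcomp_str
from .windows import WindowSet

PYRIMIDINES = ("C", "T")


@lru_cache(maxsize=None)
def channel_table(mode: int = 96) -> pd.DataFrame:
    """Channel labels (lexicographic) with context / alternate codes.

    For 96 channels the context is the pyrimidine-collapsed trinucleotide
    and codes refer to the orientation in which the central base is the
    pyrimidine; for 192 channels all central bases are kept (coding-strand
    resolved).
    """
    rows = []
    for five in BASES:
        for centre in (PYRIMIDINES if mode == 96 else BASES):
            for three in BASES:
                ctx = five + centre + three
                for alt in BASES:
                    if alt == centre:
                        continue
                    code = (BASES.index(five) * 16 + BASES.index(centre) * 4
                            + BASES.index(three))
                    rc = revcomp_str(ctx)
                    rc_code = (BASES.index(rc[0]) * 16 + BASES.index(rc[1]) * 4
                               + BASES.index(rc[2]))
                    rows.append({
                        "label": f"{five}[{centre}>{alt}]{three}",
                        "ctx": ctx, "ctx_code": code,
                        "alt_code": BASES.index(alt), "rc_ctx_code": rc_code,
                    })
    df = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)
    return df


def _channel_lookup(mode: int) -> np.ndarray:
    """(64, 4) -> channel row index for (plus-strand trinuc code, genomic alt);
    -1 for alt == central base."""
    chan = channel_table(mode)
    lut = np.full((64, 4), -1, dtype=np.int64)
    for i, row in chan.iterrows():
        lut[row.ctx_code, row.alt_code] = i
        if mode == 96:
            lut[row.rc_ctx_code, 3 - row.alt_code] = i
    return lut


def channel_profiles(mutations: pd.DataFrame, ws: WindowSet, genome: Genome,
                     mode: int = 96, group: str = "window") -> pd.DataFrame:
    """Pooled per-channel mutation counts, one column per window group.

    ``group="window"`` pools across genes by (anchor, side, bin).  In 96
    mode channels are strand-collapsed; in 192 mode mutations are read on
    the coding strand of the owning gene.
    """
    chan = channel_table(mode)
    lut = _channel_lookup(mode)
    muts = mutations.reset_index(drop=True)
    widx = assign_windows(muts, ws)
    keep = widx >= 0
    muts, widx = muts[keep].reset_index(drop=True), widx[keep]
    strands = ws.table["strand"].to_numpy()[widx]
    gkey = (ws.table["anchor"].astype(str) + "|" + ws.table["side"].astype(str)
            + "|" + ws.table["bin"].astype(str)).to_numpy()[widx]
    alts = muts["alt"].str.upper().map({b: i for i, b in enumerate(BASES)}).to_numpy()
    cidx = np.full(len(muts), -1, dtype=np.int64)
    for chrom, sub in muts.groupby("chrom", sort=False):
        i = sub.index.to_numpy()
        p = sub["pos"].to_numpy()
        if mode == 96:
            ctx = genome.context_codes(chrom, 3, "+")[p]
            ok = ctx >= 0
            cidx[i[ok]] = lut[ctx[ok], alts[i[ok]]]
        else:
            for s in "+-":
                sel = i[strands[i] == s]
                ctx = genome.context_codes(chrom, 3, s)[muts["pos"].to_numpy()[sel]]
                a = alts[sel] if s == "+" else 3 - alts[sel]
                ok = ctx >= 0
                cidx[sel[ok]] = lut[ctx[ok], a[ok]]
    ok = cidx >= 0
    out = pd.crosstab(pd.Series(cidx[ok], name="channel"),
                      pd.Series(gkey[ok], name="group"))
    out = out.reindex(range(len(chan)), fill_value=0)
    out.index = chan["label"]
    return out


def trinuc_abundances(ws: WindowSet, genome: Genome, mode: int = 96,
                      group: str = "window") -> tuple[pd.DataFrame, pd.Series]:
    """(per-group, whole-universe) trinucleotide site counts keyed by context.

    In 96 mode contexts are pyrimidine-collapsed (32 keys, counted on both
    strands of the reference); in 192 mode they are coding-strand trinucs
    (64 keys).
    """
    keys = sorted({(code_to_kmer(c, 3) if mode == 192 else _collapse(code_to_kmer(c, 3)))
                   for c in range(64)})
    key_of_code = np.array([keys.index(code_to_kmer(c, 3) if mode == 192
                                       else _collapse(code_to_kmer(c, 3)))
                            for c in range(64)])
    tab = ws.table
    gkeys = (tab["anchor"].astype(str) + "|" + tab["side"].astype(str)
             + "|" + tab["bin"].astype(str))
    groups = sorted(gkeys.unique())
    counts = np.zeros((len(keys), len(groups)))
    for (chrom, s, tr), ssub in tab.groupby(["chrom", "strand", "transcribed"],
                                            sort=False):
        v = ws.valid_mask(chrom, tr)
        ctx = genome.context_codes(chrom, 3, s if mode == 192 else "+")
        for row, gk in zip(ssub.itertuples(index=False), gkeys[ssub.index]):
            c = ctx[row.start:row.end][v[row.start:row.end]]
            c = c[c >= 0]
            counts[:, groups.index(gk)] += np.bincount(key_of_code[c], minlength=len(keys))
    per_group = pd.DataFrame(counts, index=keys, columns=groups)
    return per_group, per_group.sum(axis=1)


def _collapse(ctx: str) -> str:
    return ctx if ctx[1] in PYRIMIDINES else revcomp_str(ctx)


def rescale_profile(profile: pd.Series, window_abund: pd.Series,
                    reference_abund: pd.Series, mode: int = 96) -> pd.Series:
    """Scale each channel by reference/window trinucleotide abundance.

    Channels whose context is absent from the window must carry zero
    counts; they stay zero after rescaling.
    """
    chan = channel_table(mode)
    ctx_key = chan["ctx"] if mode == 192 else chan["ctx"].map(_collapse)
    wa = window_abund.reindex(ctx_key).to_numpy()
    ra = reference_abund.reindex(ctx_key).to_numpy()
    vals = profile.reindex(chan["label"]).fillna(0.0).to_numpy().astype(float)
    zero = (wa == 0) | np.isnan(wa)
    if np.any(zero & (vals > 0)):
        raise ValueError("nonzero counts in a channel with zero window abundance")
    out = np.zeros_like(vals)
    nz = ~zero
    out[nz] = vals[nz] * ra[nz] / wa[nz]
    return pd.Series(out, index=chan["label"].to_numpy(), name=profile.name)


@dataclass
class SignatureFit:
    weights: pd.Series        # raw NNLS weights, >= 0
    weights_norm: pd.Series   # normalized to sum 1 (all zero if empty fit)
    residual: float           # Euclidean norm of the residual
    fitted: np.ndarray        # S @ weights on the channel grid

    def density(self, total_mutations: float, n_sites: float) -> pd.Series:
        """Per-signature mutation density: weight * total / sites."""
        return self.weights_norm * total_mutations / n_sites


def nnls_fit(profile: pd.Series, signatures: pd.DataFrame) -> SignatureFit:
    """Non-negative least-squares decomposition onto signature columns."""
    S = signatures.reindex(profile.index)
    if S.isna().any().any():
        raise ValueError("signature matrix channels do not match the profile")
    A = S.to_numpy(dtype=float)
    y = profile.to_numpy(dtype=float)
    w, rnorm = nnls(A, y)
    weights = pd.Series(w, index=signatures.columns)
    total = weights.sum()
    norm = weights / total if total > 0 else weights * 0.0
    return SignatureFit(weights, norm, float(rnorm), A @ w)


def threshold_and_downsample(profiles: pd.DataFrame, min_mutations: int = 1000,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Keep windows with >= min_mutations and equalize their counts.

    Returns (downsampled eligible profiles, eligibility flags per window).
    Subsampling is without replacement down to the lowest eligible count.
    """
    totals = profiles.sum(axis=0)
    eligible = totals >= min_mutations
    if not eligible.any():
        return profiles.iloc[:, :0], eligible
    target = int(totals[eligible].min())
    rng = np.random.default_rng(seed)
    out = {}
    for col in profiles.columns[eligible]:
        counts = profiles[col].to_numpy().astype(np.int64)
        if counts.sum() == target:
            out[col] = counts
        else:
            out[col] = rng.multivariate_hypergeometric(counts, target)
    return pd.DataFrame(out, index=profiles.index), eligible


def aggregate_minor_weights(weights: pd.Series, cutoff: float = 0.05) -> pd.Series:
    """Collapse signatures with weight < cutoff into an 'Others' entry."""
    minor = weights[weights < cutoff]
    major = weights[weights >= cutoff]
    out = major.copy()
    out.loc["Others"] = float(minor.sum())
    return out


def background_subtract(profile: pd.Series, signatures: pd.DataFrame,
                        background: list[str]) -> tuple[pd.Series, float]:
    """Remove the NNLS-fitted contribution of background signatures.

    The residual is floored at zero per channel; returns (residual, the
    fraction of the fitted background mass removed by flooring).
    """
    fit = nnls_fit(profile, signatures[background])
    resid = profile.to_numpy(dtype=float) - fit.fitted
    floored = -resid[resid < 0].sum()
    resid = np.maximum(resid, 0.0)
    frac = floored / max(profile.sum(), 1e-300)
    return pd.Series(resid, index=profile.index), float(frac)


def read_signatures_tsv(path) -> pd.DataFrame:
    """Signature matrix TSV: first column channel labels, one column per
    signature, columns sum to 1 over channels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df
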