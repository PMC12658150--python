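"""TSS vs non-TSS mutation-rate-ratio tests for gene sets and single genes.

Observed and expected mutation counts are pooled over the first window
upstream and downstream of the TSS ("TSS") versus every other window in
the study including TTS-anchored ones ("rest").  The two Poisson rates are
compared with an exact conditional binomial test: given n = x_tss +
x_rest, x_tss ~ Binomial(n, E_tss/(E_tss+E_rest)) under a rate ratio of 1,
with the two-sided p-value from the minimum-likelihood method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pool_tss_vs_rest(density: pd.DataFrame, genes=None, tss_bins: int = 1):
    """(x_tss, E_tss, x_rest, E_rest) pooled over the gene subset.

    The TSS pool is the TSS-anchored bins 1..tss_bins on both sides; the
    rest pool is every other window row.
    """
    d = density if genes is None else density[density["gene_id"].isin(list(genes))]
    is_tss = (d["anchor"] == "TSS") & (d["bin"] <= tss_bins)
    x1 = float(d.loc[is_tss, "observed"].sum())
    e1 = float(d.loc[is_tss, "expected"].sum())
    x2 = float(d.loc[~is_tss, "observed"].sum())
    e2 = float(d.loc[~is_tss, "expected"].sum())
    return x1, e1, x2, e2


def exact_rate_ratio_test(x1: float, e1: float, x2: float, e2: float,
                          method: str = "minlik") -> float:
    """Two-sided exact conditional test of rate ratio 1 between two Poisson
    counts with known exposures.

    ``minlik`` sums the probabilities of all outcomes no more likely than
    the observed one; ``central`` doubles the smaller tail.
    """
    x1, x2 = int(round(x1)), int(round(x2))
    n = x1 + x2
    if n < 1:
        raise ValueError("x1 + x2 must be >= 1")
    if e1 + e2 <= 0:
        raise ValueError("E1 + E2 must be > 0")
    p0 = e1 / (e1 + e2)
    if method == "minlik":
        return float(stats.binomtest(x1, n, p0, alternative="two-sided").pvalue)
    if method == "central":
        lo = stats.binom.cdf(x1, n, p0)
        hi = stats.binom.sf(x1 - 1, n, p0)
        return float(min(1.0, 2 * min(lo, hi)))
    raise ValueError(f"unknown method {method!r}")


def rate_ratio(x1, e1, x2, e2) -> float:
    """(x1/E1)/(x2/E2); NaN when undefined (x2 == 0 or E1 == 0)."""
    if x2 == 0 or e1 == 0 or e2 == 0:
        return float("nan")
    return (x1 / e1) / (x2 / e2)


def geneset_scan(terms: pd.DataFrame, density: pd.DataFrame, max_genes: int = 100,
                 adjust: str = "bonferroni", tss_bins: int = 1) -> pd.DataFrame:
    """Rate-ratio test per term (term_id, term_name, gene_id rows).

    Terms with more than ``max_genes`` intersecting study genes are
    skipped; p-values are Bonferroni-adjusted over the tested terms.
    """
    study_genes = set(density["gene_id"])
    rows = []
    for (tid, tname), sub in terms.groupby(["term_id", "term_name"], sort=False):
        gset = set(sub["gene_id"]) & study_genes
        if len(gset) == 0 or len(gset) > max_genes:
            continue
        x1, e1, x2, e2 = pool_tss_vs_rest(density, gset, tss_bins)
        if x1 + x2 < 1 or e1 + e2 <= 0:
            continue
        rows.append({"term_id": tid, "term_name": tname, "n_genes": len(gset),
                     "x_tss": x1, "E_tss": e1, "x_rest": x2, "E_rest": e2,
                     "ratio": rate_ratio(x1, e1, x2, e2),
                     "p": exact_rate_ratio_test(x1, e1, x2, e2)})
    out = pd.DataFrame(rows)
    if len(out):
        if adjust == "bonferroni":
            out["p_adj"] = np.minimum(1.0, out["p"] * len(out))
        else:
            out["p_adj"] = out["p"]
        out = out.sort_values("p_adj").reset_index(drop=True)
    return out


def per_gene_scan(density: pd.DataFrame, fdr_q: float = 0.01,
                  tss_bins: int = 1) -> pd.DataFrame:
    """Per-gene TSS vs rest rate ratio with Benjamini-Hochberg control.

    The background is restricted to genes with mutation chances both at
    the TSS and elsewhere and a positive non-TSS mutation count (the genes
    for which the ratio is defined).
    """
    rows = []
    for gid, sub in density.groupby("gene_id", sort=False):
        x1, e1, x2, e2 = pool_tss_vs_rest(sub, None, tss_bins)
        if e1 <= 0 or e2 <= 0 or x2 == 0:
            continue
        rows.append({"gene_id": gid, "x_tss": x1, "E_tss": e1, "x_rest": x2,
                     "E_rest": e2, "ratio": rate_ratio(x1, e1, x2, e2),
                     "p": exact_rate_ratio_test(x1, e1, x2, e2)})
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
        out["significant"] = out["q"] < fdr_q
        out = out.sort_values("q").reset_index(drop=True)
    return out
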