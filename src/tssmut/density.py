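"""Relative mutation densities per gene and window, with bootstrap CIs.

Per gene ``t`` and window ``b``: ``mu_tb = observed / expected`` (expected
from the context matrix), weight ``w_tb = n_valid_sites / W``, per-gene
ratio ``g_t = sum(observed) / sum(expected)`` over all considered regions
of the gene, and ``mu'_tb = mu_tb / g_t`` which removes regional rate
variation.  Bin-level summaries are weighted means across genes; their
sampling variability is assessed by resampling genes with replacement
(carrying each gene's mutations) and taking percentile intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowSet

BIN_KEY = ["anchor", "side", "bin"]


def gene_window_density(observed, expected):
    """mu_tb = observed / expected; NaN where the expectation is zero."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = observed / expected
    mu[expected <= 0] = np.nan
    return mu


def density_table(ws: WindowSet, observed, expected) -> pd.DataFrame:
    """One row per gene x window with mu, w, g_t and mu'.

    Windows with zero expectation carry weight 0 and NaN densities; genes
    whose total expectation is zero are dropped (reported via attrs).
    """
    df = ws.table[["gene_id"] + BIN_KEY + ["n_valid_sites"]].copy()
    df["observed"] = np.asarray(observed, dtype=float)
    df["expected"] = np.asarray(expected, dtype=float)
    df["w"] = df["n_valid_sites"] / ws.width
    df.loc[df["expected"] <= 0, "w"] = 0.0
    df["mu"] = gene_window_density(df["observed"], df["expected"])
    totals = df.groupby("gene_id")[["observed", "expected"]].sum()
    g = gene_ratio(totals)
    excluded = list(g.index[~np.isfinite(g)])
    df = df[~df["gene_id"].isin(excluded)].reset_index(drop=True)
    df["g_t"] = df["gene_id"].map(g)
    df["mu_prime"] = df["mu"] / df["g_t"]
    df.attrs["excluded_genes"] = excluded
    return df


def gene_ratio(totals: pd.DataFrame) -> pd.Series:
    """g_t = total observed / total expected per gene (Eq. 4)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        g = totals["observed"] / totals["expected"]
    g[totals["expected"] <= 0] = np.nan
    return g


def aggregate_bin(df: pd.DataFrame, value: str = "mu_prime") -> pd.DataFrame:
    """Weighted mean of mu (or mu') per window key (Eq. 3)."""
    d = df[np.isfinite(df[value]) & (df["w"] > 0)]
    num = (d[value] * d["w"]).groupby([d[k] for k in BIN_KEY]).sum()
    den = d.groupby(BIN_KEY)["w"].sum()
    n = d.groupby(BIN_KEY)["gene_id"].nunique()
    out = pd.DataFrame({"point": num / den, "n_genes": n}).reset_index()
    return out


def bootstrap_bins(df: pd.DataFrame, B: int = 100, level: float = 90.0,
                   seed: int = 0, value: str = "mu_prime") -> pd.DataFrame:
    """Gene-resampling bootstrap of the per-bin weighted means.

    Returns one row per window key with the plug-in estimate, the bootstrap
    mean (the plotted point), percentile CI bounds at the requested level
    and the bootstrap standard error.  Replicates in which a bin has zero
    total weight contribute no value to that bin.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    d = df[np.isfinite(df[value]) & (df["w"] > 0)]
    key = d[BIN_KEY].astype(str).agg("|".join, axis=1)
    keys, kidx = np.unique(key.to_numpy(), return_inverse=True)
    genes, gidx = np.unique(d["gene_id"].to_numpy(), return_inverse=True)
    # accumulate per (gene, key): several window rows may share a key
    VW = np.zeros((len(genes), len(keys)))
    Wt = np.zeros_like(VW)
    np.add.at(VW, (gidx, kidx), d[value].to_numpy() * d["w"].to_numpy())
    np.add.at(Wt, (gidx, kidx), d["w"].to_numpy())

    rng = np.random.default_rng(seed)
    reps = np.empty((B, len(keys)))
    for r in range(B):
        cnt = np.bincount(rng.integers(0, len(genes), size=len(genes)),
                          minlength=len(genes)).astype(float)
        num = cnt @ VW
        den = cnt @ Wt
        with np.errstate(invalid="ignore", divide="ignore"):
            reps[r] = num / den
        reps[r, den <= 0] = np.nan
    lo_q, hi_q = (100.0 - level) / 2.0, 100.0 - (100.0 - level) / 2.0
    plug = aggregate_bin(df, value=value).set_index(BIN_KEY)
    rows = []
    for j, k in enumerate(keys):
        anchor, side, b = k.split("|")
        col = reps[:, j]
        col = col[np.isfinite(col)]
        rows.append({
            "anchor": anchor, "side": side, "bin": int(b),
            "point": np.mean(col) if len(col) else np.nan,
            "plugin": plug.loc[(anchor, side, int(b)), "point"],
            "ci_low": np.percentile(col, lo_q) if len(col) else np.nan,
            "ci_high": np.percentile(col, hi_q) if len(col) else np.nan,
            "se": np.std(col, ddof=1) if len(col) > 1 else np.nan,
            "n_replicates": len(col),
        })
    return pd.DataFrame(rows).sort_values(BIN_KEY).reset_index(drop=True)


def bracket_labels(df: pd.DataFrame, edges=((1, 1), (2, 5), (6, 50)),
                   anchor: str = "TSS") -> pd.Series:
    """Label each TSS-anchored window row with its side-specific bin bracket,
    e.g. 'downstream[2,5]'.  Rows outside the brackets or anchored elsewhere
    get NaN."""
    lab = pd.Series(np.nan, index=df.index, dtype=object)
    for lo, hi in edges:
        name = f"[{lo}]" if lo == hi else f"[{lo},{hi}]"
        sel = (df["anchor"] == anchor) & (df["bin"] >= lo) & (df["bin"] <= hi)
        lab[sel] = df.loc[sel, "side"] + name
    return lab


def pooled_rate_model(brackets, observed, expected, alpha: float = 0.05) -> pd.DataFrame:
    """Interceptless log-linear Poisson rate model with a log-expected offset.

    The maximum-likelihood coefficient for each bracket of windows has the
    closed form ``ln(sum obs / sum exp)`` with standard error
    ``1/sqrt(sum obs)``; the function solves the model analytically and
    reports the exponentiated rate ratio, normal-theory two-sided p-value
    for coefficient == 0, and the exponentiated 95% CI.  Brackets with zero
    observed counts are flagged and get an exact Poisson upper bound.
    """
    df = pd.DataFrame({"bracket": brackets, "obs": observed, "exp": expected}).dropna(subset=["bracket"])
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for name, g in df.groupby("bracket"):
        o, e = g["obs"].sum(), g["exp"].sum()
        if e <= 0:
            continue
        if o > 0:
            coef = np.log(o / e)
            se = 1.0 / np.sqrt(o)
            zval = coef / se
            p = 2 * stats.norm.sf(abs(zval))
            lo, hi = np.exp(coef - z * se), np.exp(coef + z * se)
            flagged = False
        else:
            coef, se, zval, p = -np.inf, np.nan, np.nan, np.nan
            lo = 0.0
            hi = stats.chi2.ppf(1 - alpha / 2, 2) / 2 / e  # exact Poisson bound
            flagged = True
        rows.append({"bracket": name, "n_obs": o, "n_exp": e,
                     "coef": coef, "se": se, "ratio": np.exp(coef),
                     "z": zval, "p": p, "ci_low": lo, "ci_high": hi,
                     "zero_flagged": flagged})
    return pd.DataFrame(rows)
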