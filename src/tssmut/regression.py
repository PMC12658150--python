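"""Count-model regression of window mutation counts on genomic features.

The design is ``X = [1  A  B  C]``: dummy-coded / standardized feature
columns A, sum-coded position categories B (K-1 columns; the omitted
category's coefficients are minus the sum of the included ones), and all
pairwise feature x position interaction products C.  The response is the
observed mutation count per window with the log expected count as offset,
fitted by Poisson or negative-binomial (ML dispersion) regression.
Position-specific effects are tested as linear combinations of
coefficients with single-step max-|z| family-wise adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial


@dataclass
class DesignSpec:
    columns: list[str]
    feature_cols: dict[str, list[str]]      # feature -> encoded A columns
    numeric_cols: list[str]
    position_categories: list[str]          # all K labels; last is omitted
    position_cols: list[str]                # K-1 sum-coded B columns
    interaction_cols: dict[tuple[str, str], str] = field(default_factory=dict)
    # (A column, non-omitted category) -> C column
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def omitted_category(self) -> str | None:
        return self.position_categories[-1] if self.position_categories else None

    def interaction_vector(self, a_col: str, category: str) -> pd.Series:
        """Coefficient vector extracting the interaction effect of `a_col`
        in `category` (handles the omitted sum-coded category)."""
        v = pd.Series(0.0, index=self.columns)
        if category == self.omitted_category:
            for cat in self.position_categories[:-1]:
                v[self.interaction_cols[(a_col, cat)]] = -1.0
        else:
            v[self.interaction_cols[(a_col, category)]] = 1.0
        return v


def build_design(features: pd.DataFrame, position: pd.Series | None = None,
                 interactions: bool = True, standardize: bool = True):
    """Encode the feature table into the regression design matrix.

    Rows with any missing value are dropped first; non-categorical columns
    are mean-centred and variance-scaled (after the drop, before forming
    interaction products).  Categorical features are dummy-coded against
    their first (sorted) label; position categories are sum-coded on K-1
    columns.  Returns (DesignSpec, X DataFrame, kept row index).
    """
    df = features.copy()
    keep = df.notna().all(axis=1)
    if position is not None:
        keep &= position.notna()
        position = position[keep]
    df = df[keep]
    spec_std: dict[str, tuple[float, float]] = {}
    acols: dict[str, list[str]] = {}
    numeric: list[str] = []
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for name in df.columns:
        col = df[name]
        if col.dtype.kind in "biufc" and col.dtype.kind != "b":
            v = col.astype(float)
            if standardize:
                mu, sd = v.mean(), v.std(ddof=0)
                if sd == 0:
                    warnings.warn(f"constant feature {name!r} dropped")
                    continue
                spec_std[name] = (mu, sd)
                v = (v - mu) / sd
            elif v.nunique() < 2:
                warnings.warn(f"constant feature {name!r} dropped")
                continue
            X[name] = v
            acols[name] = [name]
            numeric.append(name)
        else:
            labels = sorted(col.astype(str).unique())
            if len(labels) < 2:
                warnings.warn(f"single-label categorical feature {name!r} dropped")
                continue
            for lab in labels[1:]:
                cn = f"{name}[{lab}]"
                X[cn] = (col.astype(str) == lab).astype(float)
                acols.setdefault(name, []).append(cn)
    pos_cats: list[str] = []
    pos_cols: list[str] = []
    inter: dict[tuple[str, str], str] = {}
    if position is not None:
        pos_cats = sorted(position.astype(str).unique())
        omitted = pos_cats[-1]
        p = position.astype(str)
        for cat in pos_cats[:-1]:
            cn = f"pos[{cat}]"
            X[cn] = np.where(p == cat, 1.0, np.where(p == omitted, -1.0, 0.0))
            pos_cols.append(cn)
        if interactions:
            for f, cols in acols.items():
                for ac in cols:
                    for cat, bc in zip(pos_cats[:-1], pos_cols):
                        cn = f"{ac}:{cat}"
                        X[cn] = X[ac] * X[bc]
                        inter[(ac, cat)] = cn
    spec = DesignSpec(list(X.columns), acols, numeric, pos_cats, pos_cols,
                      inter, spec_std)
    return spec, X, df.index


@dataclass
class FitResult:
    params: pd.Series
    cov: pd.DataFrame
    family: str
    alpha: float | None        # NB dispersion; None for Poisson
    mu: np.ndarray             # fitted means (offset included)
    y: np.ndarray
    df_resid: int
    converged: bool


def fit_count_model(X: pd.DataFrame, y, offset, family: str = "negative_binomial",
                    maxiter: int = 1000) -> FitResult:
    """Maximum-likelihood Poisson or negative-binomial fit with log offset.

    Non-convergence raises; the NB dispersion is estimated jointly with the
    coefficients.
    """
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite (drop windows with zero expectation)")
    if family == "poisson":
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(maxiter=maxiter)
        if not res.converged:
            raise RuntimeError("Poisson regression did not converge")
        params = res.params
        cov = res.cov_params()
        alpha = None
        mu = res.mu
    elif family in ("negative_binomial", "nb"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = NegativeBinomial(y, X, offset=offset)
            res = mod.fit(maxiter=maxiter, disp=0)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("negative-binomial regression did not converge")
        params = res.params.drop("alpha")
        cov = res.cov_params().drop(index="alpha", columns="alpha")
        alpha = float(res.params["alpha"])
        mu = np.exp(X.to_numpy() @ params.to_numpy() + offset)
    else:
        raise ValueError(f"unknown family {family!r}")
    return FitResult(params, cov, family, alpha, np.asarray(mu), y,
                     len(y) - X.shape[1], True)


def dispersion_diagnostic(fit: FitResult, bounds=(0.7, 1.5)):
    """Pearson chi-square / df with an over/under-dispersion flag."""
    var = fit.mu if fit.alpha is None else fit.mu + fit.alpha * fit.mu ** 2
    stat = float(np.sum((fit.y - fit.mu) ** 2 / np.maximum(var, 1e-300))
                 / max(fit.df_resid, 1))
    lo, hi = bounds
    flag = "overdispersed" if stat > hi else "underdispersed" if stat < lo else "ok"
    return stat, flag


def _gvif_table(X: pd.DataFrame, groups: dict[str, list[str]], exponent: str) -> pd.Series:
    cols = [c for cs in groups.values() for c in cs]
    Z = X[cols].to_numpy()
    R = np.corrcoef(Z, rowvar=False)
    if R.ndim == 0:
        R = np.array([[1.0]])
    det_all = np.linalg.det(R)
    out = {}
    idx = {c: i for i, c in enumerate(cols)}
    for f, cs in groups.items():
        ii = [idx[c] for c in cs]
        jj = [i for i in range(len(cols)) if i not in ii]
        d1 = np.linalg.det(np.atleast_2d(R[np.ix_(ii, ii)]))
        d2 = np.linalg.det(np.atleast_2d(R[np.ix_(jj, jj)])) if jj else 1.0
        gvif = np.inf if det_all <= 0 else d1 * d2 / det_all
        df = len(cs)
        power = 1.0 / df if exponent == "paper" else 1.0 / (2 * df)
        out[f] = gvif ** power if np.isfinite(gvif) else np.inf
    return pd.Series(out)


def gvif_filter(features: pd.DataFrame, threshold: float = 5.0,
                exponent: str = "paper"):
    """Iteratively drop the feature with the largest generalized VIF.

    The GVIF is computed on a no-interaction design from the determinant
    ratio of the column correlation matrix, taken to the power 1/df
    (``exponent="paper"``) or 1/(2 df) (``exponent="conventional"``), and
    the maximum is removed until none exceeds the threshold.  Returns
    (retained feature names, per-iteration log).
    """
    spec, X, _ = build_design(features, position=None, interactions=False,
                              standardize=False)
    groups = dict(spec.feature_cols)
    log_rows = []
    it = 0
    while True:
        if not groups:
            raise ValueError("all features removed by the GVIF filter")
        if len(groups) == 1:
            break
        g = _gvif_table(X, groups, exponent).sort_index()
        for f, v in g.items():
            log_rows.append({"iteration": it, "feature": f, "gvif_adj": v,
                             "removed": False})
        if g.max() > threshold:
            worst = g[g == g.max()].index.sort_values()[0]
            log_rows[-len(g) + list(g.index).index(worst)]["removed"] = True
            del groups[worst]
            it += 1
        else:
            break
    return list(groups), pd.DataFrame(log_rows)


def contrast_tests(fit: FitResult, contrasts: pd.DataFrame,
                   adjust: str = "single_step_maxz", alpha: float = 0.05,
                   seed: int = 0, draws: int = 500_000) -> pd.DataFrame:
    """z-tests of linear combinations of coefficients with FWER control.

    ``contrasts``: one row per hypothesis, columns a subset of the fitted
    coefficient names.  ``single_step_maxz`` adjusts with the distribution
    of the maximum absolute component of a joint normal with the contrasts'
    correlation matrix (Monte-Carlo, seeded); adjusted CIs use the
    corresponding critical value.
    """
    C = contrasts.reindex(columns=fit.params.index, fill_value=0.0)
    est = C.to_numpy() @ fit.params.to_numpy()
    V = C.to_numpy() @ fit.cov.to_numpy() @ C.to_numpy().T
    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    z = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    m = len(est)
    if adjust == "none" or m == 1:
        p_adj = p
        crit = stats.norm.ppf(1 - alpha / 2)
    elif adjust == "bonferroni":
        p_adj = np.minimum(1.0, p * m)
        crit = stats.norm.ppf(1 - alpha / (2 * m))
    elif adjust == "single_step_maxz":
        with np.errstate(invalid="ignore", divide="ignore"):
            R = V / np.outer(se, se)
        R[~np.isfinite(R)] = 0.0
        np.fill_diagonal(R, 1.0)
        try:
            evals, evecs = np.linalg.eigh(R)
            if np.min(evals) < -1e-8:
                raise np.linalg.LinAlgError
            L = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0)))
        except np.linalg.LinAlgError:
            warnings.warn("singular contrast covariance; falling back to componentwise")
            p_adj = p
            crit = stats.norm.ppf(1 - alpha / 2)
            return _contrast_frame(contrasts.index, est, se, z, p, p_adj, crit)
        rng = np.random.default_rng(seed)
        maxabs = np.empty(draws)
        chunk = 100_000
        done = 0
        while done < draws:
            n = min(chunk, draws - done)
            Z = rng.standard_normal((n, m)) @ L.T
            maxabs[done:done + n] = np.abs(Z).max(axis=1)
            done += n
        p_adj = np.array([(maxabs >= abs(zi)).mean() if np.isfinite(zi) else np.nan
                          for zi in z])
        p_adj = np.maximum(p_adj, np.finfo(float).tiny)
        crit = float(np.quantile(maxabs, 1 - alpha))
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return _contrast_frame(contrasts.index, est, se, z, p, p_adj, crit)


def _contrast_frame(names, est, se, z, p, p_adj, crit) -> pd.DataFrame:
    return pd.DataFrame({
        "estimate": est, "se": se, "z": z, "p": p, "p_adj": p_adj,
        "ci_low": est - crit * se, "ci_high": est + crit * se,
        "pct_change": 100.0 * (np.exp(est) - 1.0),
    }, index=names)


def tss_effect_contrasts(spec: DesignSpec, pairs: dict | None = None,
                         total: bool = True) -> pd.DataFrame:
    """Contrast vectors comparing TSS and far interaction effects per side,
    plus the total (main + TSS interaction) effect of each feature.

    ``pairs`` maps a side label to its (TSS category, far category); by
    default inferred from category names of the form ``<side>_TSS`` /
    ``<side>_far``.
    """
    if pairs is None:
        pairs = {}
        for cat in spec.position_categories:
            if cat.endswith("_TSS"):
                side = cat[:-4]
                far = f"{side}_far"
                if far in spec.position_categories:
                    pairs[side] = (cat, far)
        if not pairs:
            raise ValueError("cannot infer TSS/far category pairs; pass `pairs`")
    rows = {}
    for feat, cols in spec.feature_cols.items():
        for ac in cols:
            for side, (tss_cat, far_cat) in pairs.items():
                v = spec.interaction_vector(ac, tss_cat) - spec.interaction_vector(ac, far_cat)
                rows[f"{ac}|{side}|TSS-far"] = v
                if total:
                    t = spec.interaction_vector(ac, tss_cat)
                    t[ac] += 1.0
                    rows[f"{ac}|{side}|total@TSS"] = t
    return pd.DataFrame(rows).T
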