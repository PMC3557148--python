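"""Linear-model differential expression with quality compensation.

Gene-wise (weighted) least squares on the log2 expression matrix, with
empirical-Bayes moderation of the residual variances (shrinkage toward a
common prior, scaled-inverse-chi-square model) and Benjamini-Hochberg
adjustment. Five strategies for handling variable array quality are
provided: per-array quality weights, exclusion of flagged arrays,
empirical-Bayes location/scale adjustment of the data itself, quality and
batch as fixed covariates, and surrogate-variable covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .core import Config, QCReport, SampleMetadata, StqcError

STRATEGIES = ("weights", "exclude", "combat", "covariate", "sva")

CONTRAST = "condition_tumour"


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def base_design(metadata: SampleMetadata, arrays=None) -> pd.DataFrame:
    """Intercept + tumour indicator; the contrast of interest is the
    tumour - normal difference (column ``condition_tumour``)."""
    idx = pd.Index(arrays) if arrays is not None else pd.Index(metadata.array_ids)
    cond = metadata.condition.reindex(idx)
    return pd.DataFrame(
        {"intercept": 1.0, CONTRAST: (cond == "tumour").astype(float)}, index=idx
    )


def add_factor(design: pd.DataFrame, values: pd.Series, prefix: str) -> pd.DataFrame:
    """Append treatment-coded dummies for a categorical factor."""
    vals = values.reindex(design.index)
    levels = sorted(pd.unique(vals.astype(str)))
    out = design.copy()
    for lev in levels[1:]:
        out[f"{prefix}_{lev}"] = (vals.astype(str) == lev).astype(float)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class LMFit:
    """Gene-wise least-squares fit shared by all strategies."""

    coef: pd.DataFrame  # genes x terms
    s2: pd.Series  # residual variance per gene
    df_resid: int
    cov_unscaled: pd.DataFrame  # (X'WX)^-1, terms x terms
    mean_expr: pd.Series


def fit_lm(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    weights: pd.Series | None = None,
) -> LMFit:
    """Per-gene (weighted) least squares with a common design.

    ``weights`` are per-array precision factors (var = sigma_g^2 / w_j);
    unit or absent weights reduce exactly to OLS.
    """
    X = design.reindex(expr.columns).to_numpy(float)
    if np.isnan(X).any():
        raise StqcError("design rows do not cover all expression columns")
    n, p = X.shape
    if n <= p:
        raise StqcError("need more arrays than design terms")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name a collinear term via QR pivoting
        _, R = np.linalg.qr(X)
        small = np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max()
        bad = [design.columns[i] for i in np.flatnonzero(small)] or list(design.columns)
        raise StqcError(f"design is rank deficient; collinear terms include {bad}")
    w = (
        np.ones(n)
        if weights is None
        else weights.reindex(expr.columns).to_numpy(float)
    )
    if (w <= 0).any() or np.isnan(w).any():
        raise StqcError("array weights must be positive for all arrays")
    Y = expr.to_numpy(float)
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)
    beta = Y @ Xw @ XtWX_inv.T  # genes x terms
    resid = Y - beta @ X.T
    s2 = (resid**2 * w[None, :]).sum(axis=1) / (n - p)
    return LMFit(
        coef=pd.DataFrame(beta, index=expr.index, columns=design.columns),
        s2=pd.Series(s2, index=expr.index, name="s2"),
        df_resid=n - p,
        cov_unscaled=pd.DataFrame(
            XtWX_inv, index=design.columns, columns=design.columns
        ),
        mean_expr=expr.mean(axis=1),
    )


def estimate_array_weights(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> pd.Series:
    """Per-array quality weights from a heteroscedastic gene-wise model.

    Assumes var(eps_gj) = sigma_g^2 / w_j and alternates gene-wise WLS
    with a leverage-corrected moment update of the array variance
    factors; weights are normalised to geometric mean 1 (so their product
    is 1). Non-convergence yields the last iterate with a warning rather
    than an error.
    """
    import warnings

    X = design.reindex(expr.columns).to_numpy(float)
    n, p = X.shape
    if n < 3:
        raise StqcError("need >= 3 arrays to estimate array weights")
    Y = expr.to_numpy(float)
    w = np.ones(n)
    for _ in range(max_iter):
        Xw = X * w[:, None]
        XtWX_inv = np.linalg.inv(X.T @ Xw)
        beta = Y @ Xw @ XtWX_inv
        resid = Y - beta @ X.T
        s2 = (resid**2 * w[None, :]).sum(axis=1) / (n - p)
        s2 = np.maximum(s2, 1e-12)
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, Xw)  # leverages of W-hat matrix
        v = (resid**2 / s2[:, None]).mean(axis=0) / np.maximum(1 - h, 1e-6)
        w_new = 1.0 / np.maximum(v, 1e-9)
        w_new /= np.exp(np.mean(np.log(w_new)))
        delta = np.max(np.abs(w_new - w) / w)
        w = w_new
        if delta < tol:
            break
    else:
        warnings.warn("array weight estimation did not converge; using last iterate")
    return pd.Series(w, index=expr.columns, name="array_weight")


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square prior on the
    gene variances, on the log scale (digamma/trigamma matching).

    Returns (prior_df d0, prior_variance s0^2); d0 = inf means all
    residual variances are consistent with a single common value.
    """
    s2 = np.asarray(s2, float)
    if np.max(s2) <= 1e-25:
        raise StqcError("all residual variances are zero")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    resid_var = evar - special.polygamma(1, df / 2.0)
    if resid_var <= 0:
        # no excess spread beyond chi-square sampling: a single common
        # variance, estimated by the plain mean
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(resid_var)
    s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def ebayes_moderate(
    fit: LMFit,
    contrast: str = CONTRAST,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics for one contrast.

    Posterior variance s~_g^2 = (d0*s0^2 + d_g*s_g^2)/(d0 + d_g);
    t = beta / (s~_g * sqrt(v)) on d0 + d_g degrees of freedom.
    ``prior_df=0`` disables shrinkage (ordinary t).
    """
    if len(fit.s2) < 10 and prior_df is None:
        raise StqcError("need >= 10 genes to estimate the variance prior")
    s2 = fit.s2.to_numpy(float)
    d = fit.df_resid
    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, d)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    # total df cannot exceed the pooled residual df of all genes
    df_total = min(df_total, len(s2) * d)
    v = float(fit.cov_unscaled.loc[contrast, contrast])
    beta = fit.coef[contrast].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / (np.sqrt(s2_post) * np.sqrt(v))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2fc": beta,
            "t": t,
            "p": p,
            "mean_expr": fit.mean_expr.to_numpy(float),
        },
        index=fit.coef.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise StqcError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------


def de_table(fit: LMFit, contrast: str = CONTRAST) -> pd.DataFrame:
    """Moderated test + BH adjustment, sorted stays in gene order."""
    out = ebayes_moderate(fit, contrast)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out.index.name = "cluster_id"
    return out


def run_strategy(
    strategy: str,
    expr: pd.DataFrame,
    report: QCReport,
    metadata: SampleMetadata,
    config: Config | None = None,
    sv: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differential expression (tumour - normal) under one quality
    strategy. ``expr`` is assumed batch-corrected upstream; the combat
    strategy additionally adjusts it for the quality categories here.
    """
    from . import batch_adjust

    cfg = config or Config()
    if strategy not in STRATEGIES:
        raise StqcError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    arrays = list(expr.columns)
    flagged = report.table["flagged"].reindex(arrays)
    X = base_design(metadata, arrays)

    if strategy == "weights":
        w = estimate_array_weights(expr, X)
        fit = fit_lm(expr, X, weights=w)
    elif strategy == "exclude":
        keep = [a for a in arrays if not flagged[a]]
        cond = metadata.condition.reindex(keep)
        if min((cond == "tumour").sum(), (cond == "normal").sum()) < 3:
            raise StqcError("excluding flagged arrays leaves < 3 arrays per group")
        fit = fit_lm(expr[keep], base_design(metadata, keep))
    elif strategy == "combat":
        quality = pd.Series(
            np.where(flagged, "flagged", "passed"), index=flagged.index
        )
        adj = batch_adjust.combat_adjust(
            expr,
            batch_adjust.BatchDesign(batch=quality, covariates=X[[CONTRAST]]),
            config=cfg,
        )
        fit = fit_lm(adj, X)
    elif strategy == "covariate":
        Xq = add_factor(
            X,
            pd.Series(np.where(flagged, "flagged", "passed"), index=flagged.index),
            "quality",
        )
        Xq = add_factor(Xq, metadata.batch, "batch")
        # drop constant dummies (e.g. single batch)
        keep_cols = [c for c in Xq.columns if Xq[c].nunique() > 1 or c == "intercept"]
        fit = fit_lm(expr, Xq[keep_cols])
    else:  # sva
        if sv is None:
            raise StqcError("sva strategy requires estimated surrogate variables")
        Xs = X.copy()
        for k in range(sv.shape[1]):
            Xs[f"sv{k + 1}"] = sv.iloc[:, k].reindex(Xs.index).to_numpy()
        fit = fit_lm(expr, Xs)
    return de_table(fit)


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------


def overlap_counts(gene_lists: dict[str, set]) -> pd.DataFrame:
    """Counts for every region of the Venn diagram of the given sets.

    One row per non-empty membership pattern over all lists; the region
    counts sum to the size of the union.
    """
    import itertools

    if len(gene_lists) < 2:
        raise StqcError("need >= 2 gene lists")
    names = list(gene_lists)
    sets = {k: set(v) for k, v in gene_lists.items()}
    rows = []
    for pattern in itertools.product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        inside = [n for n, m in zip(names, pattern) if m]
        outside = [n for n, m in zip(names, pattern) if not m]
        region = set.intersection(*(sets[n] for n in inside))
        for n in outside:
            region -= sets[n]
        rows.append({**{n: m for n, m in zip(names, pattern)}, "count": len(region)})
    return pd.DataFrame(rows)


def hcluster(
    expr: pd.DataFrame,
    distance: str = "one_minus_pearson",
    method: str = "average",
) -> np.ndarray:
    """Average-linkage agglomerative clustering of the arrays.

    Returns the scipy linkage matrix (merge list with heights).
    Distances: 'euclidean' or 'one_minus_pearson' (1 - Pearson
    correlation of the log2 expression profiles).
    """
    if expr.shape[1] < 2:
        raise StqcError("need >= 2 arrays to cluster")
    X = expr.to_numpy(float).T
    if distance == "euclidean":
        d = pdist(X, metric="euclidean")
    elif distance == "one_minus_pearson":
        if np.any(X.std(axis=1) == 0):
            bad = expr.columns[np.flatnonzero(X.std(axis=1) == 0)[0]]
            raise StqcError(f"array {bad!r} is constant; correlation undefined")
        d = pdist(X, metric="correlation")
    else:
        raise StqcError(f"unknown distance {distance!r}")
    return scipy_linkage(d, method=method)
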