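"""Known-factor adjustment (parametric empirical-Bayes location/scale,
ComBat-style) and latent-factor estimation (surrogate variable analysis).

ComBat removes an additive/multiplicative per-batch effect from every
gene while protecting specified biological covariates: genes are
standardised against the overall model fit, per-batch location and scale
parameters are estimated and shrunk toward their across-gene priors
(normal for location, inverse-gamma for scale, hyperparameters by method
of moments, joint posterior by fixed-point iteration), and the data are
back-transformed. The same routine adjusts for quality categories by
relabelling the "batches" with QC flag status.

SVA estimates how many latent factors structure the residuals (singular
values against a row-permutation null, Buja-Eyuboglu style) and then
builds each surrogate variable from the genes most associated with the
corresponding residual singular vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Config, StqcError


@dataclass
class BatchDesign:
    """Batch labels plus the biological design to protect."""

    batch: pd.Series
    covariates: pd.DataFrame | None = None  # without intercept

    def __post_init__(self) -> None:
        counts = self.batch.value_counts()
        if (counts < 2).any():
            raise StqcError(
                f"batch {counts.index[counts < 2][0]!r} has < 2 arrays"
            )
        if self.covariates is not None:
            C = self.covariates.reindex(self.batch.index).to_numpy(float)
            if np.isnan(C).any():
                raise StqcError("covariates do not cover all arrays")
            full = np.column_stack([np.ones(len(C)), C])
            if np.linalg.matrix_rank(full) < full.shape[1]:
                raise StqcError("protected covariate matrix is rank deficient")


@dataclass
class SurrogateVariables:
    """Orthonormal latent-factor estimates, one column per factor."""

    sv_matrix: pd.DataFrame  # arrays x n_sv

    @property
    def n_sv(self) -> int:
        return self.sv_matrix.shape[1]


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


def combat_adjust(
    expr: pd.DataFrame,
    design: BatchDesign,
    config: Config | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment of a log2 matrix.

    With a single batch level there is nothing to adjust and the input is
    returned unchanged.
    """
    cfg = config or Config()
    batch = design.batch.reindex(expr.columns)
    if batch.isna().any():
        raise StqcError("batch labels do not cover all arrays")
    levels = list(pd.unique(batch))
    if len(levels) < 2:
        return expr.copy()

    Y = expr.to_numpy(float)
    G, n = Y.shape
    B = np.column_stack([(batch == lev).to_numpy(float) for lev in levels])
    n_b = B.sum(axis=0)
    if design.covariates is not None:
        C = design.covariates.reindex(expr.columns).to_numpy(float)
        X = np.column_stack([B, C])
    else:
        C = None
        X = B
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StqcError("batch indicators collinear with protected covariates")

    # gene-wise OLS: batch means + protected effects
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv  # G x (n_batch + n_cov)
    gamma_hat0 = beta[:, : len(levels)]
    # grand mean: batch-size weighted batch intercepts
    alpha = gamma_hat0 @ (n_b / n)
    cov_fit = beta[:, len(levels):] @ C.T if C is not None else 0.0
    fitted = gamma_hat0 @ B.T + cov_fit
    resid = Y - fitted
    pooled_var = (resid**2).mean(axis=1)
    pooled_var = np.maximum(pooled_var, 1e-12)
    pooled_sd = np.sqrt(pooled_var)

    stand = (Y - alpha[:, None] - cov_fit) / pooled_sd[:, None]

    adjusted = stand.copy()
    for i, lev in enumerate(levels):
        mask = B[:, i].astype(bool)
        ni = int(n_b[i])
        Z = stand[:, mask]  # G x ni
        gamma_hat = Z.mean(axis=1)
        delta_hat = Z.var(axis=1, ddof=1)
        # hyperpriors by method of moments across genes
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        v = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        lam = (v**2 + 2 * s2) / s2 if s2 > 0 else np.inf
        theta = (v**3 + v * s2) / s2 if s2 > 0 else 0.0

        g_star = gamma_hat.copy()
        d_star = delta_hat.copy()
        if np.isfinite(lam) and tau2 > 0:
            sse_base = ((Z - gamma_hat[:, None]) ** 2).sum(axis=1)
            for it in range(cfg.combat_max_iter):
                g_new = (ni * tau2 * gamma_hat + d_star * gamma_bar) / (
                    ni * tau2 + d_star
                )
                sse = sse_base + ni * (gamma_hat - g_new) ** 2
                d_new = (theta + 0.5 * sse) / (ni / 2.0 + lam - 1.0)
                change = max(
                    np.max(np.abs(g_new - g_star)), np.max(np.abs(d_new - d_star))
                )
                g_star, d_star = g_new, d_new
                if change < cfg.combat_tol:
                    break
            else:
                raise StqcError(
                    f"ComBat EB fixed point did not converge for batch {lev!r}"
                )
        d_star = np.maximum(d_star, 1e-12)
        adjusted[:, mask] = (Z - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adjusted * pooled_sd[:, None] + alpha[:, None] + cov_fit
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# SVA
# ---------------------------------------------------------------------------


def _residual_matrix(expr: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    X = design.reindex(expr.columns).to_numpy(float)
    Y = expr.to_numpy(float)
    beta = Y @ X @ np.linalg.inv(X.T @ X)
    return Y - beta @ X.T


def estimate_num_sv(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    n_permutations: int | None = None,
    seed: int | None = None,
    config: Config | None = None,
) -> int:
    """Number of significant latent factors in the model residuals.

    Each residual singular value's variance-explained proportion is
    compared with a null built by permuting every gene row independently;
    factors are counted from the largest until the first one whose
    permutation p-value exceeds the significance level.
    """
    cfg = config or Config()
    n_perm = cfg.sva_n_permutations if n_permutations is None else n_permutations
    if n_perm < 20:
        raise StqcError("need >= 20 permutations")
    X = design.reindex(expr.columns).to_numpy(float)
    n, p = X.shape
    if n - p < 2:
        raise StqcError("residual degrees of freedom < 2")
    rng = np.random.default_rng(seed if seed is not None else cfg.rng_seed)
    R = _residual_matrix(expr, design)
    sv = np.linalg.svd(R, compute_uv=False)
    k_max = min(len(sv), n - p)
    prop = sv**2 / (sv**2).sum()

    exceed = np.zeros(k_max)
    Rp = R.copy()
    for _ in range(n_perm):
        # permute each gene's residuals independently
        idx = np.argsort(rng.random(R.shape), axis=1)
        Rp = np.take_along_axis(R, idx, axis=1)
        # re-project: remove the design fit from the permuted matrix
        Rp = Rp - (Rp @ X @ np.linalg.inv(X.T @ X)) @ X.T
        sv0 = np.linalg.svd(Rp, compute_uv=False)
        prop0 = sv0**2 / (sv0**2).sum()
        exceed += prop0[:k_max] >= prop[:k_max]
    pvals = (exceed + 1) / (n_perm + 1)
    n_sv = 0
    for k in range(k_max):
        if pvals[k] <= cfg.sva_alpha:
            n_sv += 1
        else:
            break
    return n_sv


def estimate_sv(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    n_sv: int,
    seed: int | None = None,
    config: Config | None = None,
) -> SurrogateVariables:
    """Construct surrogate variables from residual structure.

    For each of the leading residual singular vectors: correlate every
    gene with the vector, keep the significantly associated genes (at
    least ``sva_min_genes``), take the SVD of that gene subset's
    expression and return its singular vector most correlated with the
    original. Columns are orthonormalised against the design space and
    each other.
    """
    cfg = config or Config()
    if n_sv == 0:
        return SurrogateVariables(
            sv_matrix=pd.DataFrame(index=expr.columns, dtype=float)
        )
    X = design.reindex(expr.columns).to_numpy(float)
    n = X.shape[0]
    R = _residual_matrix(expr, design)
    _, _, vt = np.linalg.svd(R, full_matrices=False)
    Y = expr.to_numpy(float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sds = Yc.std(axis=1)
    svs = []
    for k in range(n_sv):
        f = vt[k]
        fc = (f - f.mean()) / f.std()
        r = (Yc / np.maximum(sds, 1e-12)[:, None]) @ fc / n
        # t-test p-value for the correlation of each gene with the factor
        r = np.clip(r, -0.999999, 0.999999)
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        pv = 2 * stats.t.sf(np.abs(tstat), n - 2)
        sel = pv < cfg.sva_gene_p
        if sel.sum() < cfg.sva_min_genes:
            sel = np.argsort(pv)[: cfg.sva_min_genes]
        sub = Yc[sel]
        _, _, vt_sub = np.linalg.svd(sub, full_matrices=False)
        cors = np.abs(
            [np.corrcoef(v, f)[0, 1] for v in vt_sub[: min(len(vt_sub), n)]]
        )
        best = vt_sub[int(np.argmax(cors))]
        if np.corrcoef(best, f)[0, 1] < 0:
            best = -best
        svs.append(best)
    # orthonormalise the surrogate columns
    M = np.array(svs).T  # n x n_sv
    Q, _ = np.linalg.qr(M)
    # keep sign aligned with the raw estimates
    for k in range(Q.shape[1]):
        if np.dot(Q[:, k], M[:, k]) < 0:
            Q[:, k] = -Q[:, k]
    return SurrogateVariables(
        sv_matrix=pd.DataFrame(
            Q,
            index=expr.columns,
            columns=[f"sv{k + 1}" for k in range(Q.shape[1])],
        )
    )


def sva(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    seed: int | None = None,
    config: Config | None = None,
) -> SurrogateVariables:
    """estimate_num_sv followed by estimate_sv."""
    n_sv = estimate_num_sv(expr, design, seed=seed, config=config)
    return estimate_sv(expr, design, n_sv, seed=seed, config=config)
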