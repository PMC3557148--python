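"""Transcript-level degradation bias: which clusters differ between
quality-flagged and quality-passed arrays, whether the affected groups
differ in transcript length, and 5'->3' positional intensity profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import Config, ProbeAnnotation, ProbeMatrix, QCReport, StqcError, LINEAR
from .diffexpr import add_factor, de_table, fit_lm


def quality_affected(
    expr: pd.DataFrame,
    report: QCReport,
    p_threshold: float | None = None,
    fc_threshold: float | None = None,
    config: Config | None = None,
) -> pd.DataFrame:
    """Per-cluster flagged-vs-passed fold change, adjusted p and class.

    Runs the same linear-model -> moderated-t -> BH chain as the
    disease-status analysis, with the QC flag as the grouping factor.
    Clusters with adjusted p <= p_threshold and |FC| >= fc_threshold are
    classed 'up' or 'down' (sign of the flagged-vs-passed log2 FC); the
    rest are 'unaffected'.
    """
    cfg = config or Config()
    p_thr = cfg.quality_de_p if p_threshold is None else p_threshold
    fc_thr = cfg.quality_de_fc if fc_threshold is None else fc_threshold
    flagged = report.table["flagged"].reindex(expr.columns)
    if flagged.isna().any():
        raise StqcError("QC report does not cover all arrays")
    if flagged.sum() < 2 or (~flagged).sum() < 2:
        raise StqcError("both quality groups need >= 2 arrays")
    X = pd.DataFrame(
        {"intercept": 1.0, "condition_tumour": flagged.astype(float)},
        index=expr.columns,
    )
    out = de_table(fit_lm(expr, X))
    out = out.rename(columns={"log2fc": "quality_log2fc"})
    sig = (out["adj_p"] <= p_thr) & (np.abs(out["quality_log2fc"]) >= np.log2(fc_thr))
    out["affected_class"] = np.where(
        sig & (out["quality_log2fc"] > 0),
        "up",
        np.where(sig & (out["quality_log2fc"] < 0), "down", "unaffected"),
    )
    return out


def length_bias_test(
    classes: pd.Series,
    lengths: pd.Series,
    alternative: str = "one-sided",
) -> pd.DataFrame:
    """Mann-Whitney tests of transcript length by affected class.

    One-sided directions fixed a priori: clusters with increased signal
    on degraded arrays are expected shorter than the unaffected group,
    those with decreased signal longer. Exact null distribution for small
    groups (both n <= 8), normal approximation with tie correction
    otherwise. Empty comparisons are reported with NaN rather than
    raising.
    """
    classes = classes.reindex(lengths.index)
    groups = {
        c: lengths[classes == c].to_numpy(float) for c in ("up", "down", "unaffected")
    }
    rows = []
    for cls, alt in (("up", "less"), ("down", "greater")):
        g, ref = groups[cls], groups["unaffected"]
        if len(g) == 0 or len(ref) == 0:
            rows.append(
                {
                    "comparison": f"{cls}_vs_unaffected",
                    "n": len(g),
                    "n_unaffected": len(ref),
                    "median_length": np.median(g) if len(g) else np.nan,
                    "median_unaffected": np.median(ref) if len(ref) else np.nan,
                    "u_statistic": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        method = "exact" if max(len(g), len(ref)) <= 8 else "asymptotic"
        use_alt = alt if alternative == "one-sided" else "two-sided"
        res = stats.mannwhitneyu(g, ref, alternative=use_alt, method=method)
        rows.append(
            {
                "comparison": f"{cls}_vs_unaffected",
                "n": len(g),
                "n_unaffected": len(ref),
                "median_length": float(np.median(g)),
                "median_unaffected": float(np.median(ref)),
                "u_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def class_summary(affected: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """n and median transcript length per affected class."""
    lengths = lengths.reindex(affected.index)
    rows = []
    for cls in ("up", "down", "unaffected"):
        sel = affected["affected_class"] == cls
        rows.append(
            {
                "class": cls,
                "n": int(sel.sum()),
                "median_length_bp": float(lengths[sel].median()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def positional_profile(
    matrix: ProbeMatrix,
    ann: ProbeAnnotation,
    k: int,
) -> pd.DataFrame:
    """Mean intensity by 5'->3' probe position, per array.

    Restricted to transcript clusters with exactly ``k`` PM probes; raw
    input is log2-transformed first so profiles are comparable with
    processed data. Returns a k x n_arrays table indexed by position.
    """
    pm = ann.pm
    sizes = pm.groupby("cluster_id", sort=False).size()
    use = sizes.index[sizes == k]
    if len(use) == 0:
        avail = sorted(sizes.unique().tolist())
        raise StqcError(f"no cluster has exactly {k} pm probes; sizes present: {avail}")
    sub = pm[pm["cluster_id"].isin(use)]
    vals = matrix.values.loc[sub.index].to_numpy(float)
    if matrix.scale == LINEAR:
        vals = np.log2(np.clip(vals, 0.5, None))
    pos = sub["position_index"].to_numpy(int)
    prof = np.zeros((k, vals.shape[1]))
    counts = np.zeros(k)
    for t in range(1, k + 1):
        rows = pos == t
        counts[t - 1] = rows.sum()
        prof[t - 1] = vals[rows].mean(axis=0)
    out = pd.DataFrame(
        prof, index=pd.Index(np.arange(1, k + 1), name="position"),
        columns=matrix.values.columns,
    )
    return out


def profile_slopes(profile: pd.DataFrame) -> pd.Series:
    """OLS slope of mean log2 intensity against probe position, per array."""
    x = profile.index.to_numpy(float)
    xc = x - x.mean()
    y = profile.to_numpy(float)
    slopes = (xc[:, None] * (y - y.mean(axis=0))).sum(axis=0) / (xc**2).sum()
    return pd.Series(slopes, index=profile.columns, name="slope")
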