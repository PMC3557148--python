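"""Frozen-reference preprocessing.

New arrays are processed one at a time against parameters frozen from a
reference collection of high-quality arrays: log2 transform, quantile
normalisation to the frozen reference quantiles, then robust cluster
summarisation with frozen probe affinities removed. The per-cluster
standard error feeds the GNUSE precision score.

Dialect notes: summarisation is median/MAD (SE = 1.4826*MAD/sqrt(n))
rather than robust weighted least squares — deterministic and sufficient
for precision scoring — and no convolution background correction is
applied; background probes serve only the raw PM-BG metric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    Config,
    FrozenReference,
    ProbeAnnotation,
    ProbeMatrix,
    StqcError,
    LINEAR,
    LOG2,
)

MAD_SCALE = 1.4826  # consistency factor for Normal data


def _log2_pm(raw: ProbeMatrix, ann: ProbeAnnotation, floor: float) -> pd.DataFrame:
    """log2 of the PM-probe rows, with a pseudo-floor for tiny values."""
    pm_ids = ann.pm.index
    missing = pm_ids.difference(raw.values.index)
    if len(missing):
        raise StqcError(f"pm probes missing from matrix, e.g. {missing[0]!r}")
    vals = raw.values.loc[pm_ids]
    if raw.scale == LOG2:
        return vals.copy()
    return np.log2(vals.clip(lower=floor))


def _cluster_groups(ann: ProbeAnnotation, probe_index: pd.Index):
    """Stable (cluster_id, integer row positions) pairs for PM probes."""
    pm = ann.pm
    pos = pd.Series(np.arange(len(probe_index)), index=probe_index)
    for cid, grp in pm.groupby("cluster_id", sort=False):
        yield cid, pos[grp.index].to_numpy()


def summarize_frozen(
    norm: ProbeMatrix,
    ann: ProbeAnnotation,
    frozen: FrozenReference,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-level expression and SE with frozen probe effects removed.

    expression_gj = median over cluster probes of (value - phi);
    SE_gj = 1.4826 * MAD / sqrt(n_probes).
    """
    if norm.scale != LOG2:
        raise StqcError("summarize_frozen expects log2-scale input")
    pm_ids = frozen.probe_effects.index
    missing = pm_ids.difference(norm.values.index)
    if len(missing):
        raise StqcError(f"probes missing from matrix, e.g. {missing[0]!r}")
    resid = norm.values.loc[pm_ids].to_numpy() - frozen.probe_effects.to_numpy()[:, None]

    ann_clusters = set(ann.pm["cluster_id"])
    expr_rows, se_rows, cids = [], [], []
    for cid, rows in _cluster_groups(ann, pm_ids):
        if cid not in ann_clusters:  # pragma: no cover - defensive
            raise StqcError(f"cluster {cid!r} missing from annotation")
        block = resid[rows]
        med = np.median(block, axis=0)
        mad = np.median(np.abs(block - med[None, :]), axis=0)
        expr_rows.append(med)
        se_rows.append(MAD_SCALE * mad / np.sqrt(block.shape[0]))
        cids.append(cid)
    idx = pd.Index(cids, name="cluster_id")
    expr = pd.DataFrame(expr_rows, index=idx, columns=norm.values.columns)
    se = pd.DataFrame(se_rows, index=idx, columns=norm.values.columns)
    return expr, se


def quantile_normalize_to_reference(
    raw: ProbeMatrix, frozen: FrozenReference, config: Config | None = None
) -> ProbeMatrix:
    """Replace each array's sorted log2 PM values by the frozen quantiles.

    Tied input values receive the mean of the reference quantiles they
    span, so the map is well defined and order preserving.
    """
    cfg = config or Config()
    pm_ids = frozen.probe_effects.index
    if len(pm_ids.difference(raw.values.index)):
        raise StqcError("probe universe differs from frozen reference")
    if len(pm_ids) != len(frozen.reference_quantiles):
        raise StqcError("probe count mismatch with reference quantiles")
    if raw.scale == LINEAR:
        x = np.log2(raw.values.loc[pm_ids].clip(lower=cfg.log_floor).to_numpy())
    else:
        x = raw.values.loc[pm_ids].to_numpy(float).copy()
    q = frozen.reference_quantiles
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col = np.empty(n)
        col[order] = q
        xs = x[order, j]
        # average quantiles across runs of tied input values
        if np.any(np.diff(xs) == 0):
            boundaries = np.flatnonzero(np.diff(xs) != 0) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [n]])
            for s, e in zip(starts, ends):
                if e - s > 1:
                    col[order[s:e]] = q[s:e].mean()
        out[:, j] = col
    df = pd.DataFrame(out, index=pm_ids, columns=raw.values.columns)
    df.index.name = "probe_id"
    return ProbeMatrix(values=df, scale=LOG2)


def build_frozen_reference(
    reference_raw: ProbeMatrix,
    ann: ProbeAnnotation,
    config: Config | None = None,
) -> FrozenReference:
    """Freeze quantiles, probe affinities and per-cluster SE medians from
    a collection of high-quality reference arrays."""
    cfg = config or Config()
    if reference_raw.shape[1] < 3:
        raise StqcError("need >= 3 reference arrays")
    sizes = ann.pm.groupby("cluster_id", sort=False).size()
    if (sizes < 2).any():
        raise StqcError(f"cluster {sizes.index[sizes < 2][0]!r} has < 2 pm probes")

    if reference_raw.scale == LINEAR:
        log2_pm = _log2_pm(reference_raw, ann, cfg.log_floor)
    else:
        log2_pm = reference_raw.values.loc[ann.pm.index]
    x = log2_pm.to_numpy(float)
    quantiles = np.sort(x, axis=0).mean(axis=1)

    # probe effects: median across arrays of (value - cluster median),
    # centered to sum 0 within each cluster
    phi = np.empty(x.shape[0])
    for cid, rows in _cluster_groups(ann, log2_pm.index):
        block = x[rows]
        resid = block - np.median(block, axis=0)[None, :]
        p = np.median(resid, axis=1)
        phi[rows] = p - p.mean()
    probe_effects = pd.Series(phi, index=log2_pm.index, name="phi")

    frozen = FrozenReference(
        probe_effects=probe_effects,
        reference_quantiles=quantiles,
        cluster_se_median=pd.Series(dtype=float),
    )
    norm = quantile_normalize_to_reference(reference_raw, frozen, cfg)
    _, se = summarize_frozen(norm, ann, frozen)
    frozen.cluster_se_median = se.median(axis=1)
    return frozen


def preprocess(
    raw: ProbeMatrix,
    ann: ProbeAnnotation,
    frozen: FrozenReference,
    config: Config | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full frozen pipeline: quantile normalise then summarise.

    Returns (expression, se) cluster x array tables on the log2 scale.
    """
    norm = quantile_normalize_to_reference(raw, frozen, config)
    return summarize_frozen(norm, ann, frozen)


def write_frozen_reference(frozen: FrozenReference, path) -> None:
    df = pd.DataFrame(
        {
            "probe_effect": frozen.probe_effects.to_numpy(),
            "reference_quantile": frozen.reference_quantiles,
        },
        index=frozen.probe_effects.index,
    )
    df.to_csv(path, sep="\t", index_label="probe_id")


def write_cluster_se_median(frozen: FrozenReference, path) -> None:
    frozen.cluster_se_median.rename("se_median").to_csv(
        path, sep="\t", index_label="cluster_id"
    )
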