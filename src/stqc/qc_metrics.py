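"""Within- and between-array quality metrics and the 2-of-3 flag rule.

Three per-array metrics are combined: the coefficient of variation across
all probes (raw linear scale), the perfect-match minus background probe
mean difference (raw linear scale), and the median GNUSE — the per-cluster
standard error relative to a frozen reference median, so that a typical
high-quality array scores 1 and 1.25 means precision ~25% worse than the
reference population. Arrays failing at least two of the three are
flagged; arrays are ranked worst-first by median GNUSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Config,
    FrozenReference,
    ProbeAnnotation,
    ProbeMatrix,
    QCReport,
    SampleMetadata,
    StqcError,
    LINEAR,
)


@dataclass
class QCThresholds:
    """Pass/fail boundaries for the three metrics.

    cv_max and pm_bg_min are derived from high-RIN arrays only (RIN above
    ``cv_rin_cutoff``); gnuse_max is the fixed configured threshold.
    """

    cv_max: float
    pm_bg_min: float
    gnuse_max: float


def probe_cv(raw: ProbeMatrix) -> pd.Series:
    """Coefficient of variation across all probes, per array (sample SD)."""
    if raw.scale != LINEAR:
        raise StqcError("probe_cv expects raw linear-scale intensities")
    vals = raw.values.to_numpy(float)
    mean = vals.mean(axis=0)
    if (mean == 0).any():
        raise StqcError("zero mean intensity column")
    sd = vals.std(axis=0, ddof=1)
    return pd.Series(sd / mean, index=raw.values.columns, name="cv")


def pm_bg_difference(raw: ProbeMatrix, ann: ProbeAnnotation) -> pd.Series:
    """Mean(PM) - mean(background) per array, on the raw linear scale."""
    if raw.scale != LINEAR:
        raise StqcError("pm_bg_difference expects raw linear-scale intensities")
    bg_ids = ann.background_probes
    pm_ids = ann.pm.index
    if len(bg_ids) == 0:
        raise StqcError("annotation has no background probes")
    if len(pm_ids) == 0:
        raise StqcError("annotation has no pm probes")
    pm_mean = raw.values.loc[pm_ids.intersection(raw.values.index)].mean(axis=0)
    bg_mean = raw.values.loc[bg_ids.intersection(raw.values.index)].mean(axis=0)
    return (pm_mean - bg_mean).rename("pm_bg")


def derive_thresholds(
    cvs: pd.Series,
    pm_bgs: pd.Series,
    metadata: SampleMetadata,
    config: Config | None = None,
) -> QCThresholds:
    """Build metric thresholds from the high-RIN arrays.

    cv_max = mean + k*SD of high-RIN CVs (fail above); pm_bg_min is the
    mirrored construction, mean - k*SD of high-RIN PM-BG (fail below);
    sample SD (n-1) throughout; k = ``cv_sd_multiplier``.
    """
    cfg = config or Config()
    high = metadata.rin[metadata.rin > cfg.cv_rin_cutoff].index
    if len(high) < 2:
        raise StqcError(
            f"need >= 2 arrays with RIN > {cfg.cv_rin_cutoff} to derive thresholds"
        )
    k = cfg.cv_sd_multiplier
    cv_h = cvs[high].to_numpy(float)
    pb_h = pm_bgs[high].to_numpy(float)
    return QCThresholds(
        cv_max=float(cv_h.mean() + k * cv_h.std(ddof=1)),
        pm_bg_min=float(pb_h.mean() - k * pb_h.std(ddof=1)),
        gnuse_max=cfg.gnuse_flag_threshold,
    )


def gnuse(se_matrix: pd.DataFrame, frozen: FrozenReference) -> pd.DataFrame:
    """Per-cluster GNUSE: SE divided by the frozen reference median SE."""
    med = frozen.cluster_se_median.reindex(se_matrix.index)
    if med.isna().any():
        raise StqcError("cluster missing from frozen reference SE medians")
    if (med <= 0).any():
        bad = med.index[med <= 0][0]
        raise StqcError(f"frozen SE median not positive for cluster {bad!r}")
    return se_matrix.div(med, axis=0)


def gnuse_median(se_matrix: pd.DataFrame, frozen: FrozenReference) -> pd.Series:
    """Median GNUSE per array — the precision score used for flagging."""
    return gnuse(se_matrix, frozen).median(axis=0).rename("gnuse_median")


def flag_arrays(
    cv: pd.Series,
    pm_bg: pd.Series,
    gnuse_med: pd.Series,
    thresholds: QCThresholds,
    config: Config | None = None,
) -> QCReport:
    """Apply per-metric pass/fail and the >= 2-of-3 flag rule.

    quality_rank orders arrays worst-first by median GNUSE (ties broken
    by array id).
    """
    cfg = config or Config()
    idx = cv.index
    if not (idx.equals(pm_bg.index) and idx.equals(gnuse_med.index)):
        raise StqcError("metric series must share the same arrays")
    tbl = pd.DataFrame(
        {
            "cv": cv.astype(float),
            "pm_bg": pm_bg.astype(float),
            "gnuse_median": gnuse_med.astype(float),
        },
        index=idx,
    )
    tbl["cv_pass"] = tbl["cv"] <= thresholds.cv_max
    tbl["pm_bg_pass"] = tbl["pm_bg"] >= thresholds.pm_bg_min
    tbl["gnuse_pass"] = tbl["gnuse_median"] <= thresholds.gnuse_max
    n_fail = (~tbl[["cv_pass", "pm_bg_pass", "gnuse_pass"]]).sum(axis=1)
    tbl["flagged"] = n_fail >= cfg.flag_min_failures
    # worst-first rank: descending gnuse, ties broken lexicographically
    order = sorted(idx, key=lambda a: (-tbl.at[a, "gnuse_median"], str(a)))
    rank = pd.Series(np.arange(1, len(tbl) + 1), index=order)
    tbl["quality_rank"] = rank.reindex(tbl.index).to_numpy()
    tbl.index.name = "array_id"
    tbl.attrs["flag_min_failures"] = cfg.flag_min_failures
    return QCReport(table=tbl)


def report_from_calls(
    flags: pd.DataFrame, config: Config | None = None
) -> QCReport:
    """Build a QCReport from externally supplied pass/fail calls.

    ``flags`` needs boolean cv_pass/pm_bg_pass/gnuse_pass columns and an
    ordering column ``gnuse_rank`` (worst first) or gnuse_median values;
    used to apply the flag rule to a published QC summary table.
    """
    cfg = config or Config()
    tbl = flags.copy()
    for col in ("cv", "pm_bg", "gnuse_median"):
        if col not in tbl:
            tbl[col] = np.nan
    n_fail = (~tbl[["cv_pass", "pm_bg_pass", "gnuse_pass"]].astype(bool)).sum(axis=1)
    tbl["flagged"] = n_fail >= cfg.flag_min_failures
    if "quality_rank" not in tbl:
        if "gnuse_rank" in tbl and tbl["gnuse_rank"].notna().all():
            tbl["quality_rank"] = tbl["gnuse_rank"].astype(int)
        else:
            # printed summaries rank failing arrays first; passing arrays
            # follow in array-weight order when available
            key = tbl.get("gnuse_median")
            tbl["quality_rank"] = (
                (-key).rank(method="first").astype(int)
                if key is not None and key.notna().all()
                else np.arange(1, len(tbl) + 1)
            )
    tbl.index.name = "array_id"
    tbl.attrs["flag_min_failures"] = cfg.flag_min_failures
    return QCReport(table=tbl)


def qc_summary(report: QCReport, metadata: SampleMetadata) -> dict:
    """Cohort-level QC summary.

    Flagged-group RIN dispersion uses the population SD (divisor n);
    cohort RIN dispersion the sample SD (n-1) — the conventions under
    which the published summaries are stated.
    """
    tbl = report.table
    if not set(tbl.index) == set(metadata.array_ids):
        raise StqcError("report and metadata must describe the same arrays")
    rin = metadata.rin.reindex(tbl.index).to_numpy(float)
    flagged = tbl["flagged"].to_numpy(bool)
    fl_rin = rin[flagged]
    low = rin <= 3.3
    return {
        "n_arrays": int(len(tbl)),
        "n_flagged": int(flagged.sum()),
        "flagged_rin_mean": float(fl_rin.mean()) if flagged.any() else float("nan"),
        "flagged_rin_sd": float(fl_rin.std(ddof=0)) if flagged.any() else float("nan"),
        "cohort_rin_mean": float(rin.mean()),
        "cohort_rin_sd": float(rin.std(ddof=1)),
        "n_pass_rin_below_7": int(((rin < 7) & ~flagged).sum()),
        "n_pass_all_rin_below_3": int(
            (
                (rin < 3)
                & tbl[["cv_pass", "pm_bg_pass", "gnuse_pass"]].all(axis=1).to_numpy()
            ).sum()
        ),
        "prop_flagged_rin_le_3.3": float(flagged[low].mean()) if low.any() else float("nan"),
    }


def purity_association(
    report: QCReport,
    metadata: SampleMetadata,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test of A260/230 by flag status.

    Defaults to the classical equal-variance Student's t; Welch via
    ``equal_var=False``. Returns (t, p).
    """
    a = metadata.table["a260_230"].reindex(report.table.index).to_numpy(float)
    flagged = report.table["flagged"].to_numpy(bool)
    g1, g0 = a[flagged], a[~flagged]
    if len(g1) < 2 or len(g0) < 2:
        raise StqcError("both flag groups need >= 2 arrays for a t-test")
    t, p = stats.ttest_ind(g1, g0, equal_var=equal_var)
    return float(t), float(p)
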