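"""Stage orchestration: each stage reads/writes TSV artifacts in a
working directory, so stages can be run individually (CLI subcommands)
or chained end to end. Deterministic given the configured seed."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import batch_adjust, degradation_bias, diffexpr, preprocess as prep, qc_metrics, qpcr as qpcr_mod
from .core import (
    Config,
    FrozenReference,
    ProbeMatrix,
    StqcError,
    LOG2,
    read_annotation,
    read_metadata,
    read_probe_matrix,
    read_table,
    write_annotation,
    write_metadata,
    write_probe_matrix,
    write_table,
)
from .simulate import CohortSimulator

logger = logging.getLogger("stqc")


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s failed after %.1fs", stage, dt)
                raise StqcError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", stage, dt)

    return _T()


def stage_simulate(config: Config, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with _timed("simulate"):
        sim = CohortSimulator(config)
        raw, ann, meta, truth = sim.cohort()
        ref = sim.reference_set()
        logger.info(
            "simulated %d probes x %d arrays (seed=%d)",
            raw.shape[0],
            raw.shape[1],
            config.rng_seed,
        )
        write_probe_matrix(raw, outdir / "probe_matrix.tsv")
        write_probe_matrix(ref, outdir / "reference_matrix.tsv")
        write_annotation(ann, outdir / "annotation.tsv")
        write_metadata(meta, outdir / "metadata.tsv")
        truth.clusters.to_csv(outdir / "truth_clusters.tsv", sep="\t")
        truth.arrays.to_csv(outdir / "truth_arrays.tsv", sep="\t")
        de_genes = list(truth.clusters.index[truth.clusters["de_flag"]][:2])
        eff = {g: e for g, e in zip(de_genes, (1.9, 1.85))}
        ct = sim.qpcr(truth, de_genes, eff)
        ct.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)


def stage_preprocess(config: Config, outdir: Path) -> None:
    with _timed("preprocess"):
        raw = read_probe_matrix(outdir / "probe_matrix.tsv", scale="linear")
        ref = read_probe_matrix(outdir / "reference_matrix.tsv", scale="linear")
        ann = read_annotation(outdir / "annotation.tsv")
        frozen = prep.build_frozen_reference(ref, ann, config)
        expr, se = prep.preprocess(raw, ann, frozen, config)
        write_table(expr, outdir / "expression.tsv", index_label="cluster_id")
        write_table(se, outdir / "se_matrix.tsv", index_label="cluster_id")
        prep.write_frozen_reference(frozen, outdir / "frozen_reference.tsv")
        prep.write_cluster_se_median(frozen, outdir / "cluster_se_median.tsv")


def _load_frozen_se(outdir: Path) -> pd.Series:
    df = read_table(outdir / "cluster_se_median.tsv")
    return df["se_median"]


def stage_qc(config: Config, outdir: Path) -> None:
    with _timed("qc"):
        raw = read_probe_matrix(outdir / "probe_matrix.tsv", scale="linear")
        ann = read_annotation(outdir / "annotation.tsv")
        meta = read_metadata(outdir / "metadata.tsv")
        cv = qc_metrics.probe_cv(raw)
        pm_bg = qc_metrics.pm_bg_difference(raw, ann)
        se = read_table(outdir / "se_matrix.tsv")
        frozen = FrozenReference(
            probe_effects=pd.Series(0.0, index=ann.pm.index),
            reference_quantiles=np.zeros(len(ann.pm.index)),
            cluster_se_median=_load_frozen_se(outdir),
        )
        gn = qc_metrics.gnuse_median(se, frozen)
        thresholds = qc_metrics.derive_thresholds(cv, pm_bg, meta, config)
        report = qc_metrics.flag_arrays(cv, pm_bg, gn, thresholds, config)
        summary = qc_metrics.qc_summary(report, meta)
        t, p = qc_metrics.purity_association(report, meta)
        summary["purity_t"] = t
        summary["purity_p"] = p
        logger.info(
            "qc: n_arrays=%d n_flagged=%d", summary["n_arrays"], summary["n_flagged"]
        )
        write_table(report.table, outdir / "qc_report.tsv", index_label="array_id")
        write_table(pd.DataFrame([summary]), outdir / "qc_summary.tsv")
        write_table(
            pd.DataFrame(
                [
                    {
                        "cv_max": thresholds.cv_max,
                        "pm_bg_min": thresholds.pm_bg_min,
                        "gnuse_max": thresholds.gnuse_max,
                    }
                ]
            ),
            outdir / "thresholds.tsv",
        )


def _load_expr_report_meta(outdir: Path):
    expr = read_table(outdir / "expression.tsv")
    report_tbl = read_table(outdir / "qc_report.tsv")
    report = qc_metrics.report_from_calls(report_tbl)
    meta = read_metadata(outdir / "metadata.tsv")
    return expr, report, meta


def stage_adjust_combat(config: Config, outdir: Path, by: str = "batch") -> None:
    """Adjust expression for one or more known factors, in sequence
    (e.g. ``by='batch,quality'``)."""
    with _timed("adjust-combat"):
        expr, report, meta = _load_expr_report_meta(outdir)
        X = diffexpr.base_design(meta, expr.columns)[[diffexpr.CONTRAST]]
        for factor in by.split(","):
            factor = factor.strip()
            if factor == "batch":
                labels = meta.batch.reindex(expr.columns)
            elif factor == "quality":
                flagged = report.table["flagged"].reindex(expr.columns)
                labels = pd.Series(
                    np.where(flagged, "flagged", "passed"), index=expr.columns
                )
            else:
                raise StqcError(f"unknown adjustment factor {factor!r}")
            if labels.nunique() > 1:
                expr = batch_adjust.combat_adjust(
                    expr,
                    batch_adjust.BatchDesign(batch=labels, covariates=X),
                    config=config,
                )
        write_table(expr, outdir / "expression_adjusted.tsv", index_label="cluster_id")


def _batch_corrected_expr(config: Config, outdir: Path) -> pd.DataFrame:
    """Expression with the processing-batch effect removed — the common
    input to all five strategies."""
    expr, report, meta = _load_expr_report_meta(outdir)
    X = diffexpr.base_design(meta, expr.columns)[[diffexpr.CONTRAST]]
    batch = meta.batch.reindex(expr.columns)
    if batch.nunique() > 1:
        expr = batch_adjust.combat_adjust(
            expr, batch_adjust.BatchDesign(batch=batch, covariates=X), config=config
        )
    return expr


def stage_sva(config: Config, outdir: Path) -> pd.DataFrame:
    with _timed("sva"):
        expr, report, meta = _load_expr_report_meta(outdir)
        X = diffexpr.base_design(meta, expr.columns)
        svs = batch_adjust.sva(expr, X, seed=config.rng_seed, config=config)
        logger.info("sva: %d surrogate variables", svs.n_sv)
        write_table(svs.sv_matrix, outdir / "sv.tsv", index_label="array_id")
        return svs.sv_matrix


def stage_dge(config: Config, outdir: Path, strategy: str = "all") -> None:
    with _timed(f"dge-{strategy}"):
        _, report, meta = _load_expr_report_meta(outdir)
        expr = _batch_corrected_expr(config, outdir)
        strategies = (
            list(diffexpr.STRATEGIES) if strategy == "all" else [strategy]
        )
        results = {}
        for s in strategies:
            sv = None
            if s == "sva":
                sv_path = outdir / "sv.tsv"
                if sv_path.exists():
                    sv = read_table(sv_path)
                else:
                    X = diffexpr.base_design(meta, expr.columns)
                    sv = batch_adjust.sva(
                        expr, X, seed=config.rng_seed, config=config
                    ).sv_matrix
            res = diffexpr.run_strategy(s, expr, report, meta, config, sv=sv)
            results[s] = res
            write_table(res, outdir / f"de_{s}.tsv", index_label="cluster_id")
            logger.info(
                "dge %s: %d clusters with adj_p <= 0.05",
                s,
                int((res["adj_p"] <= 0.05).sum()),
            )
        if len(results) > 1:
            lists = {
                s: set(r.index[r["adj_p"] <= 0.01]) for s, r in results.items()
            }
            write_table(
                diffexpr.overlap_counts(lists), outdir / "overlap_counts.tsv"
            )
            Z = diffexpr.hcluster(expr)
            write_table(
                pd.DataFrame(
                    Z, columns=["left", "right", "height", "n_members"]
                ),
                outdir / "dendrogram.tsv",
            )


def stage_bias(config: Config, outdir: Path) -> None:
    with _timed("bias"):
        _, report, meta = _load_expr_report_meta(outdir)
        expr = _batch_corrected_expr(config, outdir)
        ann = read_annotation(outdir / "annotation.tsv")
        affected = degradation_bias.quality_affected(expr, report, config=config)
        lengths = ann.cluster_lengths().reindex(affected.index)
        write_table(affected, outdir / "bias_report.tsv", index_label="cluster_id")
        write_table(
            degradation_bias.class_summary(affected, lengths),
            outdir / "bias_classes.tsv",
        )
        write_table(
            degradation_bias.length_bias_test(affected["affected_class"], lengths),
            outdir / "length_test.tsv",
        )
        raw = read_probe_matrix(outdir / "probe_matrix.tsv", scale="linear")
        profile = degradation_bias.positional_profile(
            raw, ann, config.probes_per_cluster
        )
        write_table(profile, outdir / "positional_profile.tsv", index_label="position")


def stage_qpcr(config: Config, outdir: Path) -> None:
    with _timed("qpcr"):
        ct = pd.read_csv(outdir / "qpcr.tsv", sep="\t")
        fcs = qpcr_mod.fold_changes_from_table(ct)
        write_table(fcs, outdir / "fc_per_patient.tsv")
        # correlate against per-patient array fold changes
        expr = _batch_corrected_expr(config, outdir)
        meta = read_metadata(outdir / "metadata.tsv")
        rows = []
        for gene in fcs["gene"].unique():
            per_pat = fcs[fcs["gene"] == gene].set_index("patient_id")["fold_change"]
            arr_fc = {}
            for pat, grp in meta.table.groupby("patient_id"):
                t = grp.index[grp["condition"] == "tumour"]
                n = grp.index[grp["condition"] == "normal"]
                if len(t) == 1 and len(n) == 1 and gene in expr.index:
                    arr_fc[pat] = expr.loc[gene, t[0]] - expr.loc[gene, n[0]]
            stats_ = qpcr_mod.correlate_fc(per_pat, pd.Series(arr_fc))
            stats_["gene"] = gene
            rows.append(stats_)
        write_table(pd.DataFrame(rows), outdir / "correlation.tsv")


def run_pipeline(
    config: Config, outdir: str | Path, strategies: str = "all"
) -> None:
    """simulate -> preprocess -> qc -> sva -> dge -> bias -> qpcr."""
    outdir = Path(outdir)
    stage_simulate(config, outdir)
    stage_preprocess(config, outdir)
    stage_qc(config, outdir)
    stage_sva(config, outdir)
    stage_dge(config, outdir, strategies)
    stage_bias(config, outdir)
    stage_qpcr(config, outdir)
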