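# stqc

Quality assessment and degradation-aware analysis of probe-level
expression-array data with variable RNA integrity.

Clinical cohorts — biopsies, archival material — often yield RNA whose
integrity (RIN, 1–10) varies widely, and degraded RNA can bias array
expression measurements. Discarding every low-RIN sample wastes
irreplaceable material; keeping them untreated risks confounded results.
`stqc` implements a complete strategy for this situation on
whole-transcript (Gene ST-style) probe matrices:

1. **Per-array QC metrics** — probe-level coefficient of variation (CV),
   perfect-match minus background probe mean (PM−BG), and the median
   **GNUSE** (global normalised unscaled standard error: per-cluster SE
   divided by a frozen reference median, so a typical good array scores 1
   and 1.25 means ~25% worse precision). An array failing ≥ 2 of the 3
   metrics is *flagged*. The CV ceiling is mean + 2 SD over arrays with
   RIN > 6; the GNUSE ceiling is 1.25.
2. **Frozen-reference preprocessing** — log2, quantile normalisation to
   quantiles frozen from a high-quality reference collection, and robust
   (median/MAD) cluster summarisation with frozen probe affinities.
3. **Five compensation strategies** for differential expression
   (tumour − normal) by gene-wise linear models with empirical-Bayes
   moderated t-statistics and Benjamini–Hochberg adjustment:
   per-array quality **weights**, **exclusion** of flagged arrays,
   **ComBat**-style empirical-Bayes adjustment of the data by quality
   category, quality/batch as **covariates**, and **SVA** surrogate
   variables estimated from the residuals.
4. **Degradation-bias analysis** — which transcript clusters differ
   between quality groups, Mann–Whitney tests of transcript length by
   direction (short transcripts gain signal on degraded arrays, long ones
   lose it), and 5'→3' positional intensity profiles.
5. **Efficiency-corrected qPCR fold change** normalised to the geometric
   mean of reference genes:
   FC = e_t^ΔCt_t / (∏_i e_i^ΔCt_i)^(1/n), with ΔCt = Ct_normal −
   Ct_tumour, reducing to the classical 2^−ΔΔCt when every primer has
   efficiency 2.

A first-class synthetic-data module generates paired tumour/normal
cohorts (17 patients, two batches of 10 and 24 arrays) with RIN-linked
degradation — inflated probe noise, attenuated PM signal, and a signed
transcript-length bias — plus matched reference arrays and qPCR tables,
with full ground truth for recovery testing.

## Worked example

Apply the 2-of-3 flag rule and cohort summaries to the packaged QC table
of a 34-array paired colorectal tumour/normal cohort:

```python
import pandas as pd
from stqc import load_qc_table, qc_table_metadata
import stqc.qc_metrics as qm

qc = load_qc_table()
flags = pd.DataFrame({
    "cv_pass": qc["cv_status"] == "pass",
    "pm_bg_pass": qc["pm_bg_status"] == "pass",
    "gnuse_pass": qc["gnuse_status"] == "pass",
}, index=qc.index)
report = qm.report_from_calls(flags)
summary = qm.qc_summary(report, qc_table_metadata())
for k, v in summary.items():
    print(f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}")
t, p = qm.purity_association(report, qc_table_metadata())
print(f"A260/230 t-test: t = {t:.3f}, p = {p:.3f}")
```

prints

```
n_arrays: 34
n_flagged: 7
flagged_rin_mean: 3.243
flagged_rin_sd: 0.4204
cohort_rin_mean: 6.259
cohort_rin_sd: 1.994
n_pass_rin_below_7: 10
n_pass_all_rin_below_3: 1
prop_flagged_rin_le_3.3: 0.8571
A260/230 t-test: t = 1.511, p = 0.141
```

Seven of 34 arrays fail at least two metrics (flagged group: mean RIN
3.2, SD 0.42, against a cohort mean of 6.3 ± 2.0); ten arrays with
RIN < 7 still pass QC — including one with RIN 2.6 — so a fixed RIN-7
cutoff would discard usable arrays. Purity (A260/230) shows no
significant association with flag status (p = 0.14).

The full simulation pipeline runs from the command line:

```
stqc run-all --seed 1 --outdir out/
```

writing the simulated cohort, QC report, expression and SE matrices,
surrogate variables, one DE table per strategy, the degradation-bias
report and the qPCR fold-change/correlation tables, all as TSV.

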