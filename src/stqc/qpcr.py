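"""Efficiency-corrected relative qPCR quantification.

Fold change of a test gene t for one sample pair, normalised to a panel
of reference genes i = 1..n with per-primer efficiencies e:

    FC = e_t^dCt_t / ( prod_i e_i^dCt_i )^(1/n)

with dCt = Ct_normal - Ct_tumour (so FC > 1 means higher expression in
tumour). Replicate Cts are averaged before dCt. When every primer has
efficiency 2 this reduces exactly to the classical 2^-ddCt with the
reference dCt replaced by the geometric-mean normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import StqcError


@dataclass
class QpcrAssay:
    """One test gene plus reference genes for one sample pair.

    delta_ct values are Ct(normal) - Ct(tumour), replicate-averaged.
    """

    test_gene: str
    test_efficiency: float
    test_delta_ct: float
    ref_genes: list[str]
    ref_efficiencies: list[float]
    ref_delta_cts: list[float]

    def __post_init__(self) -> None:
        effs = [self.test_efficiency, *self.ref_efficiencies]
        for e in effs:
            if not 1.0 < e <= 2.0:
                raise StqcError(f"primer efficiency must be in (1, 2], got {e}")
        if not self.ref_genes:
            raise StqcError("at least one reference gene is required")
        if not (
            len(self.ref_genes) == len(self.ref_efficiencies) == len(self.ref_delta_cts)
        ):
            raise StqcError("reference gene fields must have equal length")


def efficiency_fold_change(assay: QpcrAssay) -> float:
    """Efficiency-corrected fold change for one sample pair."""
    num = assay.test_efficiency**assay.test_delta_ct
    ref_terms = [
        e**d for e, d in zip(assay.ref_efficiencies, assay.ref_delta_cts)
    ]
    denom = float(np.prod(ref_terms)) ** (1.0 / len(ref_terms))
    return float(num / denom)


def fold_changes_from_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient efficiency-corrected fold changes from a Ct table.

    Expects columns gene, role (test/reference), efficiency, patient_id,
    condition and replicate columns ct_1, ct_2, ... Returns one row per
    (test gene, patient) with the fold change and its log2.
    """
    ct_cols = [c for c in ct_table.columns if c.startswith("ct_")]
    if not ct_cols:
        raise StqcError("no replicate Ct columns (ct_1, ...) found")
    tab = ct_table.copy()
    tab["ct_mean"] = tab[ct_cols].mean(axis=1)
    tab["ct_sd"] = tab[ct_cols].std(axis=1, ddof=1) if len(ct_cols) > 1 else 0.0

    ref_genes = sorted(tab.loc[tab["role"] == "reference", "gene"].unique())
    if not ref_genes:
        raise StqcError("Ct table contains no reference genes")
    test_genes = sorted(tab.loc[tab["role"] == "test", "gene"].unique())
    eff = tab.groupby("gene")["efficiency"].first()

    # patient x gene Ct means per condition
    piv = tab.pivot_table(
        index="patient_id", columns=["gene", "condition"], values="ct_mean"
    )
    rows = []
    for gene in test_genes:
        for pat in piv.index:
            try:
                d_t = piv.loc[pat, (gene, "normal")] - piv.loc[pat, (gene, "tumour")]
                d_refs = [
                    piv.loc[pat, (r, "normal")] - piv.loc[pat, (r, "tumour")]
                    for r in ref_genes
                ]
            except KeyError as exc:
                raise StqcError(
                    f"missing measurement for patient {pat!r}: {exc}"
                ) from exc
            if np.isnan(d_t) or np.any(np.isnan(d_refs)):
                raise StqcError(f"missing measurement for patient {pat!r}")
            assay = QpcrAssay(
                test_gene=gene,
                test_efficiency=float(eff[gene]),
                test_delta_ct=float(d_t),
                ref_genes=ref_genes,
                ref_efficiencies=[float(eff[r]) for r in ref_genes],
                ref_delta_cts=[float(d) for d in d_refs],
            )
            fc = efficiency_fold_change(assay)
            rows.append(
                {
                    "gene": gene,
                    "patient_id": pat,
                    "fold_change": fc,
                    "log2_fold_change": np.log2(fc),
                }
            )
    return pd.DataFrame(rows)


def correlate_fc(
    qpcr_fc: pd.Series,
    array_log2fc: pd.Series,
) -> dict:
    """OLS of log2(qPCR fold change) on array log2 fold change.

    Returns slope, intercept, r2 and adjusted R^2
    (1 - (1-R^2)(n-1)/(n-2)); requires >= 3 patients and positive
    qPCR fold changes.
    """
    common = qpcr_fc.index.intersection(array_log2fc.index)
    x = array_log2fc[common].to_numpy(float)
    y = qpcr_fc[common].to_numpy(float)
    n = len(common)
    if n < 3:
        raise StqcError("need >= 3 patients to correlate fold changes")
    if (y <= 0).any():
        raise StqcError("qPCR fold changes must be positive")
    ylog = np.log2(y)
    res = sps.linregress(x, ylog)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return {
        "n": n,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(r2),
        "adjusted_r2": float(adj),
    }
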