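"""Synthetic probe-level cohorts with RIN-linked degradation.

The generator emulates a paired tumour/normal expression-array cohort
processed in two batches, where low RNA integrity (RIN) inflates
probe-level noise, globally attenuates perfect-match signal, and biases
gene signal by transcript length: long transcripts lose intensity and
short ones gain it on degraded arrays.

Log2 intensity of PM probe p (cluster g, position t) on array j:

    y_pj = mu_g + (delta_g + u_{g,pat(j)}) * I[tumour_j] + b_g * I[batch2_j]
           + q_j * (gamma_g - c) + eta_gj + phi_p + s*(t-1)/(k-1) + eps_pj

with q_j = clip((7 - RIN_j)/5, 0, 1) the degradation level,
eta_gj ~ N(0, sigma_bio^2) sample-level biological variability shared by
all probes of a cluster,
gamma_g = -kappa * log2(length_g / L0) the signed length effect,
c a global PM attenuation, s an optional 3'-bias slope (off by default),
and eps_pj ~ N(0, (sigma0 * (1 + lambda*q_j))^2). Background probes are
drawn from a fixed low-mean log-normal unaffected by degradation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    Config,
    ProbeAnnotation,
    ProbeMatrix,
    SampleMetadata,
    StqcError,
    LINEAR,
)

N_REFERENCE_GENES = 3


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort.

    clusters: per-cluster true_log2fc, de_flag, gamma (signed length
    effect), transcript_length_bp, short_noncoding and reference_gene
    flags. arrays: per-array rin, degradation level q, batch, condition,
    patient and realised noise SD. patient_fc: per-cluster, per-patient
    tumour/normal log2 fold change actually planted (delta + u).
    probe_effects: the simulated probe affinities phi.
    """

    clusters: pd.DataFrame
    arrays: pd.DataFrame
    patient_fc: pd.DataFrame
    probe_effects: pd.Series
    sample_effects: pd.DataFrame | None = None  # clusters x arrays biological offsets


class CohortSimulator:
    """Draws gene-level parameters once, then emits cohort, reference and
    qPCR data sharing the same probe universe.

    All randomness derives from ``config.rng_seed`` through named
    substreams, so every artifact is reproducible independently of call
    order.
    """

    def __init__(self, config: Config | None = None):
        self.config = config or Config()
        cfg = self.config
        if cfg.probes_per_cluster < 2:
            raise StqcError("probes_per_cluster must be >= 2 for summarization")
        rng = np.random.default_rng([0, cfg.rng_seed])
        G, K = cfg.n_clusters, cfg.probes_per_cluster

        self.cluster_ids = np.array([f"g{i:05d}" for i in range(G)])
        # transcript lengths: log-normal around the median, with a short
        # non-coding fraction below 400 bp
        lengths = cfg.length_median_bp * 2.0 ** rng.normal(0, cfg.length_log2_sd, G)
        n_short = int(round(cfg.short_noncoding_fraction * G))
        short_idx = rng.choice(G, size=n_short, replace=False)
        lengths[short_idx] = rng.uniform(80, 400, n_short)
        short_flag = np.zeros(G, bool)
        short_flag[short_idx] = True
        self.lengths = lengths
        self.short_flag = short_flag
        self.ref_length = float(np.median(lengths))
        self.gamma = -cfg.degradation_kappa * np.log2(lengths / self.ref_length)

        self.mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, G)
        self.batch2_effect = rng.normal(0, cfg.batch_effect_sd, G)

        n_de = int(round(cfg.de_fraction * G))
        de_idx = rng.choice(G, size=n_de, replace=False)
        delta = np.zeros(G)
        delta[de_idx] = rng.uniform(cfg.de_effect_min, cfg.de_effect_max, n_de) * rng.choice(
            [-1.0, 1.0], n_de
        )
        self.delta = delta
        self.de_flag = delta != 0.0

        # housekeeping reference genes for qPCR: non-DE, no patient effect
        non_de = np.flatnonzero(~self.de_flag)
        self.reference_gene_idx = non_de[:N_REFERENCE_GENES]

        phi = rng.normal(0, cfg.probe_affinity_sd, (G, K))
        phi -= phi.mean(axis=1, keepdims=True)  # affinities sum to 0 per cluster
        self.phi = phi

        pm_ids = [
            f"{cid}_p{t + 1:02d}" for cid in self.cluster_ids for t in range(K)
        ]
        bg_ids = [f"bg{i:05d}" for i in range(cfg.n_background_probes)]
        self.pm_probe_ids = np.array(pm_ids)
        self.bg_probe_ids = np.array(bg_ids)

    # -- annotation ---------------------------------------------------------

    def annotation(self) -> ProbeAnnotation:
        cfg = self.config
        G, K = cfg.n_clusters, cfg.probes_per_cluster
        pm = pd.DataFrame(
            {
                "cluster_id": np.repeat(self.cluster_ids, K),
                "probe_type": "pm",
                "position_index": np.tile(np.arange(1, K + 1), G),
                "transcript_length_bp": np.repeat(
                    np.round(self.lengths).astype(int), K
                ),
            },
            index=self.pm_probe_ids,
        )
        bg = pd.DataFrame(
            {
                "cluster_id": "none",
                "probe_type": "background",
                "position_index": pd.NA,
                "transcript_length_bp": 1,
            },
            index=self.bg_probe_ids,
        )
        tbl = pd.concat([pm, bg])
        tbl["position_index"] = tbl["position_index"].astype("Int64")
        tbl.index.name = "probe_id"
        return ProbeAnnotation(table=tbl)

    # -- array-level draws --------------------------------------------------

    def _draw_rins(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cfg = self.config
        rins = np.empty(n)
        low = rng.random(n) < cfg.rin_low_weight
        rins[low] = rng.normal(cfg.rin_low_mean, cfg.rin_low_sd, low.sum())
        rins[~low] = rng.normal(cfg.rin_high_mean, cfg.rin_high_sd, (~low).sum())
        # truncate to [rin_min, rin_max] by redrawing
        for _ in range(1000):
            bad = (rins < cfg.rin_min) | (rins > cfg.rin_max)
            if not bad.any():
                break
            lo = bad & low
            hi = bad & ~low
            rins[lo] = rng.normal(cfg.rin_low_mean, cfg.rin_low_sd, lo.sum())
            rins[hi] = rng.normal(cfg.rin_high_mean, cfg.rin_high_sd, hi.sum())
        return np.clip(rins, cfg.rin_min, cfg.rin_max)

    @staticmethod
    def degradation_level(rin: np.ndarray) -> np.ndarray:
        """RIN -> degradation map q = clip((7 - rin)/5, 0, 1)."""
        return np.clip((7.0 - np.asarray(rin, float)) / 5.0, 0.0, 1.0)

    def _probe_log2(
        self,
        rng: np.random.Generator,
        gene_offsets: np.ndarray,  # G x n_arrays
        q: np.ndarray,
        n_arrays: int,
    ) -> np.ndarray:
        """Assemble the full probe x array log2 matrix (PM then background)."""
        cfg = self.config
        G, K = cfg.n_clusters, cfg.probes_per_cluster
        gene_part = self.mu[:, None] + gene_offsets + np.outer(
            self.gamma - cfg.pm_attenuation, q
        )
        y = np.repeat(gene_part, K, axis=0) + self.phi.reshape(-1)[:, None]
        if cfg.positional_bias_slope != 0.0 and K > 1:
            pos = np.tile(np.arange(K) / (K - 1), G)
            y += cfg.positional_bias_slope * pos[:, None]
        noise_sd = cfg.noise_sd * (1.0 + cfg.noise_degradation_mult * q)
        y += rng.standard_normal((G * K, n_arrays)) * noise_sd[None, :]
        bg = rng.normal(
            cfg.bg_log2_mean, cfg.bg_log2_sd, (cfg.n_background_probes, n_arrays)
        )
        return np.vstack([y, bg])

    # -- cohort -------------------------------------------------------------

    def cohort(
        self,
    ) -> tuple[ProbeMatrix, ProbeAnnotation, SampleMetadata, SimulationTruth]:
        cfg = self.config
        if cfg.n_patients < 2:
            raise StqcError("n_patients must be >= 2")
        rng = np.random.default_rng([1, cfg.rng_seed])
        P = cfg.n_patients
        patients = [f"p{i + 1:02d}" for i in range(P)]
        array_ids = [f"{p}{c}" for p in patients for c in ("T", "N")]
        condition = np.array(["tumour", "normal"] * P)
        patient_of = np.repeat(patients, 2)
        n_b1 = min(cfg.batch1_patients, P)
        batch = np.repeat(["b1"] * n_b1 + ["b2"] * (P - n_b1), 2)
        n = 2 * P

        rins = self._draw_rins(rng, n)
        q = self.degradation_level(rins)
        a260 = np.clip(rng.normal(2.0, 0.22, n), 1.4, None)

        # per-patient fold-change heterogeneity, only where a true effect
        # exists: genes without differential expression stay exactly null
        u = rng.normal(0, cfg.patient_fc_sd, (cfg.n_clusters, P))
        u[~self.de_flag, :] = 0.0
        u[self.reference_gene_idx, :] = 0.0
        fc = self.delta[:, None] + u  # planted per-patient log2 FC

        tumour = (condition == "tumour").astype(float)
        pat_idx = np.repeat(np.arange(P), 2)
        # sample-level biological variability, shared by a cluster's probes
        # (a property of the RNA sample, so also seen by matched qPCR)
        eta = rng.normal(0, cfg.biological_sd, (cfg.n_clusters, n))
        # housekeeping reference genes are selected for stability
        if cfg.biological_sd > 0:
            eta[self.reference_gene_idx, :] *= cfg.housekeeping_sd / cfg.biological_sd
        gene_offsets = (
            fc[:, pat_idx] * tumour[None, :]
            + np.outer(self.batch2_effect, (batch == "b2").astype(float))
            + eta
        )
        y = self._probe_log2(rng, gene_offsets, q, n)

        values = pd.DataFrame(
            2.0 ** y,
            index=np.concatenate([self.pm_probe_ids, self.bg_probe_ids]),
            columns=array_ids,
        )
        values.index.name = "probe_id"
        raw = ProbeMatrix(values=values, scale=LINEAR)

        meta = SampleMetadata(
            table=pd.DataFrame(
                {
                    "patient_id": patient_of,
                    "condition": condition,
                    "batch": batch,
                    "rin": np.round(rins, 1),
                    "a260_230": np.round(a260, 2),
                },
                index=pd.Index(array_ids, name="array_id"),
            )
        )

        clusters = pd.DataFrame(
            {
                "true_log2fc": self.delta,
                "de_flag": self.de_flag,
                "gamma": self.gamma,
                "transcript_length_bp": np.round(self.lengths).astype(int),
                "short_noncoding": self.short_flag,
                "reference_gene": np.isin(
                    np.arange(cfg.n_clusters), self.reference_gene_idx
                ),
            },
            index=pd.Index(self.cluster_ids, name="cluster_id"),
        )
        arrays = pd.DataFrame(
            {
                "patient_id": patient_of,
                "condition": condition,
                "batch": batch,
                "rin": np.round(rins, 1),
                "q": self.degradation_level(np.round(rins, 1)),
                "noise_sd": cfg.noise_sd
                * (1 + cfg.noise_degradation_mult * self.degradation_level(np.round(rins, 1))),
            },
            index=pd.Index(array_ids, name="array_id"),
        )
        truth = SimulationTruth(
            clusters=clusters,
            arrays=arrays,
            patient_fc=pd.DataFrame(
                fc, index=clusters.index, columns=pd.Index(patients, name="patient_id")
            ),
            probe_effects=pd.Series(
                self.phi.reshape(-1), index=self.pm_probe_ids, name="phi"
            ),
            sample_effects=pd.DataFrame(
                eta, index=clusters.index, columns=array_ids
            ),
        )
        return raw, self.annotation(), meta, truth

    # -- reference set ------------------------------------------------------

    def reference_set(self, n_arrays: int | None = None) -> ProbeMatrix:
        """High-quality (q = 0) arrays from the same generative model,
        standing in for a large public collection of good arrays; used
        only to build the frozen preprocessing reference."""
        cfg = self.config
        n = cfg.n_reference_arrays if n_arrays is None else n_arrays
        if n < 3:
            raise StqcError("need >= 3 reference arrays for a robust median SE")
        rng = np.random.default_rng([2, cfg.rng_seed])
        q = np.zeros(n)
        gene_offsets = rng.normal(0, cfg.biological_sd, (cfg.n_clusters, n))
        y = self._probe_log2(rng, gene_offsets, q, n)
        values = pd.DataFrame(
            2.0 ** y,
            index=np.concatenate([self.pm_probe_ids, self.bg_probe_ids]),
            columns=[f"ref{i + 1:03d}" for i in range(n)],
        )
        values.index.name = "probe_id"
        return ProbeMatrix(values=values, scale=LINEAR)

    # -- qPCR ---------------------------------------------------------------

    def qpcr(
        self,
        truth: SimulationTruth,
        genes: list[str],
        efficiencies: dict[str, float],
    ) -> pd.DataFrame:
        """Triplicate Ct table for test genes plus the reference genes.

        Ct_gj = A_g - theta_gj * ln2/ln(e_g) + N(0, sigma_ct^2), with
        theta_gj the planted log2 abundance, so the efficiency-corrected
        fold change recovers 2^(planted log2 FC) exactly when sigma_ct=0.
        """
        cfg = self.config
        rng = np.random.default_rng([3, cfg.rng_seed])
        ref_genes = list(truth.clusters.index[truth.clusters["reference_gene"]])
        all_genes = list(genes) + [g for g in ref_genes if g not in genes]
        missing = set(all_genes) - set(truth.clusters.index)
        if missing:
            raise StqcError(f"genes not in simulated clusters: {sorted(missing)}")
        eff = dict(efficiencies)
        for g in ref_genes:
            eff.setdefault(g, 2.0)
        for g, e in eff.items():
            if not 1.0 < e <= 2.0:
                raise StqcError(f"efficiency for {g!r} must be in (1, 2], got {e}")

        mu = pd.Series(self.mu, index=self.cluster_ids)
        rows = []
        for g in all_genes:
            role = "reference" if g in ref_genes else "test"
            e_g = eff[g]
            scale = np.log(2.0) / np.log(e_g)
            for aid, arr in truth.arrays.iterrows():
                theta = mu[g]
                if arr["condition"] == "tumour":
                    theta += truth.patient_fc.loc[g, arr["patient_id"]]
                if truth.sample_effects is not None:
                    theta += truth.sample_effects.loc[g, aid]
                ct = cfg.qpcr_baseline_ct - theta * scale
                reps = ct + rng.normal(0, cfg.qpcr_ct_sd, cfg.qpcr_replicates)
                row = {
                    "gene": g,
                    "role": role,
                    "efficiency": e_g,
                    "sample": aid,
                    "patient_id": arr["patient_id"],
                    "condition": arr["condition"],
                }
                row.update({f"ct_{r + 1}": reps[r] for r in range(cfg.qpcr_replicates)})
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional entry points
# ---------------------------------------------------------------------------


def simulate_cohort(
    n_patients: int | None = None,
    n_clusters: int | None = None,
    probes_per_cluster: int | None = None,
    config: Config | None = None,
) -> tuple[ProbeMatrix, ProbeAnnotation, SampleMetadata, SimulationTruth]:
    """Simulate a paired tumour/normal cohort with degradation structure."""
    import dataclasses

    cfg = config or Config()
    overrides = {}
    if n_patients is not None:
        overrides["n_patients"] = n_patients
    if n_clusters is not None:
        overrides["n_clusters"] = n_clusters
    if probes_per_cluster is not None:
        overrides["probes_per_cluster"] = probes_per_cluster
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return CohortSimulator(cfg).cohort()


def simulate_reference_set(n_arrays: int, config: Config | None = None) -> ProbeMatrix:
    """Simulate a high-quality reference array collection (q = 0)."""
    if n_arrays < 10:
        raise StqcError("reference collections should have >= 10 arrays")
    return CohortSimulator(config or Config()).reference_set(n_arrays)


def simulate_qpcr(
    truth: SimulationTruth,
    genes: list[str],
    efficiencies: dict[str, float],
    config: Config | None = None,
    simulator: CohortSimulator | None = None,
) -> pd.DataFrame:
    """Simulate triplicate qPCR Ct values matched to a simulated cohort."""
    sim = simulator or CohortSimulator(config or Config())
    return sim.qpcr(truth, genes, efficiencies)
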