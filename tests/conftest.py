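import dataclasses

import numpy as np
import pandas as pd
import pytest

from stqc import Config, CohortSimulator
import stqc.batch_adjust as ba
import stqc.diffexpr as dx
import stqc.preprocess as pp
import stqc.qc_metrics as qm


SMALL = dict(n_clusters=800, probes_per_cluster=10, n_background_probes=200)


def make_config(seed=0, **overrides):
    return Config(rng_seed=seed, **{**SMALL, **overrides})


def clean_overrides():
    """Settings that switch off degradation, batch effects and DE."""
    return dict(
        rin_low_weight=0.0,
        rin_high_mean=8.0,
        rin_high_sd=0.0,
        batch_effect_sd=0.0,
    )


def noise_free_overrides():
    """Fully deterministic generative settings."""
    return dict(
        noise_sd=0.0,
        biological_sd=0.0,
        patient_fc_sd=0.0,
        qpcr_ct_sd=0.0,
        **clean_overrides(),
    )


class Bundle:
    """A simulated cohort taken through preprocessing and QC."""

    def __init__(self, cfg: Config):
        self.cfg = cfg
        self.sim = CohortSimulator(cfg)
        self.raw, self.ann, self.meta, self.truth = self.sim.cohort()
        self.reference = self.sim.reference_set(20)
        self.frozen = pp.build_frozen_reference(self.reference, self.ann, cfg)
        self.expr, self.se = pp.preprocess(self.raw, self.ann, self.frozen, cfg)
        self.cv = qm.probe_cv(self.raw)
        self.pm_bg = qm.pm_bg_difference(self.raw, self.ann)
        self.gnuse_median = qm.gnuse_median(self.se, self.frozen)
        self.thresholds = qm.derive_thresholds(self.cv, self.pm_bg, self.meta, cfg)
        self.report = qm.flag_arrays(
            self.cv, self.pm_bg, self.gnuse_median, self.thresholds, cfg
        )

    def batch_corrected(self) -> pd.DataFrame:
        X = dx.base_design(self.meta)
        return ba.combat_adjust(
            self.expr,
            ba.BatchDesign(self.meta.batch, X[[dx.CONTRAST]]),
            self.cfg,
        )


@pytest.fixture(scope="session")
def degraded_bundle():
    """Default-structure degraded cohort (two batches, mixed RINs)."""
    return Bundle(make_config(seed=0))


@pytest.fixture(scope="session")
def clean_bundle():
    """Cohort with no degradation and no batch effect (DE still planted)."""
    return Bundle(make_config(seed=0, **clean_overrides()))
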