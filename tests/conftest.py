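"""Shared fixtures: synthetic cohorts reused across the expensive tests.

Cohort generation dominates the suite's runtime, so the large cohorts are
session-scoped and shared: the 24-patient zero-noise cohort feeds both the
parameter-recovery checks and the CNN generalisation check; the small
noisy cohorts feed the directional-ordering check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epidfluence.pipeline import patient_feature_rows, simulate_cohort_features
from epidfluence.radiomics_features import ML_CONFIG_SOURCES
from epidfluence.synthetic_data import SimulationConfig, iter_patients


@pytest.fixture(scope="session")
def recovery_cohort():
    """24-patient zero-noise cohort: ML3 feature matrix + 128px CNN stacks.

    Sized so that post-filter feature counts stay well below the number
    of training rows (the regime the study's 32-patient training set
    provides), which plain LDA needs for stable covariance estimates.
    """
    cfg = SimulationConfig(n_patients=24, noise_sigma_frac=0.0, master_seed=1)
    cf = simulate_cohort_features(cfg, ml_config="ml3", cnn_size=128)
    return cf.matrix, cf.cnn_stacks


@pytest.fixture(scope="session")
def dd_cohorts():
    """Three independent small cohorts (default noise), DD-map features only."""
    out = []
    for seed in (2, 3, 4):
        cfg = SimulationConfig(n_patients=6, master_seed=seed)
        rows = []
        for _pid, records in iter_patients(cfg):
            r, _ = patient_feature_rows(records, ML_CONFIG_SOURCES["ml1"])
            rows.extend(r)
        out.append(pd.DataFrame(rows))
    return out


@pytest.fixture(scope="session")
def tiny_map_pair():
    """A small deterministic fluence-like map pair for map-level tests."""
    rng = np.random.default_rng(42)
    base = rng.random((24, 24)) * 100.0
    shifted = np.roll(base, 2, axis=0) + rng.random((24, 24))
    return base, shifted
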