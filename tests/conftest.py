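import logging

import numpy as np
import pandas as pd
import pytest

from snsubtype.pipeline import PipelineConfig, run_pipeline
from snsubtype.snf import SNFParams
from snsubtype.synthetic import SimConfig, simulate_bulk, simulate_cohort

logging.getLogger("snsubtype").setLevel(logging.ERROR)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort: 15 cases (6/4/5), 16 controls, 3 cell
    types, 500 genes, 50 sets, 100 cells per patient per type."""
    config = SimConfig(seed=DEFAULT_SEED)
    cohort = simulate_cohort(config)
    bulk = simulate_bulk(config, cohort.truth)
    return config, cohort, bulk


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for module-level checks."""
    config = SimConfig(seed=5, n_genes=240, n_gene_sets=15, de_genes_per_subtype_per_type=10,
                       cells_per_patient_per_type=40)
    cohort = simulate_cohort(config)
    return config, cohort


@pytest.fixture(scope="session")
def pipeline_run(default_cohort, tmp_path_factory):
    """One full pipeline run on the default cohort (shared across tests)."""
    config, cohort, bulk = default_cohort
    out = tmp_path_factory.mktemp("pipeline_run1")
    risk = [g for (s, _t), feats in cohort.truth.de_features.items() if s == 0
            for g, _e in feats][:40]
    pc = PipelineConfig(out_dir=str(out), seed=DEFAULT_SEED,
                        snf=SNFParams(seed=DEFAULT_SEED), bulk=bulk, risk_genes=risk)
    result = run_pipeline(pc, cohort=cohort)
    return pc, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def truth_labels(cohort, index) -> np.ndarray:
    truth = cohort.truth.subtype_of_patient
    return np.array([truth[p] for p in index])
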