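import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pkdresp import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def large_cohort():
    """n=2000 cohort under default generative parameters (shared, read-only)."""
    return simulate_cohort(CohortConfig(n_patients=2000, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small cohort with zero sequence noise: scans sit exactly on trajectories."""
    return simulate_cohort(CohortConfig(n_patients=20, sequence_cv=0.0, seed=3))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline run on the default 32-patient cohort, fixed seed 0."""
    from pkdresp import run_full_pipeline

    outdir = tmp_path_factory.mktemp("run")
    manifest = run_full_pipeline(outdir=outdir, seed=0, make_plots=False)
    return outdir, manifest
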