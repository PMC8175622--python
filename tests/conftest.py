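import numpy as np
import pytest

from virtualstroke.pipeline import ProcessingParams, process_cohort
from virtualstroke.synthetic import CohortConfig, generate_cohort, generate_patient


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-scale 2+2 cohort on a coarse grid."""
    return CohortConfig(
        n_theophylline=2, n_placebo=2, shape=(24, 24, 16), spacing=(3.0, 3.0, 4.0)
    )


@pytest.fixture(scope="session")
def processed_cohort(small_config):
    """2+2 cohort run through the full post-processing chain."""
    cases = generate_cohort(small_config, seed=42)
    return process_cohort(cases, ProcessingParams(), drop_raw=False)


@pytest.fixture(scope="session")
def noisefree_case():
    """One patient with noise-free DWI and perfusion (exact inversion)."""
    cfg = CohortConfig(
        n_theophylline=2,
        n_placebo=2,
        shape=(24, 24, 16),
        spacing=(3.0, 3.0, 4.0),
        dwi_noise_sd=0.0,
        perfusion_noise_sd=0.0,
        field_jitter_sd=0.0,
    )
    return generate_patient(cfg, 5, 0, "theophylline")
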