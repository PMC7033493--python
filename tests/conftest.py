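import logging

import pytest

from editscan.pipeline import load_cohort, run_pipeline
from editscan.simulate import SimulationConfig, null_config, simulate_cohort

logging.getLogger("editscan").setLevel(logging.ERROR)

DEFAULT_SEED = 20
NULL_SEED = 21


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default-scale synthetic cohort (80 tumor / 30 normal, 2,000 sites)."""
    out = tmp_path_factory.mktemp("cohort_default")
    return simulate_cohort(SimulationConfig(seed=DEFAULT_SEED), out)


@pytest.fixture(scope="session")
def default_inputs(default_cohort):
    return load_cohort(default_cohort.out_dir)


@pytest.fixture(scope="session")
def default_result(default_inputs):
    """Full pipeline run (all stages) on the default cohort."""
    return run_pipeline(default_inputs)


@pytest.fixture(scope="session")
def null_result(tmp_path_factory):
    """Pipeline run on a zero-planted-effect cohort (type-I-error checks)."""
    out = tmp_path_factory.mktemp("cohort_null")
    simulate_cohort(null_config(seed=NULL_SEED), out)
    return run_pipeline(load_cohort(out), run_rewire=False)
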