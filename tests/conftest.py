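import warnings

import pytest
from hypothesis import HealthCheck, settings

from onoffgrn.pipeline import run_pipeline
from onoffgrn.synthetic import SimConfig, simulate_timecourse

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_PIPELINE_CONFIG = {
    "seed": 5,
    "simulate": {"n_genes": 40, "n_tfs": 6, "n_isg_fast": 8, "n_isg_slow": 8, "replicates_per_cell": 2},
    "grn": {"n_trees": 25},
}


@pytest.fixture(scope="session")
def default_sim():
    """The full study-scale simulation (shared: it is the expensive fixture)."""
    return simulate_timecourse(SimConfig())


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """One end-to-end run of the default pipeline configuration."""
    out = tmp_path_factory.mktemp("pipeline_default")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline({"seed": 0}, out)
    return out, manifest
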