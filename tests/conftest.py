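import pytest

from secprof.pipeline import PipelineConfig, run_pipeline
from secprof.profiles_io import FractionScheme, SeparationKind
from secprof.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sec_scheme():
    return FractionScheme(
        SeparationKind.SEC_SUPERDEX, tuple(range(1, 25)), void_fraction=2
    )


@pytest.fixture(scope="session")
def sucrose_scheme():
    return FractionScheme(SeparationKind.SUCROSE, tuple(range(1, 26)))


@pytest.fixture(scope="session")
def sim60():
    """A modest labelled dataset reused across tests (deterministic, seed 1)."""
    return simulate_dataset(SimulationConfig(seed=1, n_proteins=60))


@pytest.fixture(scope="session")
def pipeline60(sim60):
    """Full pipeline run on the shared simulated dataset."""
    return run_pipeline(
        sim60.sec_profiles,
        sim60.records,
        sim60.standards,
        config=PipelineConfig(),
        sucrose_profiles=sim60.sucrose_profiles,
        cytosol_table=sim60.cytosol_table,
    )
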