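import numpy as np
import pytest

from lazsim import (
    AllocationRule,
    EffectProfile,
    ExperimentConfig,
    PopulationParams,
    run_grid,
    simulate_trial,
)


@pytest.fixture(scope="session")
def params():
    return PopulationParams.maled_bangladesh()


@pytest.fixture(scope="session")
def effect():
    return EffectProfile.default()


@pytest.fixture(scope="session")
def small_trial(params, effect):
    """One moderate imbalanced trial for per-trial identity checks."""
    return simulate_trial(params, effect, AllocationRule.imbalanced(), 400, seed=7)


@pytest.fixture(scope="session")
def table2_results():
    """The full imbalanced-scenario cell at n = 1000 with 1000 replicates.

    Shared by the acceptance checks and the oracle-agreement properties so the
    heavy simulation runs once per session.
    """
    config = ExperimentConfig(
        scenarios=("imbalanced",), n_grid=(1000,), n_replicates=1000, master_seed=20230713
    )
    return run_grid(config)


@pytest.fixture(scope="session")
def null_balanced_results():
    """Balanced allocation with a null effect profile: the calibration setting
    where every method's rejection rate should sit at alpha and coverage at
    the nominal 95%."""
    config = ExperimentConfig(
        scenarios=("balanced",),
        n_grid=(500,),
        n_replicates=1500,
        master_seed=424242,
        timepoints=(6.0, 24.0),
    )
    return run_grid(config, effect=EffectProfile.null())
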