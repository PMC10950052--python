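import numpy as np
import pytest

from lbacascade.lba import (LBAParameters, make_design, simulate_lba,
                            trials_to_dataframe)


@pytest.fixture(scope="session")
def cell_params():
    """Reference accumulator parameters: drift varies over the four
    condition cells, everything else shared."""
    return LBAParameters(v=np.array([3.5, 2.5, 3.0, 2.0]),
                         b=1.2, z=0.6, t0=0.35, s=1.0)


@pytest.fixture(scope="session")
def trial_table(cell_params):
    """One subject's simulated trial table (160 trials, 40 per cell)."""
    trials = simulate_lba(cell_params, make_design(40, seed=0), seed=2)
    return trials_to_dataframe(trials)


@pytest.fixture(scope="session")
def big_trial_table(cell_params):
    """A 640-trial table at the full per-participant scale."""
    trials = simulate_lba(cell_params, make_design(160, seed=1), seed=3)
    return trials_to_dataframe(trials)
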