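import numpy as np
import pytest

from fdindex import SimulationConfig, make_cohort, make_source_space, run_cohort


@pytest.fixture(scope="session")
def small_space():
    """600-source sphere with the five standard network patches."""
    return make_source_space(600, seed=1)


@pytest.fixture(scope="session")
def mini_cohort():
    """A small simulated cohort with a strong built-in group effect.

    3 + 3 subjects, 400 sources, 10 s at 125 Hz; shared across tests that
    only need a plausible end-to-end run, to keep the suite fast.
    """
    config = SimulationConfig(
        n_sources=400,
        fs=125.0,
        duration=10.0,
        hurst=0.3,
        group_effect=0.4,
        seed=7,
    )
    return make_cohort(3, 3, config, seed=7)


@pytest.fixture(scope="session")
def mini_cohort_run(mini_cohort):
    """Pipeline output (cohort table with FDI columns, window records)."""
    space, matrices, table = mini_cohort
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_cohort(space, matrices, table)
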