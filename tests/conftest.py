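import numpy as np
import pytest

from alphaband import CohortConfig, generate_cohort
from alphaband.cohort import build_source_grid


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny single-group cohort with signals, shared across read-only tests."""
    cfg = CohortConfig(
        group_sizes={"noSCD": 4}, n_per_axis=2, epoch_count=10, seed=7,
    )
    return generate_cohort(cfg, with_signals=True)


@pytest.fixture(scope="session")
def grid3():
    return build_source_grid(3, 10.0)
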