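import numpy as np
import pandas as pd
import pytest

from mitoclock import SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic gain cohort: 14 sites (2 per delta), 120 samples."""
    from mitoclock.simulate import AgeVarianceTable

    table = AgeVarianceTable(
        intervals=(
            (19.0, 40.0, 10, 1e-4),
            (40.0, 50.0, 15, 2e-4),
            (50.0, 60.0, 25, 3e-4),
            (60.0, 70.0, 30, 5e-4),
            (70.0, 80.0, 25, 7e-4),
            (80.0, 101.0, 15, 1e-3),
        )
    )
    spec = SimulationSpec(
        n_sites=14, n_samples=120, variance_table=table, seed=2024
    )
    return simulate_cohort(spec)


@pytest.fixture
def param_table():
    """A per-probe kinetic parameter table for clock scoring."""
    rng = np.random.default_rng(7)
    n = 25
    return pd.DataFrame(
        {
            "delta": rng.uniform(2e-5, 1e-3, n),
            "beta0": rng.uniform(0.0, 0.08, n),
        },
        index=pd.Index([f"cg{i:05d}" for i in range(n)], name="probe_id"),
    )
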