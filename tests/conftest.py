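"""Shared fixtures: reference plant, simulation runs, benchmark tables.

Expensive closed-loop runs and benchmark fits are session-scoped so the
same results back both the unit tests and the acceptance checks.
"""

import logging

import numpy as np
import pandas as pd
import pytest

from ventilab.bench import run_benchmark
from ventilab.dataset import LABEL_COLUMN, BreathTable, DatasetConfig, generate
from ventilab.engine import (
    default_pressure_scenario,
    default_volume_scenario,
    run_scenario,
)
from ventilab.plant import canonical_plant

# the canonical-plant assembly intentionally logs a reconciliation
# warning; keep it out of test output
logging.getLogger("ventilab.plant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def plant():
    """Delay-free canonical reference plant."""
    return canonical_plant()


@pytest.fixture(scope="session")
def pressure_runs():
    """Default CPAP pressure scenario under all three controllers."""
    return {
        name: run_scenario(default_pressure_scenario(name))
        for name in ("none", "pid", "ilcpid")
    }


@pytest.fixture(scope="session")
def volume_runs():
    """Default volume scenario under all three controllers."""
    return {
        name: run_scenario(default_volume_scenario(name))
        for name in ("none", "pid", "ilcpid")
    }


@pytest.fixture(scope="session")
def separable_table():
    """High-separability synthetic breath table (wide mode shifts)."""
    return generate(DatasetConfig(n_rows=1200, effect_size=4.0, seed=5))


@pytest.fixture(scope="session")
def separable_results(separable_table):
    return run_benchmark(separable_table, seed=5)


@pytest.fixture(scope="session")
def permuted_table():
    """A default-scale table with its labels permuted (seeded null).

    Run at the full 7000-row default: label-permutation nulls need the
    large sample for per-family accuracies to concentrate on chance.
    """
    frame = generate(DatasetConfig(seed=5)).frame.copy()
    rng = np.random.default_rng(17)
    frame[LABEL_COLUMN] = rng.permutation(frame[LABEL_COLUMN].to_numpy())
    return BreathTable(frame)


@pytest.fixture(scope="session")
def permuted_results(permuted_table):
    return run_benchmark(permuted_table, seed=5)
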