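"""Shared fixtures: small panels, cohorts and graphs built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from fairclin.cohort import CohortConfig, default_panel, generate_cohort
from fairclin.guprid import GupridPolicy
from fairclin.mapping import default_mapping
from fairclin.metadata import CatalogInfo, emit_fdp_layout
from fairclin.pipeline import default_descriptor
from fairclin.rdfizer import rdfize_measurements


def small_config(rng: np.random.Generator, max_records: int = 8,
                 max_analytes: int = 10) -> CohortConfig:
    """A random small cohort configuration over a prefix of the default panel.

    Using a prefix keeps the analytes' positional term ids identical to the
    full default mapping, so the shipped protein fixture stays applicable.
    """
    n_records = int(rng.integers(1, max_records + 1))
    n_patients = int(rng.integers(1, n_records + 1))
    n_analytes = int(rng.integers(1, max_analytes + 1))
    panel = [(label, 1) for label, _ in default_panel()[:n_analytes]]
    return CohortConfig(
        n_records=n_records,
        n_patients=n_patients,
        analyte_panel=panel,
        seed=int(rng.integers(0, 2**31 - 1)),
        missing_rate=float(rng.choice([0.0, 0.0, 0.2])),
    )


@pytest.fixture
def policy() -> GupridPolicy:
    return GupridPolicy()


@pytest.fixture(scope="session")
def pilot_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def pilot_cohort(pilot_config):
    return generate_cohort(pilot_config)


@pytest.fixture(scope="session")
def pilot_mapping():
    return default_mapping()


@pytest.fixture(scope="session")
def pilot_graph(pilot_cohort, pilot_mapping):
    return rdfize_measurements(pilot_cohort, pilot_mapping, GupridPolicy())


@pytest.fixture
def dataset_metadata_layout():
    return emit_fdp_layout(CatalogInfo(), [default_descriptor()], GupridPolicy())
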