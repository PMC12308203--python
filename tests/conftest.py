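"""Shared fixtures: the packaged reference tables and one default simulation."""

import pytest

from mitoprof.datasets import (
    load_reference_annotation,
    load_reference_codon_counts,
    load_reference_codon_frame,
    load_reference_composition,
    load_reference_feature_frame,
)
from mitoprof.gene_order import load_reference_orders
from mitoprof.synthetic_data import SimulationConfig, simulate_mitogenome


@pytest.fixture(scope="session")
def reference_annotation():
    return load_reference_annotation()


@pytest.fixture(scope="session")
def reference_features_frame():
    return load_reference_feature_frame()


@pytest.fixture(scope="session")
def reference_composition():
    return load_reference_composition()


@pytest.fixture(scope="session")
def reference_codon_counts():
    return load_reference_codon_counts()


@pytest.fixture(scope="session")
def reference_codon_frame():
    return load_reference_codon_frame()


@pytest.fixture(scope="session")
def reference_orders():
    orders, groups = load_reference_orders()
    return orders, groups


@pytest.fixture(scope="session")
def default_simulation():
    """One deterministic full-genome simulation shared across tests."""
    return simulate_mitogenome(SimulationConfig(seed=1))
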