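import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import trisodeconv as td


@pytest.fixture(scope="session")
def design():
    return td.make_design()


@pytest.fixture(scope="session")
def meta(design):
    return pd.DataFrame(
        [
            {"sample_id": s.sample_id, "line_id": s.line_id,
             "trisomic": s.trisomic, "batch": s.batch, "pool": s.pool}
            for s in design.samples
        ]
    ).set_index("sample_id")


@pytest.fixture(scope="session")
def reference():
    return td.simulate_reference(seed=11)


@pytest.fixture(scope="session")
def bulk_default(design, reference):
    """Default dosage (1.5x chr21) simulation shared across tests."""
    return td.simulate_bulk_counts(design, reference, seed=11)


@pytest.fixture(scope="session")
def basis(reference):
    return td.build_basis(
        reference.marker_table,
        reference.profiles_A,
        reference.profiles_B,
        reference.cluster_to_celltype,
        reference.annotation,
    )
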