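import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bccs

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from bccs.containers import ExpressionMatrix, SampleManifest


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort shared by read-only tests."""
    return bccs.generate_cohort(bccs.default_config(seed=11, n_normal=20, n_tumor=40))


@pytest.fixture(scope="session")
def consort_fixture():
    return bccs.generate_consort_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_manifest(rows):
    """rows: (sample_id, study, tissue, cancer_type, exclusion_class)."""
    return SampleManifest(
        pd.DataFrame(
            rows,
            columns=["sample_id", "study", "tissue", "cancer_type", "exclusion_class"],
        )
    )


def make_expression(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
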