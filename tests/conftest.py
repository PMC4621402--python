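import pytest

from scctraj.pipeline_io import build_cohort_table
from scctraj.synthetic_cohort import FIXTURE_SEED, generate_cohort, generate_fixture


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort under the default configuration."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def cohort_table(default_cohort):
    table, _ = build_cohort_table(default_cohort.records)
    return table


@pytest.fixture(scope="session")
def fixture_csv(tmp_path_factory):
    """The bundled small-cohort CSV, regenerated into a temp dir."""
    path = tmp_path_factory.mktemp("fixture") / "cohort.csv"
    generate_fixture(FIXTURE_SEED, path)
    return path
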