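import pytest
from hypothesis import HealthCheck, settings

from exome_triage.core_io import load_default_gene_table
from exome_triage.pipeline import run_pipeline_from_paths
from exome_triage.synthetic_cohort import (
    SyntheticConfig,
    generate_cohort,
    curated_fixture_config,
)

settings.register_profile(
    "triage",
    settings(
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("triage")


@pytest.fixture(scope="session")
def catalog():
    return load_default_gene_table()


@pytest.fixture(scope="session")
def curated_cohort():
    """Cohort with only the curated actionable set over a benign background."""
    return generate_cohort(curated_fixture_config(seed=1))


@pytest.fixture(scope="session")
def curated_result(curated_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("curated_cohort")
    paths = curated_cohort.write(out)
    return run_pipeline_from_paths(
        paths["vcf"],
        paths["participants"],
        paths["evidence"],
        genes_path=paths["genes"],
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full study-condition cohort: curated set, carriers, APOE, PGx."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("default_cohort")
    paths = default_cohort.write(out)
    return run_pipeline_from_paths(
        paths["vcf"],
        paths["participants"],
        paths["evidence"],
        genes_path=paths["genes"],
        panel_path=paths.get("panel"),
    )
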