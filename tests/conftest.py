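import pytest

from kpburden import (
    PlannedNovelVariant,
    SimulationParams,
    default_gene_set,
    simulate_cohort,
    write_fixtures,
)


@pytest.fixture(scope="session")
def gene_set():
    return default_gene_set()


@pytest.fixture(scope="session")
def planted_params():
    """Small cohort with planted novel variants, including one that must be
    rejected by depth QC and one carried by a single control individual."""
    return SimulationParams(
        seed=11,
        n_cases=120,
        n_sites_per_gene=5,
        novel_plan=(
            PlannedNovelVariant("GOT2", deleterious=True),
            PlannedNovelVariant("KYNU", deleterious=True),
            PlannedNovelVariant("HAAO", consequence="splicing", deleterious=True),
            PlannedNovelVariant("WARS", deleterious=False, depth=20),  # fails depth QC
            PlannedNovelVariant("TPH2", deleterious=False, control_carriers=1),
        ),
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_params):
    return simulate_cohort(planted_params)


@pytest.fixture(scope="session")
def fixture_dir(planted_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(planted_cohort, out)
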