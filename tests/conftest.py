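import pytest

import cosegscan as cs


@pytest.fixture(scope="session")
def family():
    return cs.load_family_pedigree()


@pytest.fixture(scope="session")
def table1_regions():
    return cs.load_table1_regions()


@pytest.fixture(scope="session")
def linked_regions():
    return cs.load_linked_regions()


@pytest.fixture(scope="session")
def candidates(family):
    return cs.load_candidate_vcf()


@pytest.fixture(scope="session")
def annotations():
    return cs.load_candidate_annotations()


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale simulation: 2 chromosomes, sparse markers, few variants."""
    return cs.SimulationConfig(
        chromosomes=(
            cs.ChromosomeSpec("1", 50_000_000, 50.0),
            cs.ChromosomeSpec("2", 40_000_000, 40.0),
        ),
        markers_per_chrom=15,
        n_background_variants=20,
    )
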