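import pytest

from glycotopo import fixture_path
from glycotopo.io_annotations import read_site_table, read_topology_table
from glycotopo.synthetic_data import generate_bundle


@pytest.fixture(scope="session")
def table1_sites():
    return read_site_table(fixture_path("table1_sites.tsv"))


@pytest.fixture(scope="session")
def table2_sites():
    return read_site_table(fixture_path("table2_interface_O.tsv"))


@pytest.fixture(scope="session")
def table3_sites():
    return read_site_table(fixture_path("table3_interface_N.tsv"))


@pytest.fixture(scope="session")
def topologies():
    return read_topology_table(fixture_path("topology.tsv"))


@pytest.fixture()
def bundle():
    """Default 4-helix bundle with planted glycans and orientations.

    Function-scoped: some tests rename residues in place.
    """
    return generate_bundle(
        n_helices=4,
        n_res=30,
        glycan_plants={5: "ASN", 40: "THR", 72: "SER"},
        orientation_plants={10: "lipid_facing", 50: "interior_facing"},
        seed=11,
    )
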