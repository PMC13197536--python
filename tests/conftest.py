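import pytest

from apricolor import io_tables, locus, synthetic_data


@pytest.fixture(scope="session")
def reference():
    return locus.reference_locus()


@pytest.fixture(scope="session")
def named_specs():
    return synthetic_data.named_allele_specs()


@pytest.fixture(scope="session")
def named_loci(named_specs):
    return {
        name: synthetic_data.simulate_allele_sequence(spec)
        for name, spec in named_specs.items()
    }


@pytest.fixture(scope="session")
def table1():
    return io_tables.load_fixture("table1_gxc")


@pytest.fixture(scope="session")
def table2():
    return io_tables.load_fixture("table2_cultivars")
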