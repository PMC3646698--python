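import pytest

from mitofossil.core_io import Gene, GeneOrderRecord, TaxonGroups, parse_dated_tree


@pytest.fixture
def quartet():
    """((A,B),(C,D)) with unit branch durations."""
    return parse_dated_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def basal_tree():
    """L sister to all other taxa, mirroring a magnoliid-outgroup layout."""
    return parse_dated_tree("(L:3,((M:1,N:1):1,(O:1,P:1):1):1);")


@pytest.fixture
def toy_groups():
    return TaxonGroups(
        {
            "Lirio": "magnoliid",
            "Cycas": "gymnosperm_outgroup",
            "Zea": "monocot_grass",
            "Phoenix": "monocot_nongrass",
            "Vitis": "eudicot_rosid",
            "Nicotiana": "eudicot_asterid",
            "Beta": "eudicot_other",
        }
    )


def make_record(species, genes, genome_length=100_000, topology="linear"):
    return GeneOrderRecord(
        species,
        genome_length,
        topology,
        [Gene(*g) if not isinstance(g, Gene) else g for g in genes],
    )


@pytest.fixture
def record_factory():
    return make_record
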