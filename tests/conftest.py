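import pytest

from ericakey import fixtures
from ericakey.matrix_model import (
    KeyDataset,
    TaxonRecord,
    default_schema,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def worked():
    """The tubular-flower-on-the-Peninsula dataset and its selection."""
    return fixtures.worked_example()


@pytest.fixture()
def tiny_dataset(schema):
    """Hand-built four-taxon dataset with a synonym and an unplaced name."""
    taxa = {
        "ar": TaxonRecord("ar", "Erica arborea"),
        "pl": TaxonRecord("pl", "Erica plukenetii"),
        "pl-h": TaxonRecord("pl-h", "Erica plukenetii subsp. hirsuta",
                            rank="subspecies", parent_id="pl"),
        "pl-p": TaxonRecord("pl-p", "Erica plukenetii subsp. plukenetii",
                            rank="subspecies", parent_id="pl"),
        "syn": TaxonRecord("syn", "Erica vetusta", status="synonym",
                           accepted_id="ar"),
        "unp": TaxonRecord("unp", "Erica dubia", status="unplaced",
                           wfo_id="wfo-0000000001"),
    }
    codings = {
        "ar": {"corolla_shape": frozenset({"tube"}),
               "corolla_colour": frozenset({"white"})},
        "pl-h": {"corolla_shape": frozenset({"tube"}),
                 "corolla_colour": frozenset({"red"})},
        "pl-p": {"corolla_shape": frozenset({"urn", "tube"}),
                 "corolla_colour": frozenset({"red"})},
    }
    distributions = {
        "ar": frozenset({"3318CD"}),
        "pl-h": frozenset({"3318CD", "3418BA"}),
        "pl-p": frozenset({"3418BA"}),
    }
    return KeyDataset(schema=schema, taxa=taxa, codings=codings,
                      distributions=distributions, points=[])


def random_dataset(seed, n_taxa=60, **kwargs):
    """Shared helper: a seeded random dataset for property tests."""
    spec = fixtures.DatasetSpec(n_taxa=n_taxa, seed=seed, **kwargs)
    return fixtures.generate_dataset(spec)
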