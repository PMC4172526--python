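import pytest

from binomatch import build_index, generate_reference


@pytest.fixture
def small_rows():
    return [
        {"genus": "Halymenia", "epithet": "dilatata", "authority": "Zanardini",
         "status": "accepted", "group": "plantae"},
        {"genus": "Halymenia", "epithet": "digitata", "authority": "J. Agardh",
         "status": "accepted", "group": "plantae"},
        {"genus": "Halymenia", "epithet": "floresii", "authority": "",
         "status": "accepted", "group": "plantae"},
        {"genus": "Homo", "epithet": "sapiens", "authority": "Linnaeus, 1758",
         "status": "accepted", "group": "animalia"},
        {"genus": "Fagus", "epithet": "sylvatica", "authority": "L.",
         "status": "accepted", "group": "plantae"},
        {"genus": "Fagus", "epithet": "silvatica", "authority": "",
         "status": "misspelling", "group": "plantae"},
        {"genus": "Siganus", "epithet": "canaliculatus", "authority": "(Park, 1797)",
         "status": "accepted", "group": "animalia"},
        # genus with no species: matchable at genus level only
        {"genus": "Catharacta", "epithet": "", "authority": "Brunnich, 1764",
         "status": "accepted", "group": "animalia"},
    ]


@pytest.fixture
def small_index(small_rows):
    return build_index(small_rows)


@pytest.fixture(scope="session")
def synthetic_rows():
    return generate_reference(60, 3, seed=7)


@pytest.fixture(scope="session")
def synthetic_index(synthetic_rows):
    return build_index(synthetic_rows)
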