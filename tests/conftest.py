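import pytest

from ftnorm.golden import bundled_phrase_types, bundled_rulestore


@pytest.fixture(scope="session")
def age_char_store():
    return bundled_rulestore("age", "character")


@pytest.fixture(scope="session")
def age_word_store():
    return bundled_rulestore("age", "word")


@pytest.fixture(scope="session")
def age_phrase_ruleset():
    return bundled_phrase_types("age")


@pytest.fixture(scope="session")
def loc_char_store():
    return bundled_rulestore("data_location", "character")


@pytest.fixture(scope="session")
def loc_word_store():
    return bundled_rulestore("data_location", "word")


@pytest.fixture(scope="session")
def loc_phrase_ruleset():
    return bundled_phrase_types("data_location")


@pytest.fixture
def stores_for():
    """Dataset name -> (char store, word store, phrase ruleset)."""
    def _get(dataset):
        return (bundled_rulestore(dataset, "character"),
                bundled_rulestore(dataset, "word"),
                bundled_phrase_types(dataset))
    return _get
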