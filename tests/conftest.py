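import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_records():
    from glycoflav.spectra import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture(scope="session")
def flavonoid_records(fixture_records):
    return [r for r in fixture_records if r.record_class == "flavonoid"]


@pytest.fixture(scope="session")
def aglycone_dict():
    from glycoflav.annotate import default_aglycone_dict

    return default_aglycone_dict()


@pytest.fixture()
def record_by_name(fixture_records):
    def get(name):
        return next(r for r in fixture_records if r.name == name)

    return get
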