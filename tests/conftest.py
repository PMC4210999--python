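import pytest

from microexpo import load_study_bundle


@pytest.fixture(scope="session")
def bundle():
    return load_study_bundle()


@pytest.fixture(scope="session")
def conc_table(bundle):
    return bundle.conc_table


@pytest.fixture(scope="session")
def male_profile(bundle):
    return bundle.profiles["male"]


@pytest.fixture(scope="session")
def female_profile(bundle):
    return bundle.profiles["female"]
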