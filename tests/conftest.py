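import warnings

import pytest

from socchrono import bundle_stock_profiles, generate_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (7 clusters, 11 plantations) with truth."""
    bundle, truth = generate_study(seed=7)
    return bundle, truth


@pytest.fixture(scope="session")
def bundle(study):
    return study[0]


@pytest.fixture(scope="session")
def truth(study):
    return study[1]


@pytest.fixture(scope="session")
def profiles(bundle):
    return bundle_stock_profiles(bundle)
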