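import random

import pytest

from gemforge.fixtures import (
    FixtureSpec,
    generate_bundle,
    generate_proteome_and_hits,
    toy_models,
)


@pytest.fixture(scope="session")
def toys():
    return toy_models()


@pytest.fixture(scope="session")
def bundle_fixture():
    return generate_bundle(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def proteome_fixture(bundle_fixture):
    return generate_proteome_and_hits(bundle_fixture, FixtureSpec(seed=1))


@pytest.fixture()
def rng():
    return random.Random(20240917)
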