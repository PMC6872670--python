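import json
import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for the oracles module

from druggability import synthetic as synth  # noqa: E402


@pytest.fixture(scope="session")
def fixture_corpus():
    """The fixed, hand-checkable miniature corpus."""
    return synth.generate_worked_fixture()


@pytest.fixture(scope="session")
def expected():
    """Oracle-computed expected values for the worked fixture."""
    path = os.path.join(os.path.dirname(__file__), "data", "worked_fixture_expected.json")
    with open(path) as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def small_corpus():
    """A small planted-effect corpus shared across read-only tests."""
    cfg = synth.SyntheticConfig(seed=11, n_targets=120, n_nontargets=240)
    return synth.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_partition(small_corpus):
    from druggability import cohorts as ch

    corp, _ = small_corpus
    return ch.build_cohorts(corp, seed=11)
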