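import datetime as dt

import pytest

from medreview.formulary import default_formulary
from medreview.rule_catalog import default_ruleset
from medreview.triggers import build_trigger_bundle

AS_OF = dt.date(2016, 6, 1)


@pytest.fixture(scope="session")
def as_of():
    return AS_OF


@pytest.fixture(scope="session")
def formulary():
    return default_formulary()


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def trigger_bundle():
    """One constructed patient per catalog rule (46 records)."""
    return build_trigger_bundle(AS_OF)
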