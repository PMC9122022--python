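import datetime as dt

import pytest

from oaphen.io import load_codesets
from oaphen.model import CodedEvent
from oaphen.rules import default_algorithms


@pytest.fixture(scope="session")
def codesets():
    return load_codesets()


@pytest.fixture(scope="session")
def algorithms_by_name():
    return {a.name: a for a in default_algorithms()}


@pytest.fixture(scope="session")
def oa_code(codesets):
    return codesets.codes("knee_oa")[0]


@pytest.fixture(scope="session")
def pain_code(codesets):
    return codesets.codes("knee_pain")[0]


BASE = dt.date(2005, 3, 1)


def events_at(code: str, offsets, pid: str = "P1", base: dt.date = BASE):
    """Coded events for one patient at day offsets from a base date."""
    return [CodedEvent(pid, code, base + dt.timedelta(days=o)) for o in offsets]
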