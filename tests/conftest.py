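import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from studysim.synth import make_toy, toy_ic

TOY_OBO = """\
format-version: 1.2

[Term]
id: R
name: root

[Term]
id: A
name: branch a
is_a: R ! root

[Term]
id: B
name: branch b
is_a: R ! root

[Term]
id: A1
name: leaf a1
is_a: A ! branch a

[Term]
id: A2
name: leaf a2
is_a: A ! branch a

[Term]
id: B1
name: leaf b1
is_a: B ! branch b
"""

#: parent-edge map of the toy ontology, for the brute-force oracles
TOY_EDGES = {
    "R": [],
    "A": ["R"],
    "B": ["R"],
    "A1": ["A"],
    "A2": ["A"],
    "B1": ["B"],
}

#: item-level class sets feeding the toy IC table
TOY_IC_SETS = {
    "I1": {"A1", "A2"},
    "I2": {"A1", "B1"},
    "I3": {"B"},
}


@pytest.fixture(scope="session")
def toy():
    """(ontology, corpus, ic) for the fixed six-class toy fixture."""
    ont, corpus = make_toy()
    ic = toy_ic(ont, corpus)
    return ont, corpus, ic


@pytest.fixture()
def toy_obo_file(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path
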