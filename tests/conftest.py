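import numpy as np
import pytest

from cnmfa.models import load_default_model
from cnmfa.correction import load_fragment_library
from cnmfa.network import parse_model


@pytest.fixture(scope="session")
def default_model():
    return load_default_model()


@pytest.fixture(scope="session")
def fragment_lib():
    return load_fragment_library()


def make_toy(text, config=None):
    return parse_model(text, config)


CHAIN = """rxn_id,equation,atom_transition,class,lb,ub
v1,A -> B,ab > ab,measured,0,10
v2,B -> C,ab > ab,dependent,0,10
"""

BRANCH_REARRANGE = """rxn_id,equation,atom_transition,class,lb,ub
u,S -> A,abc > abc,measured,0,10
r1,A -> B,abc > abc,dependent,0,10
r2,A -> B,abc > cba,free,0,10
out,B -> X,abc > abc,dependent,0,10
"""

CONDENSATION = """rxn_id,equation,atom_transition,class,lb,ub
ua,Sa -> A,ab > ab,measured,0,10
ub,Sb -> B,ab > ab,measured,0,10
c,A + B -> C,ab + cd > abcd,dependent,0,10
out,C -> X,abcd > abcd,dependent,0,10
"""

DECARBOXYLATION = """rxn_id,equation,atom_transition,class,lb,ub
u,S -> A,abc > abc,measured,0,10
dc,A -> B + CO2,abc > bc + a,dependent,0,10
fix,B + CO2 -> D,ab + c > abc,dependent,0,10
out,D -> X,abc > abc,dependent,0,10
"""

SYMMETRIC = """rxn_id,equation,atom_transition,class,lb,ub
u,S -> A,abcd > abcd,measured,0,10
s1,A -> P,abcd > abcd,dependent,0,10
out,P -> X,abcd > abcd,dependent,0,10
"""

REVERSIBLE_PAIR = """rxn_id,equation,atom_transition,class,lb,ub
u,S -> A,abc > abc,measured,0,10
x,A <-> B,abc > cba,dependent,-10,10
out,B -> X,abc > abc,dependent,0,10
"""


@pytest.fixture
def toy_models():
    return {
        "chain": make_toy(CHAIN),
        "branch": make_toy(BRANCH_REARRANGE),
        "condensation": make_toy(CONDENSATION),
        "decarboxylation": make_toy(DECARBOXYLATION),
        "symmetric": make_toy(SYMMETRIC, {"symmetric": ["P"]}),
        "reversible": make_toy(REVERSIBLE_PAIR),
    }


def random_mid(rng, n):
    x = rng.dirichlet(np.ones(n))
    return x
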