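import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from knotlayers.layering import IndexedPairSet, decompose
from knotlayers.synthdata import gen_planted_pairs, instance_to_ips


@pytest.fixture(scope="session")
def htype_instance():
    """The H-type (3+2 stems) planted instance used throughout."""
    return gen_planted_pairs([3, 2], seed=0)


@pytest.fixture(scope="session")
def htype_ips(htype_instance) -> IndexedPairSet:
    return instance_to_ips(htype_instance)


@pytest.fixture(scope="session")
def htype_decomposition(htype_ips):
    return decompose(htype_ips)


@pytest.fixture(scope="session")
def htype_cif(htype_instance, tmp_path_factory):
    from knotlayers.synthdata import gen_helix_mmcif

    path = tmp_path_factory.mktemp("fixtures") / "htype.cif"
    gen_helix_mmcif(htype_instance, path)
    return path


# Non-minimality witness: four stems P(3), Q(2), R(2), S(3) whose crossing
# graph is the path P-Q-R-S.  The unique maximum non-crossing subset is
# P u S (6 pairs), after which Q and R cross each other: greedy needs 3
# layers, but {P u R, Q u S} is a valid 2-layer partition.
WITNESS_PAIRS = {
    (0, 10), (1, 9), (2, 8),       # P
    (5, 15), (6, 14),              # Q
    (12, 22), (13, 21),            # R
    (17, 27), (18, 26), (19, 25),  # S
}
WITNESS_N = 28


@pytest.fixture(scope="session")
def witness_pairs():
    return set(WITNESS_PAIRS)
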