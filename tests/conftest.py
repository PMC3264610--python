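import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from organelle_dynamics.datasets import (BOEA_MT_LENGTH,
                                         BOEA_RECOMBINANT_REPEATS)
from organelle_dynamics.recombination import build_master_state, \
    decompose_segments
from organelle_dynamics.synthetic_data import random_sequence
from organelle_dynamics.seqio import CircularSequence


@pytest.fixture(scope="session")
def boea_pairs():
    return list(BOEA_RECOMBINANT_REPEATS)


@pytest.fixture(scope="session")
def boea_segments(boea_pairs):
    return decompose_segments(BOEA_MT_LENGTH, boea_pairs)


@pytest.fixture(scope="session")
def boea_mc(boea_segments, boea_pairs):
    return build_master_state(boea_segments, boea_pairs, BOEA_MT_LENGTH)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_circle(rng):
    return CircularSequence("rnd5k", random_sequence(rng, 5000, 0.43))
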