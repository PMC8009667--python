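import dataclasses

import numpy as np
import pytest

from pursuitlearn.paradigm import Geometry, SessionSpec, build_block, build_session
from pursuitlearn.synthetic_eyes import HOMOGENEOUS_PRESET, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geometry():
    return Geometry(base_deg=270.0, learned_deg=0.0)


@pytest.fixture
def config():
    return HOMOGENEOUS_PRESET


@pytest.fixture
def noiseless_config():
    return dataclasses.replace(HOMOGENEOUS_PRESET, pos_noise_sd_deg=0.0)


@pytest.fixture
def small_session(rng):
    """Paradigm-1 session with one learning block of each type plus washouts."""
    return build_session(1, 3, rng)


def paired_fixation_session(rng, n_pairs=3):
    """Alternating congruent/incongruent fixation blocks, each with a washout."""
    geom = Geometry(base_deg=270.0, learned_deg=0.0)
    blocks = []
    washout_map = {}
    for _ in range(n_pairs):
        for btype in ("fix_congruent", "fix_incongruent"):
            w = build_block("washout", geom, rng, block_id=len(blocks))
            blocks.append(w)
            lb = build_block(btype, geom, rng, block_id=len(blocks))
            blocks.append(lb)
            washout_map[lb.block_id] = w.block_id
    return SessionSpec(paradigm_id=1, blocks=blocks, washout_map=washout_map)
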