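import itertools

import numpy as np
import pytest

import heurbayes as hb


def exhaustive_inputs(m):
    """All 3^m comparison rows x in {-1,0,+1}^m."""
    return [np.array(x) for x in itertools.product((-1, 0, 1), repeat=m)]


@pytest.fixture(scope="session")
def small_table():
    """Five objects, three cues, all criterion values distinct."""
    return hb.ObjectTable(
        object_ids=["a", "b", "c", "d", "e"],
        criterion=np.array([10.0, 7.0, 5.0, 3.0, 1.0]),
        cues=np.array(
            [
                [1.0, 0.0, 1.0],
                [1.0, 1.0, 0.0],
                [0.0, 1.0, 1.0],
                [0.0, 0.0, 1.0],
                [0.0, 0.0, 0.0],
            ]
        ),
        cue_names=["c1", "c2", "c3"],
    )


@pytest.fixture(scope="session")
def env_pairs():
    """Mid-sized generated environment with known directions."""
    spec = hb.EnvironmentSpec(
        m=4, n_objects=12, weight_scale=1.0, cue_correlation=0.3, noise_sd=1.0, seed=3
    )
    return hb.make_pairs(hb.generate_environment(spec))
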